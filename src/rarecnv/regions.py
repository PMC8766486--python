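"""Carrier-aggregation regions, call assignment, gene burden, SV matching.

Regions are built per CNV type from per-probe distinct-carrier counts:
a region starts at a probe where at least ``min_carriers`` samples carry
a call and ends at the probe before the count first drops below the
threshold; regions separated by at most ``merge_gap_probes`` intervening
probes are merged.  Calls are assigned to the single region containing
at least 90% of their length.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import CarrierMatrix

__all__ = [
    "passing_calls",
    "build_regions",
    "merge_gene_regions",
    "assign_calls_to_regions",
    "harmonise_arrays",
    "gene_burden_matrix",
    "match_reference_variants",
]

REGION_COLUMNS = [
    "region_id",
    "chromosome",
    "start",
    "end",
    "start_index",
    "end_index",
    "n_probes",
    "cnv_type",
    "source_array",
]


def passing_calls(calls: pd.DataFrame, cnv_type: str | None = None) -> pd.DataFrame:
    """Calls of the given type with no filter flags."""
    ok = (calls["cnv_type"] != "none") & (calls["filter_flags"].fillna("") == "")
    if cnv_type is not None:
        ok &= calls["cnv_type"] == cnv_type
    return calls.loc[ok].reset_index(drop=True)


def _probe_carrier_counts(
    calls: pd.DataFrame, positions: np.ndarray
) -> np.ndarray:
    """Distinct samples carrying a call at each probe (diff-array sweep)."""
    delta = np.zeros(len(positions) + 1, dtype=int)
    for _, sample_calls in calls.groupby("sample_id", sort=False):
        covered = np.zeros(len(positions) + 1, dtype=int)
        for s, e in zip(sample_calls["start"], sample_calls["end"]):
            lo = np.searchsorted(positions, s, side="left")
            hi = np.searchsorted(positions, e, side="left")
            if hi > lo:
                covered[lo] += 1
                covered[hi] -= 1
        delta += (np.cumsum(covered[:-1]) > 0).astype(int).tolist() + [0]
    return delta[:-1]


def build_regions(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    cnv_type: str,
    min_carriers: int = 5,
    merge_gap_probes: int = 5,
    source_array: str | None = None,
) -> pd.DataFrame:
    """Build regions of one CNV type from filter-passing calls.

    ``probe_map`` must be the manifest of the array whose probe grid
    defines the regions.  Returns a frame with 0-based half-open
    coordinates; empty if no probe reaches ``min_carriers``.
    """
    calls = passing_calls(calls, cnv_type)
    source_array = source_array or (
        probe_map["array"].iloc[0] if len(probe_map) else "unknown"
    )
    rows = []
    for chrom, pm in probe_map.groupby("chromosome", sort=False):
        sub = calls[calls["chromosome"] == chrom]
        if sub.empty:
            continue
        positions = pm["position"].to_numpy()
        counts = _probe_carrier_counts(sub, positions)
        above = counts >= min_carriers
        if not above.any():
            continue
        # runs of qualifying probes as half-open index intervals
        edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
        runs = list(zip(edges[::2], edges[1::2]))
        merged = [list(runs[0])]
        for a, b in runs[1:]:
            if a - merged[-1][1] <= merge_gap_probes:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            rows.append(
                (
                    f"{cnv_type[:3]}_{chrom}_{positions[a]}",
                    chrom,
                    int(positions[a]),
                    int(positions[b - 1]) + 1,
                    int(a),
                    int(b),
                    int(b - a),
                    cnv_type,
                    source_array,
                )
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def merge_gene_regions(regions: pd.DataFrame, anchor_genes: pd.DataFrame) -> pd.DataFrame:
    """Merge all regions intersecting an anchor gene into a single region.

    ``anchor_genes`` columns: gene, chromosome, start, end (half-open).
    Regions not touching any anchor are unchanged.
    """
    if regions.empty or anchor_genes is None or anchor_genes.empty:
        return regions.copy()
    regions = regions.copy()
    out = []
    consumed = np.zeros(len(regions), dtype=bool)
    for _, g in anchor_genes.iterrows():
        hit = (
            (regions["chromosome"] == g["chromosome"])
            & (regions["start"] < g["end"])
            & (regions["end"] > g["start"])
            & ~consumed
        ).to_numpy()
        if not hit.any():
            continue
        sub = regions.loc[hit]
        consumed |= hit
        for cnv_type, tsub in sub.groupby("cnv_type", sort=False):
            out.append(
                {
                    "region_id": f"{cnv_type[:3]}_{g['chromosome']}_anchor_{g['gene']}",
                    "chromosome": g["chromosome"],
                    "start": int(tsub["start"].min()),
                    "end": int(tsub["end"].max()),
                    "start_index": int(tsub["start_index"].min()),
                    "end_index": int(tsub["end_index"].max()),
                    "n_probes": int(tsub["end_index"].max() - tsub["start_index"].min()),
                    "cnv_type": cnv_type,
                    "source_array": tsub["source_array"].iloc[0],
                }
            )
    if not out:
        return regions
    merged = pd.concat(
        [regions.loc[~consumed], pd.DataFrame(out, columns=REGION_COLUMNS)],
        ignore_index=True,
    )
    return merged.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)


def assign_calls_to_regions(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    sample_ids: np.ndarray,
    min_fraction: float = 0.9,
) -> tuple[CarrierMatrix, pd.DataFrame]:
    """Assign each passing call to at most one region by overlap fraction.

    A call joins the region holding at least ``min_fraction`` of its
    length; among eligible regions the largest fraction wins and ties
    go to the leftmost region.  Returns the binary carrier matrix over
    ``sample_ids`` x regions plus the per-call assignment table.
    """
    sample_ids = np.asarray(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    values = np.zeros((len(sample_ids), len(regions)), dtype=np.uint8)
    assignments = []
    if len(regions):
        regions = regions.sort_values(["chromosome", "start"], kind="stable").reset_index(
            drop=True
        )
    for ci, call in passing_calls(calls).iterrows():
        if len(regions) == 0:
            break
        cand = regions[
            (regions["chromosome"] == call["chromosome"])
            & (regions["cnv_type"] == call["cnv_type"])
        ]
        if cand.empty:
            continue
        length = call["end"] - call["start"]
        ov = np.minimum(cand["end"], call["end"]) - np.maximum(cand["start"], call["start"])
        frac = np.maximum(ov, 0) / length
        best = float(frac.max())
        if best < min_fraction:
            continue
        region = cand.loc[frac.idxmax()]  # idxmax: first max in start order
        assignments.append(
            (call["sample_id"], call["chromosome"], call["start"], call["end"],
             call["cnv_type"], region["region_id"], best)
        )
        ri = regions.index[regions["region_id"] == region["region_id"]][0]
        if call["sample_id"] in sample_index:
            values[sample_index[call["sample_id"]], ri] = 1
    matrix = CarrierMatrix(
        sample_ids=sample_ids,
        unit_ids=regions["region_id"].to_numpy() if len(regions) else np.array([]),
        values=values,
    )
    table = pd.DataFrame(
        assignments,
        columns=["sample_id", "chromosome", "start", "end", "cnv_type", "region_id", "fraction"],
    )
    return matrix, table


def harmonise_arrays(
    sparse_calls: pd.DataFrame,
    dense_regions: pd.DataFrame,
    sparse_probe_map: pd.DataFrame,
    cnv_type: str,
    min_carriers: int = 5,
    merge_gap_probes: int = 5,
    min_fraction: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-pass harmonisation of the sparser array onto the dense regions.

    Sparse-array calls overlapping a dense region by ``min_fraction`` of
    their length are assigned there; the remaining calls build
    sparse-only regions on the sparse probe grid.  Returns the combined
    region table with a ``provenance`` column (dense / both /
    sparse_only) and the sparse-call assignment table.
    """
    sparse_calls = passing_calls(sparse_calls, cnv_type)
    assigned_rows = []
    leftover = np.ones(len(sparse_calls), dtype=bool)
    dense = dense_regions[dense_regions["cnv_type"] == cnv_type].reset_index(drop=True)
    for ci, call in sparse_calls.iterrows():
        cand = dense[dense["chromosome"] == call["chromosome"]]
        if cand.empty:
            continue
        length = call["end"] - call["start"]
        ov = np.minimum(cand["end"], call["end"]) - np.maximum(cand["start"], call["start"])
        frac = np.maximum(ov, 0) / length
        if float(frac.max()) >= min_fraction:
            assigned_rows.append((ci, cand.loc[frac.idxmax(), "region_id"], float(frac.max())))
            leftover[ci] = False
    sparse_only = build_regions(
        sparse_calls.loc[leftover],
        sparse_probe_map,
        cnv_type,
        min_carriers=min_carriers,
        merge_gap_probes=merge_gap_probes,
    )
    sparse_only["provenance"] = "sparse_only"
    dense = dense.copy()
    hit_ids = {r for _, r, _ in assigned_rows}
    dense["provenance"] = np.where(dense["region_id"].isin(hit_ids), "both", "dense")
    combined = pd.concat([dense, sparse_only], ignore_index=True)
    assignment = pd.DataFrame(
        [
            (sparse_calls.loc[i, "sample_id"], region_id, frac)
            for i, region_id, frac in assigned_rows
        ],
        columns=["sample_id", "region_id", "fraction"],
    )
    return combined, assignment


def gene_burden_matrix(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    cnv_type: str,
    sample_ids: np.ndarray,
    min_carriers: int = 24,
) -> tuple[CarrierMatrix, pd.DataFrame]:
    """Exon-overlap gene burden carrier matrix.

    ``genes`` holds one row per exon (gene, chromosome, start, end,
    half-open).  A sample carries a gene iff any passing call of
    ``cnv_type`` intersects any exon by >= 1 bp.  Genes with fewer than
    ``min_carriers`` total carriers are dropped; the second return value
    records every gene's carrier count and whether it was tested.
    """
    calls = passing_calls(calls, cnv_type)
    sample_ids = np.asarray(sample_ids)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    gene_names = []
    columns = []
    counts = []
    for gene, exons in genes.groupby("gene", sort=False):
        exons = exons[exons["end"] > exons["start"]]
        if exons.empty:
            warnings.warn(f"gene {gene!r} has no usable exons; skipped")
            continue
        col = np.zeros(len(sample_ids), dtype=np.uint8)
        for _, ex in exons.iterrows():
            hit = calls[
                (calls["chromosome"] == ex["chromosome"])
                & (calls["start"] < ex["end"])
                & (calls["end"] > ex["start"])
            ]
            for s in hit["sample_id"]:
                if s in sample_index:
                    col[sample_index[s]] = 1
        gene_names.append(gene)
        columns.append(col)
        counts.append(int(col.sum()))
    summary = pd.DataFrame(
        {"gene": gene_names, "n_carriers": counts}
    ).assign(tested=lambda d: d["n_carriers"] >= min_carriers)
    kept = summary["tested"].to_numpy()
    values = (
        np.column_stack([c for c, k in zip(columns, kept) if k])
        if kept.any()
        else np.zeros((len(sample_ids), 0), dtype=np.uint8)
    )
    matrix = CarrierMatrix(
        sample_ids=sample_ids,
        unit_ids=np.asarray([g for g, k in zip(gene_names, kept) if k]),
        values=values,
    )
    return matrix, summary


def match_reference_variants(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    min_fraction: float = 0.9,
    max_reference_frequency: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Match calls to rare reference structural variants of the same type.

    A call matches when a same-type reference variant (frequency below
    ``max_reference_frequency``) covers at least ``min_fraction`` of the
    call's length.  Returns the per-call match table and a summary with
    the fraction of calls matched and of reference variants hit.
    """
    calls = passing_calls(calls)
    ref = reference[reference["frequency"] < max_reference_frequency].reset_index(drop=True)
    matched_ref: set = set()
    rows = []
    for _, call in calls.iterrows():
        cand = ref[
            (ref["chromosome"] == call["chromosome"])
            & (ref["cnv_type"] == call["cnv_type"])
        ]
        match_id, best = None, 0.0
        if not cand.empty:
            length = call["end"] - call["start"]
            ov = np.minimum(cand["end"], call["end"]) - np.maximum(cand["start"], call["start"])
            frac = np.maximum(ov, 0) / length
            best = float(frac.max())
            if best >= min_fraction:
                match_id = cand.loc[frac.idxmax(), "variant_id"]
                matched_ref.add(match_id)
        rows.append(
            (call["sample_id"], call["chromosome"], call["start"], call["end"],
             call["cnv_type"], match_id, best)
        )
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start", "end", "cnv_type", "matched_variant", "fraction"],
    )
    summary = {
        "n_calls": len(table),
        "fraction_calls_matched": float(table["matched_variant"].notna().mean()) if len(table) else 0.0,
        "n_reference": int(len(ref)),
        "fraction_reference_hit": float(len(matched_ref) / len(ref)) if len(ref) else 0.0,
    }
    return table, summary
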