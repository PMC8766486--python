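"""Sample-level quality control and positional exclusion masks.

Exclusions: sample call rate <= 0.99, non-blood DNA source, whole-genome
amplified samples, per-study DLRS outliers (pre- and post-adjustment),
and segment-count outliers via the ``y = 2*sqrt(x)`` transform with a
``median(y) + 3.5`` cutoff.  Calls intersecting telomere/centromere
buffers or configured immune loci by at least 1 bp are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "dlrs",
    "dlrs_per_sample",
    "exclude_by_dlrs",
    "segment_count_cutoff",
    "apply_sample_qc",
    "apply_region_masks",
    "structure_masks",
]


def dlrs(lrr: np.ndarray, chromosomes: np.ndarray | None = None) -> float:
    """Derivative log ratio spread of one sample's position-ordered LRR.

    SD (n-1 denominator) of first differences divided by sqrt(2).
    Differences never span chromosome boundaries, so per-sample offsets
    between chromosomes do not inflate the metric.
    """
    lrr = np.asarray(lrr, dtype=float)
    if lrr.size < 3:
        raise ValueError("dlrs requires at least 3 probes")
    if chromosomes is None:
        diffs = np.diff(lrr)
    else:
        chromosomes = np.asarray(chromosomes)
        same = chromosomes[1:] == chromosomes[:-1]
        diffs = np.diff(lrr)[same]
    if diffs.size < 2:
        raise ValueError("dlrs requires at least 2 within-chromosome differences")
    return float(np.std(diffs, ddof=1) / np.sqrt(2.0))


def dlrs_per_sample(lrr: np.ndarray, chromosomes: np.ndarray) -> np.ndarray:
    """Vectorised DLRS over the rows of a samples x probes LRR matrix."""
    lrr = np.asarray(lrr, dtype=float)
    chromosomes = np.asarray(chromosomes)
    same = chromosomes[1:] == chromosomes[:-1]
    diffs = np.diff(lrr, axis=1)[:, same]
    return np.std(diffs, axis=1, ddof=1) / np.sqrt(2.0)


def exclude_by_dlrs(
    metrics: pd.DataFrame, column: str, k_sd: float = 3.5
) -> pd.Series:
    """Per-study DLRS outlier flags: strictly above ``mean + k_sd * SD``.

    ``metrics`` needs ``study`` plus the named DLRS column.  Values
    exactly at the bound are retained.  Single-sample studies produce a
    warning and no exclusion.
    """
    out = pd.Series(False, index=metrics.index)
    for study, sub in metrics.groupby("study", sort=False):
        if len(sub) < 2:
            warnings.warn(f"study {study!r} has a single sample; DLRS cutoff skipped")
            continue
        vals = sub[column].to_numpy(float)
        bound = vals.mean() + k_sd * vals.std(ddof=1)
        out.loc[sub.index] = vals > bound
    return out


def segment_count_cutoff(counts) -> tuple[float, np.ndarray]:
    """Segment-count exclusion via ``y = 2*sqrt(x)``, cutoff ``median(y) + 3.5``.

    Returns ``(cutoff, excluded)`` where ``excluded`` marks samples with
    ``y`` strictly above the cutoff.  The even-n median is the midpoint
    of the two central values.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("segment_count_cutoff requires at least one sample")
    if (counts < 0).any():
        raise ValueError("segment counts must be non-negative")
    y = 2.0 * np.sqrt(counts)
    cutoff = float(np.median(y)) + 3.5
    return cutoff, y > cutoff


def apply_sample_qc(
    sheet: pd.DataFrame,
    metrics: pd.DataFrame,
    min_call_rate: float = 0.99,
    k_sd: float = 3.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply all sample-level exclusions.

    ``metrics`` is indexed like ``sheet`` rows (joined on sample_id) and
    carries ``dlrs_pre``, ``dlrs_post`` and ``segment_count``.  Returns
    ``(filtered sheet, per-sample QC report, per-study reason ledger)``.
    Call rate is a strict ``> min_call_rate`` requirement.
    """
    report = sheet[["sample_id", "study", "array"]].copy()
    merged = sheet.merge(metrics, on="sample_id", how="left", validate="one_to_one")

    reasons = {
        "call_rate": (merged["call_rate"] <= min_call_rate).to_numpy(),
        "not_blood": (~merged["blood_source"].astype(bool)).to_numpy(),
        "wga": merged["wga"].astype(bool).to_numpy(),
    }
    for col, name in (("dlrs_pre", "dlrs_pre"), ("dlrs_post", "dlrs_post")):
        if col in merged.columns and merged[col].notna().any():
            reasons[name] = exclude_by_dlrs(merged, col, k_sd=k_sd).to_numpy()
    if "segment_count" in merged.columns and merged["segment_count"].notna().any():
        counts = merged["segment_count"].fillna(0)
        cutoff, excl = segment_count_cutoff(counts)
        reasons["segment_count"] = excl
        report["segment_score"] = 2.0 * np.sqrt(counts.to_numpy(float))
        report.attrs["segment_cutoff"] = cutoff

    for name, mask in reasons.items():
        report[f"excl_{name}"] = mask
    excluded = np.column_stack(list(reasons.values())).any(axis=1)
    report["excluded"] = excluded
    report["exclusion_reasons"] = [
        ";".join(sorted(n for n, m in reasons.items() if m[i])) for i in range(len(report))
    ]
    for col in ("dlrs_pre", "dlrs_post", "segment_count"):
        if col in merged.columns:
            report[col] = merged[col].to_numpy()

    ledger = (
        report[report["excluded"]]
        .assign(reason=lambda d: d["exclusion_reasons"])
        .groupby(["study", "reason"])
        .size()
        .rename("n_samples")
        .reset_index()
    )
    filtered = sheet.loc[~excluded].reset_index(drop=True)
    return filtered, report, ledger


def _validate_masks(masks: pd.DataFrame) -> pd.DataFrame:
    required = {"chromosome", "start", "end"}
    if not required <= set(masks.columns):
        raise ValueError(f"mask table needs columns {sorted(required)}")
    if (masks["end"] <= masks["start"]).any():
        raise ValueError("malformed mask interval: end <= start")
    return masks


def apply_region_masks(calls: pd.DataFrame, masks: pd.DataFrame | None) -> pd.DataFrame:
    """Drop calls intersecting any mask interval by >= 1 bp (half-open)."""
    if masks is None or len(masks) == 0:
        return calls.copy()
    _validate_masks(masks)
    keep = np.ones(len(calls), dtype=bool)
    for chrom, sub in masks.groupby("chromosome", sort=False):
        sel = (calls["chromosome"] == chrom).to_numpy()
        if not sel.any():
            continue
        cs = calls.loc[sel, "start"].to_numpy()
        ce = calls.loc[sel, "end"].to_numpy()
        hit = np.zeros(sel.sum(), dtype=bool)
        for _, m in sub.iterrows():
            hit |= (cs < m["end"]) & (ce > m["start"])
        keep[np.flatnonzero(sel)[hit]] = False
    return calls.loc[keep].reset_index(drop=True)


def structure_masks(
    structure: pd.DataFrame, buffer_bp: int = 1_000_000
) -> pd.DataFrame:
    """Telomere/centromere exclusion intervals with a +/- buffer.

    ``structure`` columns: chromosome, length, centromere_start,
    centromere_end.  Output intervals are half-open and clipped to the
    chromosome.
    """
    rows = []
    for _, r in structure.iterrows():
        length = int(r["length"])
        rows.append((r["chromosome"], 0, min(length, buffer_bp), "telomere_p"))
        rows.append((r["chromosome"], max(0, length - buffer_bp), length, "telomere_q"))
        rows.append(
            (
                r["chromosome"],
                max(0, int(r["centromere_start"]) - buffer_bp),
                min(length, int(r["centromere_end"]) + buffer_bp),
                "centromere",
            )
        )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])
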