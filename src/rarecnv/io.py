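"""Tabular I/O.

All report tables are UTF-8 TSV with a header row.  Genomic coordinates
in report TSVs are 1-based inclusive (GRCh37 convention of the result
tables); BED files are 0-based half-open; both are converted to the
package-internal 0-based half-open representation on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CALL_COLUMNS, IntensityPanel, validate_probe_map, validate_sample_sheet

__all__ = [
    "load_intensities",
    "write_intensities_long",
    "read_probe_map",
    "write_probe_map",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_truth",
    "read_truth",
    "write_calls",
    "read_calls",
    "write_regions",
    "read_regions",
    "read_bed",
    "write_bed",
]

_LONG_ALIASES = {
    "sample_id": {"sample_id", "sample", "sample id"},
    "probe_id": {"probe_id", "snp name", "probe", "snp_name"},
    "lrr": {"lrr", "log r ratio", "log_r_ratio"},
    "baf": {"baf", "b allele freq", "b_allele_freq", "b allele frequency"},
}


def _normalise_long_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for canonical, aliases in _LONG_ALIASES.items():
        for col in df.columns:
            if col.strip().lower() in aliases:
                mapping[col] = canonical
                break
    df = df.rename(columns=mapping)
    missing = set(_LONG_ALIASES) - set(df.columns)
    if missing:
        raise ValueError(f"intensity file missing columns: {sorted(missing)}")
    return df


def load_intensities(
    path,
    probe_map: pd.DataFrame,
    sample_ids=None,
    layout: str = "long",
) -> tuple[IntensityPanel, pd.Series]:
    """Read an intensity table into a panel aligned with the manifest.

    ``layout="long"`` expects final-report style columns (sample id,
    probe id, Log R Ratio, B Allele Freq); ``layout="wide"`` expects
    ``path`` to be a ``(lrr_path, baf_path)`` pair of probes x samples
    matrices with ``probe_id`` as the first column.  Unknown probe ids
    raise with an offender list; duplicate (sample, probe) rows raise;
    BAF outside [0, 1] is clipped with a warning.  Returns the panel and
    the per-sample count of missing intensity values (for call-rate
    accounting).
    """
    probe_ids = probe_map["probe_id"].to_numpy()
    array = probe_map["array"].iloc[0]
    if layout == "long":
        df = pd.read_csv(path, sep="\t")
        df = _normalise_long_columns(df)
        unknown = sorted(set(df["probe_id"]) - set(probe_ids))
        if unknown:
            raise ValueError(
                f"{len(unknown)} unknown probe ids, e.g. {unknown[:5]}"
            )
        if df.duplicated(subset=["sample_id", "probe_id"]).any():
            bad = df[df.duplicated(subset=["sample_id", "probe_id"])].iloc[0]
            raise ValueError(
                f"duplicated (sample, probe) row: ({bad['sample_id']}, {bad['probe_id']})"
            )
        if sample_ids is None:
            sample_ids = df["sample_id"].drop_duplicates().to_numpy()
        lrr = (
            df.pivot(index="sample_id", columns="probe_id", values="lrr")
            .reindex(index=sample_ids, columns=probe_ids)
        )
        baf = (
            df.pivot(index="sample_id", columns="probe_id", values="baf")
            .reindex(index=sample_ids, columns=probe_ids)
        )
    elif layout == "wide":
        lrr_path, baf_path = path
        lrr = pd.read_csv(lrr_path, sep="\t", index_col=0).T
        baf = pd.read_csv(baf_path, sep="\t", index_col=0).T
        if sample_ids is None:
            sample_ids = lrr.index.to_numpy()
        unknown = sorted(set(lrr.columns) - set(probe_ids))
        if unknown:
            raise ValueError(f"{len(unknown)} unknown probe ids, e.g. {unknown[:5]}")
        lrr = lrr.reindex(index=sample_ids, columns=probe_ids)
        baf = baf.reindex(index=sample_ids, columns=probe_ids)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    missing = lrr.isna().sum(axis=1) + baf.isna().sum(axis=1)
    baf_arr = baf.to_numpy(float)
    n_clip = int(np.sum((baf_arr < 0) | (baf_arr > 1)))
    if n_clip:
        warnings.warn(f"clipped {n_clip} BAF values to [0, 1]")
        baf_arr = np.clip(baf_arr, 0.0, 1.0)
    panel = IntensityPanel(
        array=array,
        sample_ids=np.asarray(sample_ids),
        probe_ids=probe_ids,
        lrr=lrr.to_numpy(float),
        baf=baf_arr,
    )
    return panel, pd.Series(missing.to_numpy(), index=sample_ids, name="n_missing")


def write_intensities_long(panel: IntensityPanel, path) -> None:
    """Write a panel as a long-format TSV (sample_id, probe_id, lrr, baf)."""
    n, p = panel.lrr.shape
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(panel.sample_ids, p),
            "probe_id": np.tile(panel.probe_ids, n),
            "lrr": panel.lrr.ravel(),
            "baf": panel.baf.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_probe_map(df: pd.DataFrame, path) -> None:
    validate_probe_map(df).to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    return validate_probe_map(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    validate_sample_sheet(df).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))


def write_truth(truth, path) -> None:
    """Planted-variant truth table (1-based inclusive coordinates)."""
    rows = [
        (
            t.variant_id,
            t.chromosome,
            t.start + 1,
            t.end,
            t.cnv_type,
            t.population_frequency,
            t.log_odds_ratio,
            ",".join(sorted(t.carrier_samples)),
        )
        for t in truth
    ]
    pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chromosome", "start", "end", "cnv_type",
            "frequency", "log_odds_ratio", "carrier_samples",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list:
    from .core import CNVTruth

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        carriers = (
            frozenset(str(r["carrier_samples"]).split(","))
            if pd.notna(r["carrier_samples"]) and str(r["carrier_samples"])
            else frozenset()
        )
        out.append(
            CNVTruth(
                variant_id=r["variant_id"],
                chromosome=str(r["chromosome"]),
                start=int(r["start"]) - 1,
                end=int(r["end"]),
                cnv_type=r["cnv_type"],
                population_frequency=float(r["frequency"]),
                log_odds_ratio=float(r["log_odds_ratio"]),
                carrier_samples=carriers,
            )
        )
    return out


def write_calls(calls: pd.DataFrame, path) -> None:
    """Calls TSV with 1-based inclusive start/end."""
    out = calls.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"chromosome": str})
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    df["filter_flags"] = df["filter_flags"].astype(str).replace("nan", "")
    return df[CALL_COLUMNS + [c for c in df.columns if c not in CALL_COLUMNS]]


def write_regions(regions: pd.DataFrame, path) -> None:
    out = regions.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> internal intervals (identical convention)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chromosome", "start", "end", "name"][: min(df.shape[1], 4)]
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    df["chromosome"] = df["chromosome"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chromosome", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def atomic_write_json(obj: dict, path) -> None:
    """Write JSON via a temp file + rename so manifests are never partial."""
    import json

    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, default=str))
    tmp.replace(path)
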