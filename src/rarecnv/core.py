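"""Shared data containers and validation helpers.

Conventions used throughout the package:

* genomic intervals are 0-based half-open internally; report TSVs are
  written 1-based inclusive (GRCh37) and BED files 0-based half-open,
  with conversion handled in :mod:`rarecnv.io`;
* probe indices are 0-based with exclusive end, so ``n_probes ==
  end_index - start_index``;
* sample sheets and probe manifests are plain :class:`pandas.DataFrame`
  objects with fixed column sets (see the ``*_COLUMNS`` constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_MAP_COLUMNS = ["probe_id", "chromosome", "position", "array"]

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]

SAMPLE_SHEET_COLUMNS = (
    ["sample_id", "study", "array", "status", "er_status", "triple_negative"]
    + PC_COLUMNS
    + ["call_rate", "blood_source", "wga"]
)

CALL_COLUMNS = [
    "sample_id",
    "chromosome",
    "start",
    "end",
    "start_index",
    "end_index",
    "n_probes",
    "mean_z",
    "cnv_type",
    "filter_flags",
]

DELETION = "deletion"
DUPLICATION = "duplication"
NO_CALL = "none"


def validate_probe_map(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe manifest: required columns, unique ids, sorted positions.

    Positions must be strictly increasing within each chromosome (per array).
    Returns the frame unchanged on success.
    """
    missing = set(PROBE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe map missing columns: {sorted(missing)}")
    for arr, sub in df.groupby("array", sort=False):
        if sub["probe_id"].duplicated().any():
            dup = sub.loc[sub["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id {dup!r} in array {arr!r}")
        for chrom, pos in sub.groupby("chromosome", sort=False)["position"]:
            d = np.diff(pos.to_numpy())
            if len(d) and (d <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on {chrom} (array {arr!r})"
                )
    return df


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet: column set, unique ids, call rate in [0, 1]."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    cr = df["call_rate"].to_numpy(float)
    if np.any((cr < 0) | (cr > 1)):
        raise ValueError("call_rate outside [0, 1]")
    return df


@dataclass
class IntensityPanel:
    """LRR/BAF matrices for the samples and probes of one array.

    ``lrr`` and ``baf`` are ``(n_samples, n_probes)`` arrays aligned with
    ``sample_ids`` and ``probe_ids``.
    """

    array: str
    sample_ids: np.ndarray
    probe_ids: np.ndarray
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.probe_ids = np.asarray(self.probe_ids)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        shape = (len(self.sample_ids), len(self.probe_ids))
        if self.lrr.shape != shape or self.baf.shape != shape:
            raise ValueError(
                f"matrix shape mismatch: lrr {self.lrr.shape}, baf "
                f"{self.baf.shape}, expected {shape}"
            )
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BAF values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class CarrierMatrix:
    """Binary samples x units carrier indicator matrix.

    Units are regions, genes, or probes depending on the analysis.
    """

    sample_ids: np.ndarray
    unit_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.unit_ids = np.asarray(self.unit_ids)
        self.values = np.asarray(self.values, dtype=np.uint8)
        shape = (len(self.sample_ids), len(self.unit_ids))
        if self.values.shape != shape:
            raise ValueError(f"carrier matrix shape {self.values.shape} != {shape}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("carrier matrix must be binary")

    @property
    def carrier_counts(self) -> pd.Series:
        return pd.Series(self.values.sum(axis=0), index=self.unit_ids)

    def column(self, unit_id) -> np.ndarray:
        idx = np.flatnonzero(self.unit_ids == unit_id)
        if idx.size == 0:
            raise KeyError(unit_id)
        return self.values[:, idx[0]]


@dataclass(frozen=True)
class CNVTruth:
    """A planted copy-number variant with its carrier set (simulation truth)."""

    variant_id: str
    chromosome: str
    start: int
    end: int
    cnv_type: str
    population_frequency: float
    log_odds_ratio: float
    carrier_samples: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.variant_id}: start must be < end")
        if self.cnv_type not in (DELETION, DUPLICATION):
            raise ValueError(f"{self.variant_id}: bad type {self.cnv_type!r}")
        if not 0 <= self.population_frequency <= 1:
            raise ValueError(f"{self.variant_id}: bad frequency")
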