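"""Intensity-to-call conversion.

Stages, per array: per-study PCA adjustment of the LRR matrix, noisy /
masked probe removal, per-probe z-scores pooled over all samples,
circular binary segmentation per sample and chromosome, classification
against the deletion/duplication z windows, and the BAF-consistency and
sample-level LRR-shift filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import (
    CALL_COLUMNS,
    DELETION,
    DUPLICATION,
    NO_CALL,
    IntensityPanel,
)
from .segmentation import Segment, segment_values

__all__ = [
    "CallingParams",
    "CallingResult",
    "pca_adjust",
    "probe_zscores",
    "classify_segments",
    "baf_consistency_filter",
    "lrr_shift_filter",
    "noisy_probe_mask",
    "call_cnvs",
]


@dataclass
class CallingParams:
    """Tunable thresholds of the calling stage.

    The z-score windows, probe-count limits and the two-SD merge rule
    are fixed analysis choices; the BAF/LRR-shift filter bounds and the
    noisy-probe percentile are configurable because no published rule
    pins them down.
    """

    n_components: int = 5
    min_probe_sd: float = 1e-4
    noisy_probe_percentile: float = 97.5
    cbs_alpha: float = 0.01
    cbs_max_perm: int = 1000
    undo_sd: float = 2.0
    del_z_range: tuple[float, float] = (-14.0, -3.7)
    dup_z_range: tuple[float, float] = (2.0, 10.0)
    min_probes: int = 3
    max_probes: int = 200
    het_band: tuple[float, float] = (0.25, 0.75)
    max_het_fraction: float = 0.1
    del_shift_range: tuple[float, float] = (-1.2, -0.15)
    dup_shift_range: tuple[float, float] = (0.1, 0.7)
    seed: int = 0


@dataclass
class CallingResult:
    """Calls plus the side products needed by sample QC."""

    calls: pd.DataFrame
    segment_counts: pd.Series  # short (3-200 probe) segments per sample
    excluded_probes: list
    probe_sd: pd.Series
    sample_metrics: pd.DataFrame = None  # sample_id, dlrs_pre, dlrs_post, segment_count


def pca_adjust(lrr: np.ndarray, n_components: int, study: str | None = None) -> np.ndarray:
    """Remove the top principal components from one study's LRR matrix.

    The projection is computed on the column-centred matrix and the
    centring restored afterwards, so probe means are preserved.
    ``n_components == 0`` is the identity.
    """
    lrr = np.asarray(lrr, dtype=float)
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    if n_components == 0:
        return lrr.copy()
    label = f" for study {study!r}" if study else ""
    if lrr.shape[0] < n_components + 1:
        raise ValueError(
            f"{lrr.shape[0]} samples{label} cannot support "
            f"{n_components} principal components"
        )
    if n_components >= min(lrr.shape):
        raise ValueError(f"n_components must be < min(samples, probes){label}")
    solver = "full" if min(lrr.shape) <= 200 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(lrr)
    return lrr - scores @ pca.components_


def probe_zscores(
    lrr: np.ndarray, min_probe_sd: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each probe over all samples (n-1 denominator).

    Returns ``(z, excluded)`` where ``excluded`` marks probes with SD
    below ``min_probe_sd``; their z columns are NaN.  Raises if the
    matrix has fewer than two samples.
    """
    lrr = np.asarray(lrr, dtype=float)
    if lrr.shape[0] < 2:
        raise ValueError("probe_zscores requires at least 2 samples")
    mean = lrr.mean(axis=0)
    sd = lrr.std(axis=0, ddof=1)
    excluded = sd < min_probe_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (lrr - mean) / sd
    z[:, excluded] = np.nan
    return z, excluded


def noisy_probe_mask(lrr: np.ndarray, percentile: float = 97.5) -> np.ndarray:
    """Mark probes whose across-sample SD exceeds the given percentile."""
    sd = np.asarray(lrr, float).std(axis=0, ddof=1)
    return sd > np.percentile(sd, percentile)


def _mask_probe_hits(positions: np.ndarray, masks: pd.DataFrame | None) -> np.ndarray:
    if masks is None or masks.empty:
        return np.zeros(len(positions), dtype=bool)
    hit = np.zeros(len(positions), dtype=bool)
    for _, row in masks.iterrows():
        hit |= (positions >= row["start"]) & (positions < row["end"])
    return hit


def classify_segments(
    segments: list[Segment],
    params: CallingParams | None = None,
) -> list[tuple[Segment, str, set]]:
    """Classify segments by mean z; windows inclusive at both bounds.

    Returns ``(segment, class, flags)`` triples.  Segments whose mean
    falls in a calling window but whose probe count is outside
    ``[min_probes, max_probes]`` are set to ``none`` with a
    ``probe_count`` flag.
    """
    params = params or CallingParams()
    out = []
    for seg in segments:
        flags: set[str] = set()
        lo_d, hi_d = params.del_z_range
        lo_u, hi_u = params.dup_z_range
        if lo_d <= seg.mean <= hi_d:
            cls = DELETION
        elif lo_u <= seg.mean <= hi_u:
            cls = DUPLICATION
        else:
            cls = NO_CALL
        if cls != NO_CALL and not (params.min_probes <= seg.n_probes <= params.max_probes):
            cls = NO_CALL
            flags.add("probe_count")
        out.append((seg, cls, flags))
    return out


def baf_consistency_filter(
    cnv_type: str,
    baf_values: np.ndarray,
    het_band: tuple[float, float] = (0.25, 0.75),
    max_het_fraction: float = 0.1,
) -> set:
    """Flag deletions retaining a heterozygous BAF band.

    A true heterozygous deletion has one allele left, so BAF collapses
    to 0/1; a fraction of values inside ``het_band`` above
    ``max_het_fraction`` marks the call ``baf_inconsistent``.
    Duplications pass unexamined.  An empty BAF slice keeps the call.
    """
    if cnv_type != DELETION:
        return set()
    baf_values = np.asarray(baf_values, float)
    baf_values = baf_values[np.isfinite(baf_values)]
    if baf_values.size == 0:
        return set()
    lo, hi = het_band
    frac = np.mean((baf_values > lo) & (baf_values < hi))
    return {"baf_inconsistent"} if frac > max_het_fraction else set()


def lrr_shift_filter(
    cnv_type: str,
    shift_values: np.ndarray,
    del_range: tuple[float, float] = (-1.2, -0.15),
    dup_range: tuple[float, float] = (0.1, 0.7),
) -> set:
    """Flag calls whose sample-level LRR shift is outside the expected range.

    ``shift_values`` are the raw in-segment LRRs minus the sample's
    genome-wide median LRR; the decision uses their median.
    """
    if cnv_type == NO_CALL:
        return set()
    med = float(np.median(np.asarray(shift_values, float)))
    lo, hi = del_range if cnv_type == DELETION else dup_range
    return set() if lo <= med <= hi else {"lrr_shift"}


def call_cnvs(
    panel: IntensityPanel,
    probe_map: pd.DataFrame,
    sheet: pd.DataFrame,
    params: CallingParams | None = None,
    common_cnv_mask: pd.DataFrame | None = None,
) -> CallingResult:
    """Run the full calling stage on one array's intensity panel.

    ``sheet`` supplies the study grouping for the PCA adjustment.
    ``common_cnv_mask`` (columns chromosome/start/end, half-open) drops
    probes inside known common CNVs before standardisation.
    """
    params = params or CallingParams()
    pm = probe_map.set_index("probe_id").loc[panel.probe_ids].reset_index()
    positions = pm["position"].to_numpy()
    chromosomes = pm["chromosome"].to_numpy()

    # 1. per-study PCA adjustment
    studies = sheet.set_index("sample_id").loc[panel.sample_ids, "study"].to_numpy()
    adjusted = np.empty_like(panel.lrr)
    for study in pd.unique(studies):
        rows = np.flatnonzero(studies == study)
        adjusted[rows] = pca_adjust(panel.lrr[rows], params.n_components, study=study)

    # 2. probe exclusions: noisy tail + common-CNV mask
    drop = noisy_probe_mask(adjusted, params.noisy_probe_percentile)
    if common_cnv_mask is not None:
        for chrom in pd.unique(chromosomes):
            sel = chromosomes == chrom
            sub = common_cnv_mask[common_cnv_mask["chromosome"] == chrom]
            drop[sel] |= _mask_probe_hits(positions[sel], sub)

    # 3. z-scores over all samples of the array
    z, low_sd = probe_zscores(adjusted, params.min_probe_sd)
    drop |= low_sd
    keep = ~drop
    excluded_probes = list(np.asarray(panel.probe_ids)[drop])
    if not keep.any():
        raise ValueError("all probes excluded; empty z-score panel")

    probe_sd = pd.Series(
        adjusted.std(axis=0, ddof=1), index=panel.probe_ids, name="probe_sd"
    )

    z = z[:, keep]
    kept_pos = positions[keep]
    kept_chrom = chromosomes[keep]
    kept_index = np.flatnonzero(keep)
    sample_median_lrr = np.median(panel.lrr, axis=1)

    rng = np.random.default_rng(params.seed)
    records = []
    seg_counts = np.zeros(panel.n_samples, dtype=int)
    chrom_order = pd.unique(kept_chrom)
    chrom_slices = {c: np.flatnonzero(kept_chrom == c) for c in chrom_order}
    for si in range(panel.n_samples):
        for chrom in chrom_order:
            cols = chrom_slices[chrom]
            segs = segment_values(
                z[si, cols],
                alpha=params.cbs_alpha,
                max_perm=params.cbs_max_perm,
                undo_sd=params.undo_sd,
                rng=rng,
            )
            seg_counts[si] += sum(
                1 for s in segs if params.min_probes <= s.n_probes <= params.max_probes
            )
            for seg, cls, flags in classify_segments(segs, params):
                if cls == NO_CALL and not flags:
                    continue
                lo, hi = cols[seg.start], cols[seg.end - 1]
                probe_cols = kept_index[cols[seg.start] : cols[seg.end - 1] + 1]
                if cls != NO_CALL:
                    flags |= baf_consistency_filter(
                        cls,
                        panel.baf[si, probe_cols],
                        params.het_band,
                        params.max_het_fraction,
                    )
                    shift = panel.lrr[si, probe_cols] - sample_median_lrr[si]
                    flags |= lrr_shift_filter(
                        cls, shift, params.del_shift_range, params.dup_shift_range
                    )
                records.append(
                    (
                        panel.sample_ids[si],
                        chrom,
                        int(kept_pos[lo]),
                        int(kept_pos[hi]) + 1,
                        int(seg.start),
                        int(seg.end),
                        seg.n_probes,
                        seg.mean,
                        cls,
                        ";".join(sorted(flags)),
                    )
                )
    calls = pd.DataFrame(records, columns=CALL_COLUMNS)
    from .qc import dlrs_per_sample

    metrics = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "dlrs_pre": dlrs_per_sample(panel.lrr, chromosomes),
            "dlrs_post": dlrs_per_sample(adjusted, chromosomes),
            "segment_count": seg_counts,
        }
    )
    return CallingResult(
        calls=calls,
        segment_counts=pd.Series(seg_counts, index=panel.sample_ids, name="segment_count"),
        excluded_probes=excluded_probes,
        probe_sd=probe_sd,
        sample_metrics=metrics,
    )
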