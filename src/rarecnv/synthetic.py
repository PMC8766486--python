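"""Synthetic cohort generation.

Produces probe manifests for two arrays of different density, sample
sheets across several studies, planted rare deletions/duplications with
known carrier sets and effect sizes, case-control labels from a logistic
disease model, and LRR/BAF intensity panels with study-level low-rank
batch structure.  Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    DELETION,
    DUPLICATION,
    PC_COLUMNS,
    CNVTruth,
    IntensityPanel,
    validate_probe_map,
    validate_sample_sheet,
)

__all__ = [
    "VariantSpec",
    "StudySpec",
    "ScenarioConfig",
    "generate_probe_maps",
    "generate_truth_cohort",
    "assign_case_status",
    "simulate_intensity_panel",
    "synthetic_exons",
    "synthetic_reference_variants",
    "default_chromosome_structure",
]


@dataclass(frozen=True)
class VariantSpec:
    """Blueprint for one planted CNV."""

    chromosome: str
    start: int
    end: int
    cnv_type: str
    frequency: float
    log_odds_ratio: float = 0.0


@dataclass(frozen=True)
class StudySpec:
    """One study stratum: sample count, assigned array, disease-model offset."""

    name: str
    n_samples: int
    array: str
    effect: float = 0.0


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario.

    ``arrays`` maps array name to total probe count; probes are spread
    over ``chromosome_lengths`` proportionally to length on a jittered
    grid, so planted intervals of a few hundred kb are guaranteed probe
    coverage on the denser array.
    """

    chromosome_lengths: dict[str, int]
    arrays: dict[str, int]
    studies: list[StudySpec]
    variants: list[VariantSpec] = field(default_factory=list)
    noise_sd: float = 0.12
    batch_components: int = 0
    batch_scale: float = 0.1
    shift_del: float = -0.5
    shift_dup: float = 0.3
    het_rate: float = 0.3
    baf_noise: float = 0.03
    baseline_logit: float = 0.0
    er_negative_rate: float = 0.25
    triple_negative_rate: float = 0.1
    frac_noisy_samples: float = 0.0
    noisy_multiplier: float = 3.0
    allow_overlap: bool = False


def generate_probe_maps(config: ScenarioConfig, rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Jittered-grid probe positions per array, sorted within chromosome."""
    total_len = sum(config.chromosome_lengths.values())
    maps = {}
    for array, n_probes in config.arrays.items():
        rows = []
        for chrom, length in config.chromosome_lengths.items():
            k = max(3, int(round(n_probes * length / total_len)))
            spacing = length / k
            base = (np.arange(k) + 0.5) * spacing
            jitter = rng.uniform(-0.45, 0.45, size=k) * spacing
            pos = np.unique(np.clip((base + jitter).astype(np.int64), 0, length - 1))
            rows.append(
                pd.DataFrame(
                    {
                        "probe_id": [f"{array}_{chrom}_{i}" for i in range(len(pos))],
                        "chromosome": chrom,
                        "position": pos,
                        "array": array,
                    }
                )
            )
        maps[array] = validate_probe_map(pd.concat(rows, ignore_index=True))
    return maps


def _check_overlap(variants: list[VariantSpec]) -> None:
    by_key: dict[tuple, list[VariantSpec]] = {}
    for v in variants:
        by_key.setdefault((v.chromosome, v.cnv_type), []).append(v)
    for group in by_key.values():
        group = sorted(group, key=lambda v: v.start)
        for a, b in zip(group[:-1], group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping planted {a.cnv_type}s on {a.chromosome}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def generate_truth_cohort(
    config: ScenarioConfig, seed: int
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, list[CNVTruth]]:
    """Generate probe maps, a sample sheet, and planted CNV truth.

    Carrier sets are drawn independently per variant at its stated
    frequency.  Overlapping same-type variants are rejected unless
    ``config.allow_overlap`` is set.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if not config.allow_overlap:
        _check_overlap(config.variants)
    probe_maps = generate_probe_maps(config, rng)

    rows = []
    for study in config.studies:
        if study.array not in config.arrays:
            raise ValueError(f"study {study.name!r} uses unknown array {study.array!r}")
        for i in range(study.n_samples):
            rows.append((f"{study.name}_{i:05d}", study.name, study.array))
    sheet = pd.DataFrame(rows, columns=["sample_id", "study", "array"])
    n = len(sheet)
    sheet["status"] = "control"
    er = np.where(rng.random(n) < config.er_negative_rate, "negative", "positive")
    sheet["er_status"] = er
    sheet["triple_negative"] = (er == "negative") & (
        rng.random(n) < config.triple_negative_rate / max(config.er_negative_rate, 1e-9)
    )
    pcs = rng.normal(0.0, 1.0, size=(n, 10))
    for j, col in enumerate(PC_COLUMNS):
        sheet[col] = pcs[:, j]
    sheet["call_rate"] = np.clip(1.0 - np.abs(rng.normal(0.0, 0.002, n)), 0.0, 1.0)
    sheet["blood_source"] = True
    sheet["wga"] = False
    sheet["noisy"] = rng.random(n) < config.frac_noisy_samples
    validate_sample_sheet(sheet)

    sample_ids = sheet["sample_id"].to_numpy()
    truth = []
    for k, v in enumerate(config.variants):
        if v.frequency > 0:
            carriers = frozenset(sample_ids[rng.random(n) < v.frequency])
        else:
            carriers = frozenset()
        truth.append(
            CNVTruth(
                variant_id=f"cnv_{k:03d}",
                chromosome=v.chromosome,
                start=v.start,
                end=v.end,
                cnv_type=v.cnv_type,
                population_frequency=v.frequency,
                log_odds_ratio=v.log_odds_ratio,
                carrier_samples=carriers,
            )
        )
    return probe_maps, sheet, truth


def assign_case_status(
    truth: list[CNVTruth],
    sheet: pd.DataFrame,
    baseline_logit: float,
    study_effects: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw case/control labels from the logistic disease model.

    ``P(case) = expit(baseline + sum_k beta_k * carrier_k + study effect)``.
    ``baseline_logit`` of ``-inf``/``+inf`` yields all controls/cases.
    """
    for t in truth:
        if not np.isfinite(t.log_odds_ratio):
            raise ValueError(f"non-finite log odds ratio for {t.variant_id}")
    rng = np.random.default_rng(seed)
    sheet = sheet.copy()
    eta = np.full(len(sheet), float(baseline_logit))
    if study_effects:
        eta += sheet["study"].map(lambda s: study_effects.get(s, 0.0)).to_numpy(float)
    sample_ids = sheet["sample_id"].to_numpy()
    for t in truth:
        if t.carrier_samples and t.log_odds_ratio != 0.0:
            eta += np.isin(sample_ids, list(t.carrier_samples)) * t.log_odds_ratio
    p = expit(eta)
    sheet["status"] = np.where(rng.random(len(sheet)) < p, "case", "control")
    # subtype labels only apply to cases
    sheet.loc[sheet["status"] == "control", "er_status"] = "unknown"
    sheet.loc[sheet["status"] == "control", "triple_negative"] = False
    return sheet


def _baf_background(n: int, het_rate: float, baf_noise: float, rng) -> np.ndarray:
    """Diploid BAF: homozygous clusters at 0/1, heterozygous band at 0.5."""
    het = rng.random(n) < het_rate
    baf = np.where(
        rng.random(n) < 0.5,
        np.abs(rng.normal(0.0, baf_noise, n)),
        1.0 - np.abs(rng.normal(0.0, baf_noise, n)),
    )
    baf[het] = rng.normal(0.5, baf_noise, het.sum())
    return np.clip(baf, 0.0, 1.0)


def simulate_intensity_panel(
    probe_map: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: list[CNVTruth],
    noise_sd: float = 0.12,
    batch_components: int = 0,
    shift_del: float = -0.5,
    shift_dup: float = 0.3,
    seed: int | None = None,
    het_rate: float = 0.3,
    baf_noise: float = 0.03,
    batch_scale: float = 0.1,
    noisy_multiplier: float = 3.0,
) -> IntensityPanel:
    """Simulate LRR/BAF for the samples of one array.

    Carrier probes inside a planted variant get their LRR mean shifted
    by the type's shift (all carriers heterozygous); deletion BAF is
    drawn only near 0/1 and duplication BAF near {0, 1/3, 2/3, 1}.
    Study-level rank-``batch_components`` structure is added to the LRR
    on top of the i.i.d. noise, so that a per-study PCA adjustment is
    the correct remover.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not shift_del < 0 < shift_dup:
        raise ValueError("require shift_del < 0 < shift_dup")
    rng = np.random.default_rng(seed)
    array = probe_map["array"].iloc[0]
    sheet = sheet[sheet["array"] == array]
    sample_ids = sheet["sample_id"].to_numpy()
    positions = probe_map["position"].to_numpy()
    chroms = probe_map["chromosome"].to_numpy()
    n, p = len(sample_ids), len(positions)

    per_sample_sd = np.full(n, noise_sd)
    if "noisy" in sheet.columns:
        per_sample_sd[sheet["noisy"].to_numpy(bool)] *= noisy_multiplier
    lrr = rng.normal(0.0, 1.0, size=(n, p)) * per_sample_sd[:, None]
    baf = _baf_background(n * p, het_rate, baf_noise, rng).reshape(n, p)

    if batch_components > 0:
        for study in sheet["study"].unique():
            idx = np.flatnonzero((sheet["study"] == study).to_numpy())
            for _ in range(batch_components):
                u = rng.normal(0.0, 1.0, size=len(idx))
                v = rng.normal(0.0, 1.0, size=p)
                lrr[idx] += batch_scale * np.outer(u, v)

    sample_index = {s: i for i, s in enumerate(sample_ids)}
    for t in truth:
        cols = np.flatnonzero(
            (chroms == t.chromosome) & (positions >= t.start) & (positions < t.end)
        )
        if cols.size == 0:
            continue
        rows = [sample_index[s] for s in t.carrier_samples if s in sample_index]
        for r in rows:
            if t.cnv_type == DELETION:
                lrr[r, cols] += shift_del
                # single remaining allele: BAF collapses to 0/1
                m = cols.size
                b = np.where(
                    rng.random(m) < 0.5,
                    np.abs(rng.normal(0.0, baf_noise, m)),
                    1.0 - np.abs(rng.normal(0.0, baf_noise, m)),
                )
                baf[r, cols] = np.clip(b, 0.0, 1.0)
            else:
                lrr[r, cols] += shift_dup
                m = cols.size
                het = rng.random(m) < het_rate
                b = np.where(
                    rng.random(m) < 0.5,
                    np.abs(rng.normal(0.0, baf_noise, m)),
                    1.0 - np.abs(rng.normal(0.0, baf_noise, m)),
                )
                b[het] = np.where(
                    rng.random(het.sum()) < 0.5,
                    rng.normal(1.0 / 3.0, baf_noise, het.sum()),
                    rng.normal(2.0 / 3.0, baf_noise, het.sum()),
                )[: het.sum()]
                baf[r, cols] = np.clip(b, 0.0, 1.0)

    return IntensityPanel(
        array=array,
        sample_ids=sample_ids,
        probe_ids=probe_map["probe_id"].to_numpy(),
        lrr=lrr,
        baf=baf,
    )


def synthetic_exons(
    truth: list[CNVTruth], n_exons: int = 3, flank: int = 10_000
) -> pd.DataFrame:
    """Gene models covering each planted variant (one gene per variant).

    Exons tile the variant interval so an exon-overlap burden test can
    recover the planted carriers.  Returns a frame with columns
    ``gene, chromosome, start, end`` (0-based half-open exons).
    """
    rows = []
    for t in truth:
        gene = f"GENE_{t.variant_id}"
        span = t.end - t.start + 2 * flank
        exon_len = max(50, span // (3 * n_exons))
        for e in range(n_exons):
            s = t.start - flank + e * span // n_exons
            rows.append((gene, t.chromosome, max(0, s), max(0, s) + exon_len))
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end"])


def synthetic_reference_variants(
    truth: list[CNVTruth],
    jitter: int = 0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Reference SV table mirroring the planted truth (optionally jittered)."""
    rng = np.random.default_rng(rng)
    rows = []
    for t in truth:
        d1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        d2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        rows.append(
            (
                t.variant_id,
                t.chromosome,
                max(0, t.start + d1),
                max(t.start + d1 + 1, t.end + d2),
                t.cnv_type,
                t.population_frequency,
            )
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "start", "end", "cnv_type", "frequency"]
    )


def default_chromosome_structure(chromosome_lengths: dict[str, int]) -> pd.DataFrame:
    """Chromosome length table with a nominal centromere at 45-55% of length."""
    rows = [
        (chrom, length, int(0.45 * length), int(0.55 * length))
        for chrom, length in chromosome_lengths.items()
    ]
    return pd.DataFrame(
        rows, columns=["chromosome", "length", "centromere_start", "centromere_end"]
    )
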