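"""Bayesian false discovery probabilities and the directional U statistic.

BFDP follows Wakefield's approximate Bayes factor with a log-normal
effect prior whose scale is set by a 95% odds-ratio bound K.  The
direction-of-effect statistic is the maximum over r of the normalised
partial sum of ranked signed z-scores, assessed by permuting
case-control labels within study and re-running the association scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import fit_logistic, fit_logistic_lrt, make_design
from .core import CarrierMatrix

__all__ = [
    "BFDPConfig",
    "BFDPResult",
    "bfdp",
    "signed_z_scores",
    "signed_z_from_p",
    "u_statistic",
    "direction_permutation_test",
    "DirectionTestResult",
]


@dataclass(frozen=True)
class BFDPConfig:
    """Prior for the BFDP: probability of association and 95% OR bound."""

    prior_pi: float = 0.001
    k_bound: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_pi < 1.0:
            raise ValueError("prior_pi must be in (0, 1)")
        if self.k_bound <= 1.0:
            raise ValueError("k_bound must exceed 1")

    @property
    def prior_w(self) -> float:
        """Prior variance of the log odds ratio: (ln K / 1.96)^2."""
        return (np.log(self.k_bound) / 1.96) ** 2


@dataclass
class BFDPResult:
    unit_id: str
    beta: float
    se: float
    z: float
    abf: float  # P(data | H0) / P(data | H1)
    bfdp: float


def bfdp(beta: float, se: float, config: BFDPConfig, unit_id: str = "") -> BFDPResult:
    """Bayesian false discovery probability for one estimate.

    ABF = sqrt((V+W)/V) * exp(-z^2 W / (2 (V+W))) with V = se^2 and
    W the prior variance; BFDP = ABF(1-pi) / (ABF(1-pi) + pi).
    """
    if se <= 0:
        raise ValueError("se must be positive")
    v = se**2
    w = config.prior_w
    z = beta / se
    abf = float(np.sqrt((v + w) / v) * np.exp(-(z**2) * w / (2.0 * (v + w))))
    pi = config.prior_pi
    post = abf * (1.0 - pi) / (abf * (1.0 - pi) + pi)
    return BFDPResult(unit_id=unit_id, beta=beta, se=se, z=float(z), abf=abf, bfdp=float(post))


def signed_z_scores(results: pd.DataFrame) -> pd.Series:
    """Signed z: sign(beta) * sqrt(LRT chi2), indexed by unit id.

    A beta of exactly zero yields z = 0 regardless of the statistic.
    """
    beta = results["beta"].to_numpy(float)
    chi2 = results["lrt_chi2"].to_numpy(float)
    if not (np.isfinite(beta).all() and np.isfinite(chi2).all()):
        raise ValueError("signed z-scores require finite statistics")
    z = np.sign(beta) * np.sqrt(chi2)
    return pd.Series(z, index=results["unit_id"].to_numpy(), name="z")


def signed_z_from_p(p, direction) -> np.ndarray:
    """Signed z from two-sided p-values and a +/- direction indicator.

    ``|z| = Phi^-1(1 - p/2)``; summary-table mode for results published
    without the underlying statistics.  ``p == 0`` is rejected.
    """
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        raise ValueError("p = 0 cannot be inverted; use the statistic form")
    sign = np.where(np.asarray(direction) == "-", -1.0, 1.0)
    return sign * norm.isf(p / 2.0)


def u_statistic(z, direction: str = "auto") -> tuple[float, str]:
    """Maximum normalised partial sum of ranked signed z-scores.

    positive: rank descending, ``U+ = max_r sum(top r) / sqrt(r)``;
    negative: rank ascending, ``U- = min_r sum(bottom r) / sqrt(r)``;
    auto: whichever tail has the larger magnitude.
    Returns ``(U, direction used)``.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("u_statistic requires at least one z-score")
    r = np.sqrt(np.arange(1, z.size + 1))
    u_pos = float(np.max(np.cumsum(np.sort(z)[::-1]) / r))
    u_neg = float(np.min(np.cumsum(np.sort(z)) / r))
    if direction == "positive":
        return u_pos, "positive"
    if direction == "negative":
        return u_neg, "negative"
    if direction != "auto":
        raise ValueError(f"unknown direction {direction!r}")
    if abs(u_neg) > abs(u_pos):
        return u_neg, "negative"
    return u_pos, "positive"


@dataclass
class DirectionTestResult:
    u_observed: float
    direction: str
    permuted_u: np.ndarray
    k_extreme: int
    p: float


def permutation_p(k_extreme: int, n_perm: int) -> float:
    """Two-sided permutation p-value convention: 2 (k+1) / (B+1)."""
    return 2.0 * (k_extreme + 1) / (n_perm + 1)


def _scan_z(
    values: np.ndarray,
    unit_ids: np.ndarray,
    y: np.ndarray,
    X0: np.ndarray,
    min_carriers: int,
) -> pd.Series:
    reduced = fit_logistic(X0, y)
    z = {}
    for j, unit in enumerate(unit_ids):
        carrier = values[:, j].astype(float)
        if carrier.sum() < min_carriers or carrier.min() == carrier.max():
            continue
        r = fit_logistic_lrt(y, carrier, X0, unit_id=str(unit), reduced_fit=reduced)
        if r.converged:
            z[unit] = np.sign(r.beta) * np.sqrt(r.lrt_chi2)
    return pd.Series(z, dtype=float)


def direction_permutation_test(
    carrier_matrix: CarrierMatrix,
    sheet: pd.DataFrame,
    exclusions: list | None = None,
    n_perm: int = 50,
    seed: int | None = None,
    direction: str = "auto",
    min_carriers: int = 24,
    include_pcs: bool = True,
) -> DirectionTestResult:
    """Permutation test of the directional U statistic.

    The observed scan fixes the direction (under ``auto``, the larger
    tail).  Each permutation shuffles case/control labels within study
    -- preserving per-study case counts exactly -- re-runs the scan on
    the same carrier matrix, and recomputes U in the observed direction.
    ``exclusions`` removes known units (e.g. established susceptibility
    regions) before the statistic.  p = 2 (k+1) / (B+1), where k counts
    permutations at least as extreme in the observed direction; with
    B = 50 the minimum attainable p is 2/51 ~ 0.039.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    sheet = sheet.reset_index(drop=True)
    order = {s: i for i, s in enumerate(carrier_matrix.sample_ids)}
    idx = sheet["sample_id"].map(order)
    if idx.isna().any():
        raise ValueError("sheet contains samples absent from the carrier matrix")
    values = carrier_matrix.values[idx.to_numpy(int)]
    unit_ids = carrier_matrix.unit_ids
    if exclusions:
        keep = ~np.isin(unit_ids, list(exclusions))
        values = values[:, keep]
        unit_ids = unit_ids[keep]
    y = (sheet["status"] == "case").to_numpy(float)
    X0 = make_design(sheet, include_pcs=include_pcs)

    z_obs = _scan_z(values, unit_ids, y, X0, min_carriers)
    if z_obs.empty:
        raise ValueError("no units passed the carrier threshold")
    u_obs, used = u_statistic(z_obs.to_numpy(), direction)

    study_groups = [
        np.flatnonzero((sheet["study"] == s).to_numpy()) for s in pd.unique(sheet["study"])
    ]
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y.copy()
        for g in study_groups:
            y_perm[g] = y[g][rng.permutation(len(g))]
            assert y_perm[g].sum() == y[g].sum()
        z_b = _scan_z(values, unit_ids, y_perm, X0, min_carriers)
        u_b, _ = u_statistic(z_b.to_numpy(), used) if len(z_b) else (0.0, used)
        permuted[b] = u_b
    if used == "positive":
        k = int(np.sum(permuted >= u_obs))
    else:
        k = int(np.sum(permuted <= u_obs))
    return DirectionTestResult(
        u_observed=float(u_obs),
        direction=used,
        permuted_u=permuted,
        k_extreme=k,
        p=permutation_p(k, n_perm),
    )
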