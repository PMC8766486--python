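"""Logistic-regression association tests, meta-analysis, inflation.

Model: case status ~ carrier + study indicators + 10 ancestry PCs
(+ optional extra dosages).  Significance comes from the likelihood
ratio test against the model without the carrier term; the Wald SE of
the carrier coefficient is reported alongside.  Per-array results are
combined by inverse-variance fixed-effect meta-analysis after
re-deriving each stratum SE as |beta| / sqrt(LRT chi2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .core import PC_COLUMNS, CarrierMatrix

__all__ = [
    "AssociationResult",
    "MetaResult",
    "InflationResult",
    "LogisticFit",
    "fit_logistic",
    "fit_logistic_lrt",
    "make_design",
    "run_region_scan",
    "probe_scan",
    "meta_fixed_effects",
    "subtype_scan",
    "subtype_difference_test",
    "genomic_inflation",
    "rescale_lambda",
]

CHI2_MEDIAN_1DF = float(chi2_dist.ppf(0.5, 1))  # 0.4549364...


@dataclass
class AssociationResult:
    unit_id: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    lrt_chi2: float
    p: float
    carriers_case: int
    carriers_control: int
    converged: bool = True

    @property
    def direction(self) -> str:
        return "+" if self.beta >= 0 else "-"


@dataclass
class MetaResult:
    unit_id: str
    beta: float
    se: float
    p: float
    directions: str  # one character per stratum in array order, "?" if absent


@dataclass
class InflationResult:
    lambda_: float
    lambda_1000: float
    n_cases: int
    n_controls: int


@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    llf: float
    converged: bool


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    ``X`` must already include an intercept column.  Raises
    ``ValueError`` on a singular (collinear) design; a fit that walks to
    huge coefficients (separation) or fails to converge is returned with
    ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        xtwx = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix (collinear covariates)") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 25.0:
        converged = False
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta)
    llf = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    w = mu * (1.0 - mu)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return LogisticFit(beta=beta, cov=cov, llf=llf, converged=converged)


def make_design(
    sheet: pd.DataFrame,
    include_pcs: bool = True,
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate design: intercept, study indicators (ref = first), PCs.

    ``extra`` appends additional dosage columns (e.g. conditioning SNPs).
    """
    n = len(sheet)
    cols = [np.ones(n)]
    studies = pd.unique(sheet["study"])
    for s in studies[1:]:
        cols.append((sheet["study"] == s).to_numpy(float))
    if include_pcs:
        for c in PC_COLUMNS:
            if c in sheet.columns:
                cols.append(sheet[c].to_numpy(float))
    X = np.column_stack(cols)
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, float))
        if extra.shape[0] != n:
            extra = extra.T
        X = np.column_stack([X, extra])
    return X


def fit_logistic_lrt(
    y: np.ndarray,
    carrier: np.ndarray,
    covariates: np.ndarray | None = None,
    unit_id: str = "",
    reduced_fit: LogisticFit | None = None,
) -> AssociationResult:
    """Carrier association with a 1-df likelihood ratio test.

    ``covariates`` is a design matrix including the intercept (defaults
    to intercept only).  ``reduced_fit`` lets scans share the fit of the
    carrier-free model.  Requires both outcome classes present and a
    non-constant carrier vector.
    """
    y = np.asarray(y, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if carrier.min() == carrier.max():
        raise ValueError("carrier vector is constant")
    if covariates is None:
        covariates = np.ones((len(y), 1))
    X_full = np.column_stack([covariates, carrier])
    full = fit_logistic(X_full, y)
    if reduced_fit is None:
        reduced_fit = fit_logistic(covariates, y)
    lrt = max(0.0, 2.0 * (full.llf - reduced_fit.llf))
    beta = float(full.beta[-1])
    se = float(np.sqrt(full.cov[-1, -1]))
    p = float(chi2_dist.sf(lrt, 1))
    cc = int(np.sum((carrier > 0) & (y == 1)))
    cn = int(np.sum((carrier > 0) & (y == 0)))
    with np.errstate(over="ignore"):  # CI bounds may overflow under separation
        return AssociationResult(
            unit_id=unit_id,
            beta=beta,
            se=se,
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            lrt_chi2=float(lrt),
            p=max(p, 1e-300),
            carriers_case=cc,
            carriers_control=cn,
            converged=full.converged and reduced_fit.converged,
        )


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "unit_id": r.unit_id,
            "beta": r.beta,
            "se": r.se,
            "or": r.or_,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "lrt_chi2": r.lrt_chi2,
            "p": r.p,
            "carriers_case": r.carriers_case,
            "carriers_control": r.carriers_control,
            "direction": r.direction,
            "converged": r.converged,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "beta", "se", "or", "ci_low", "ci_high", "lrt_chi2",
            "p", "carriers_case", "carriers_control", "direction", "converged",
        ],
    )


def run_region_scan(
    carrier_matrix: CarrierMatrix,
    sheet: pd.DataFrame,
    min_carriers: int = 24,
    include_pcs: bool = True,
    extra: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list]:
    """One LRT per region with at least ``min_carriers`` carriers.

    Returns ``(results frame, skipped unit ids)``.  The carrier-free
    model is fitted once and shared across units.
    """
    sheet = sheet.reset_index(drop=True)
    order = {s: i for i, s in enumerate(carrier_matrix.sample_ids)}
    idx = sheet["sample_id"].map(order)
    if idx.isna().any():
        raise ValueError("sheet contains samples absent from the carrier matrix")
    values = carrier_matrix.values[idx.to_numpy(int)]
    y = (sheet["status"] == "case").to_numpy(float)
    X0 = make_design(sheet, include_pcs=include_pcs, extra=extra)
    reduced = fit_logistic(X0, y)
    results, skipped = [], []
    for j, unit in enumerate(carrier_matrix.unit_ids):
        carrier = values[:, j].astype(float)
        if carrier.sum() < min_carriers:
            skipped.append(unit)
            continue
        if carrier.min() == carrier.max():
            skipped.append(unit)
            continue
        results.append(
            fit_logistic_lrt(y, carrier, X0, unit_id=str(unit), reduced_fit=reduced)
        )
    return results_frame(results), skipped


def probe_scan(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    sheet: pd.DataFrame,
    cnv_type: str,
    probe_ids: np.ndarray | None = None,
    min_carriers: int = 1,
    include_pcs: bool = True,
) -> pd.DataFrame:
    """Per-probe pseudo-genotype scan.

    Each probe's carrier vector codes 1 for samples with a passing call
    of ``cnv_type`` covering the probe position.  Probes covered by no
    call are skipped.
    """
    from .regions import passing_calls

    calls = passing_calls(calls, cnv_type)
    pm = probe_map if probe_ids is None else probe_map[probe_map["probe_id"].isin(probe_ids)]
    sheet = sheet.reset_index(drop=True)
    sample_index = {s: i for i, s in enumerate(sheet["sample_id"])}
    y = (sheet["status"] == "case").to_numpy(float)
    X0 = make_design(sheet, include_pcs=include_pcs)
    reduced = fit_logistic(X0, y)
    results = []
    for _, probe in pm.iterrows():
        cov = calls[
            (calls["chromosome"] == probe["chromosome"])
            & (calls["start"] <= probe["position"])
            & (calls["end"] > probe["position"])
        ]
        if cov.empty:
            continue
        carrier = np.zeros(len(sheet))
        for s in cov["sample_id"]:
            if s in sample_index:
                carrier[sample_index[s]] = 1.0
        if carrier.sum() < min_carriers or carrier.min() == carrier.max():
            continue
        results.append(
            fit_logistic_lrt(y, carrier, X0, unit_id=str(probe["probe_id"]), reduced_fit=reduced)
        )
    return results_frame(results)


def meta_fixed_effects(
    per_array: dict[str, AssociationResult | None],
    array_order: list[str],
) -> MetaResult | None:
    """Inverse-variance fixed-effect combination across arrays.

    Each stratum SE is re-derived from the likelihood ratio statistic as
    ``|beta| / sqrt(chi2)``; strata with no data (or chi2 == 0, where
    that SE is undefined) contribute a "?" to the direction string.
    Returns ``None`` when no stratum is usable.
    """
    betas, ws, marks = [], [], []
    unit_id = ""
    for arr in array_order:
        r = per_array.get(arr)
        if r is None or not r.converged or r.lrt_chi2 <= 0:
            marks.append("?")
            continue
        unit_id = r.unit_id
        se = abs(r.beta) / np.sqrt(r.lrt_chi2)
        if not np.isfinite(se) or se <= 0:
            marks.append("?")
            continue
        betas.append(r.beta)
        ws.append(1.0 / se**2)
        marks.append("+" if r.beta >= 0 else "-")
    if not betas:
        return None
    betas, ws = np.asarray(betas), np.asarray(ws)
    beta = float(np.sum(ws * betas) / np.sum(ws))
    se = float(1.0 / np.sqrt(np.sum(ws)))
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    return MetaResult(unit_id=unit_id, beta=beta, se=se, p=max(p, 1e-300), directions="".join(marks))


def subtype_scan(
    carrier_matrix: CarrierMatrix,
    sheet: pd.DataFrame,
    subtype: str,
    min_carriers: int = 24,
    include_pcs: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Scan restricted to one case subtype; all controls retained.

    ``subtype`` is "er_positive", "er_negative", or "triple_negative".
    """
    is_case = sheet["status"] == "case"
    if subtype == "er_positive":
        keep_case = is_case & (sheet["er_status"] == "positive")
    elif subtype == "er_negative":
        keep_case = is_case & (sheet["er_status"] == "negative")
    elif subtype == "triple_negative":
        keep_case = is_case & sheet["triple_negative"].astype(bool)
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    if not keep_case.any():
        raise ValueError(f"no cases with subtype {subtype!r}")
    sub = sheet[keep_case | ~is_case].reset_index(drop=True)
    return run_region_scan(
        carrier_matrix, sub, min_carriers=min_carriers, include_pcs=include_pcs
    )


def subtype_difference_test(
    carrier: np.ndarray,
    case_sheet: pd.DataFrame,
    outcome: np.ndarray,
    include_pcs: bool = True,
) -> float:
    """Case-only test of carrier frequency difference between two subtypes.

    Logistic regression of the binary subtype ``outcome`` on carrier
    status among cases, adjusted for study (and PCs); two-sided Wald p
    for the carrier term.  Raises on separation or degenerate inputs.
    """
    outcome = np.asarray(outcome, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if outcome.min() == outcome.max():
        raise ValueError("both subtype classes must be present")
    X = np.column_stack([make_design(case_sheet, include_pcs=include_pcs), carrier])
    fit = fit_logistic(X, outcome)
    if not fit.converged:
        raise ValueError("subtype difference model did not converge (separation?)")
    z = fit.beta[-1] / np.sqrt(fit.cov[-1, -1])
    return float(2.0 * norm.sf(abs(z)))


def rescale_lambda(lambda_: float, n_cases: int, n_controls: int) -> float:
    """Rescale an inflation factor to 1,000 cases / 1,000 controls."""
    return 1.0 + (lambda_ - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)


def genomic_inflation(
    lrt_chi2, n_cases: int, n_controls: int
) -> InflationResult:
    """Median-based genomic inflation factor and its lambda_1000 rescaling."""
    stats = np.asarray(lrt_chi2, dtype=float)
    if stats.size == 0:
        raise ValueError("genomic_inflation requires at least one statistic")
    lam = float(np.median(stats) / CHI2_MEDIAN_1DF)
    return InflationResult(
        lambda_=lam,
        lambda_1000=rescale_lambda(lam, n_cases, n_controls),
        n_cases=n_cases,
        n_controls=n_controls,
    )
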