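"""Circular binary segmentation of per-probe z-scores.

Recursive changepoint search: at each step the arc ``(i, j]`` maximising
the circular two-sample t-statistic (arc versus the rest of the current
segment, pooled variance) is located exhaustively, accepted if its
permutation p-value falls below ``alpha``, and the three resulting
pieces are searched recursively.  Adjacent segments whose means differ
by less than ``undo_sd`` (z units) are merged afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segment", "best_arc", "segment_values"]

# pairs with zero pooled variance but unequal means get this pseudo-t
_T_INF = 1e12


@dataclass(frozen=True)
class Segment:
    """Half-open probe-index interval with its mean value."""

    start: int
    end: int
    mean: float

    @property
    def n_probes(self) -> int:
        return self.end - self.start


def best_arc(x: np.ndarray) -> tuple[int, int, float]:
    """Exhaustively locate the arc maximising the circular two-sample |t|.

    Considers every arc ``x[i:j]`` (``0 <= i < j <= n``, excluding the
    full vector) against its circular complement and returns
    ``(i, j, |t|)`` for the maximiser.  Ties resolve to the first pair
    in row-major ``(i, j)`` scan order.  Returns ``(0, n, 0.0)`` when no
    valid split exists (n < 2 or zero variance throughout).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 0, n, 0.0
    s = np.concatenate(([0.0], np.cumsum(x)))
    q = np.concatenate(([0.0], np.cumsum(x * x)))
    total, total_sq = s[n], q[n]

    best_tsq = -1.0
    best_ij = (0, n)
    # chunk over i to bound memory on long chromosomes
    chunk = max(1, int(4e6 // n))
    j = np.arange(n + 1)
    dof = max(n - 2, 1)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        i = np.arange(lo, hi)[:, None]
        k = (j[None, :] - i).astype(float)  # arc length; <1 or >n-1 invalid
        m = n - k
        sum1 = s[None, j] - s[i]
        ss1 = q[None, j] - q[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = sum1 / k - (total - sum1) / m
            ss = ss1 - sum1 * sum1 / k + (total_sq - ss1) - (total - sum1) ** 2 / m
            np.clip(ss, 0.0, None, out=ss)
            tsq = diff * diff * dof / (ss * (1.0 / k + 1.0 / m))
        # zero pooled variance with unequal means -> infinite t
        tsq[np.isnan(tsq)] = -1.0
        invalid = (k < 1) | (k > n - 1)
        tsq[invalid] = -1.0
        if n <= 2:
            tsq[np.abs(diff) <= 1e-12] = -1.0
        flat = int(np.argmax(tsq))
        ti = float(tsq.reshape(-1)[flat])
        if ti > best_tsq:
            best_tsq = ti
            best_ij = (lo + flat // (n + 1), flat % (n + 1))
    if best_tsq <= 0.0:
        return 0, n, 0.0
    t = _T_INF if np.isinf(best_tsq) else float(np.sqrt(best_tsq))
    return best_ij[0], best_ij[1], t


def _permutation_p(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    max_perm: int,
    rng: np.random.Generator,
    early_stop_k: int = 2,
    accept_t: float = 12.0,
) -> float:
    """Permutation p-value for the observed max arc |t| with early stopping.

    Sequential boundaries: stop and reject the split once exceedances
    make ``p >= alpha`` a foregone conclusion (``k >= early_stop_k`` with
    ``(k+1)/(b+1) > 2*alpha``, or ``k`` at the count that caps ``p``
    above ``alpha`` even at ``max_perm`` draws); stop and accept once
    ``(k+1)/(b+1) < alpha`` with no exceedance seen recently enough to
    matter.  An observed statistic above ``accept_t`` -- far beyond the
    null max-t range for any realistic probe count -- is accepted
    outright.  Deterministic given the generator state.
    """
    if t_obs >= accept_t:
        return 1.0 / (max_perm + 1)
    k = 0
    b = 0
    guarantee_k = int(np.ceil(alpha * (max_perm + 1)))
    while b < max_perm:
        xp = rng.permutation(x)
        _, _, t_perm = best_arc(xp)
        b += 1
        if t_perm >= t_obs:
            k += 1
            if k >= guarantee_k:
                break
            if k >= early_stop_k and (k + 1) / (b + 1) > 2 * alpha:
                break
        elif (k + 1) / (b + 1) < alpha:
            break
    return (k + 1) / (b + 1)


def _split_recursive(
    x: np.ndarray,
    offset: int,
    alpha: float,
    max_perm: int,
    rng: np.random.Generator,
    boundaries: set[int],
) -> None:
    n = x.size
    if n < 2:
        return
    i, j, t = best_arc(x)
    if t <= 0.0:
        return
    p = _permutation_p(x, t, alpha, max_perm, rng)
    if p >= alpha:
        return
    cuts = sorted({i, j} - {0, n})
    if not cuts:  # degenerate: full-vector arc, nothing to cut
        return
    edges = [0] + cuts + [n]
    for lo, hi in zip(edges[:-1], edges[1:]):
        boundaries.add(offset + lo)
        boundaries.add(offset + hi)
        _split_recursive(x[lo:hi], offset + lo, alpha, max_perm, rng, boundaries)


def _merge_close_means(x: np.ndarray, edges: list[int], undo_sd: float) -> list[int]:
    """Iteratively remove the boundary between the closest-mean adjacent pair."""
    edges = list(edges)
    while len(edges) > 2:
        means = [x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] >= undo_sd:
            break
        del edges[k + 1]
    return edges


def segment_values(
    x: np.ndarray,
    alpha: float = 0.01,
    max_perm: int = 1000,
    undo_sd: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> list[Segment]:
    """Segment one ordered vector of z-scores.

    Parameters
    ----------
    x
        z-scores ordered by probe position for one sample/chromosome.
    alpha
        Permutation significance required to accept a split.
    max_perm
        Permutation budget per split test (early stopping applies).
    undo_sd
        Post-hoc merge threshold: adjacent segments whose means differ
        by less than this (z units) are re-joined.
    rng
        Seed or generator driving the permutations.

    Returns
    -------
    list of :class:`Segment` partitioning ``range(len(x))``.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return []
    if not np.isfinite(x).all():
        raise ValueError("segment_values requires finite input")
    if x.size == 1:
        return [Segment(0, 1, float(x[0]))]
    rng = np.random.default_rng(rng)
    boundaries: set[int] = {0, x.size}
    _split_recursive(x, 0, alpha, max_perm, rng, boundaries)
    edges = sorted(boundaries)
    edges = _merge_close_means(x, edges, undo_sd)
    return [
        Segment(a, b, float(x[a:b].mean())) for a, b in zip(edges[:-1], edges[1:])
    ]
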