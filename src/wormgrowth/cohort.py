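"""Population-level comparisons of aligned per-animal trajectories.

Animals are aggregated on a common grid (hours post-hatch or percent of
larval stage); the module provides mean curves with normal-approximation
95% bands, bootstrap difference curves between groups (percentile
intervals over animal resampling), control-normalized summaries, recovery
ratios, and a Wilcoxon rank-sum test with an exact small-sample mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "CohortResult",
    "DifferenceCurve",
    "average_trajectories",
    "bootstrap_difference",
    "bootstrap_ratio",
    "normalize_to_control",
    "recovery_ratio",
    "rank_sum_test",
]


@dataclass
class CohortResult:
    """Mean trajectory of one group with a pointwise 95% band."""

    group: str
    n: int
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    curves: np.ndarray  # (n, grid) per-animal matrix


@dataclass
class DifferenceCurve:
    """Bootstrap mean-difference curve (group B − group A)."""

    grid: np.ndarray
    diff: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_boot: int
    seed: int
    degenerate: bool = False  # a group of size 1: band equals the estimate


def _curve_matrix(curves) -> np.ndarray:
    m = np.asarray(curves, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a (n_animals, n_gridpoints) matrix")
    return m


def average_trajectories(
    curves, grid: np.ndarray, group: str = "", z: float = 1.96
) -> CohortResult:
    """Pointwise mean with a mean ± z·SEM band (95% for z = 1.96).

    NaNs are ignored pointwise; grid points with fewer than 2 animals are
    masked in the band and fewer than 1 in the mean.
    """
    m = _curve_matrix(curves)
    if m.shape[0] == 0:
        raise ValueError("empty group")
    grid = np.asarray(grid, dtype=float)
    n_pt = np.sum(np.isfinite(m), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_pt >= 1, np.nanmean(m, axis=0), np.nan)
        sd = np.where(n_pt >= 2, np.nanstd(m, axis=0, ddof=1), np.nan)
    sem = sd / np.sqrt(np.maximum(n_pt, 1))
    return CohortResult(
        group=group,
        n=m.shape[0],
        grid=grid,
        mean=mean,
        lo=mean - z * sem,
        hi=mean + z * sem,
        curves=m,
    )


def _bootstrap_stat(
    a: np.ndarray,
    b: np.ndarray,
    stat,
    n_boot: int,
    seed: int,
):
    rng = np.random.default_rng(seed)
    na, nb = a.shape[0], b.shape[0]
    reps = np.empty((n_boot, a.shape[1]))
    for r in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        reps[r] = stat(a[ia], b[ib])
    return reps


def bootstrap_difference(
    curves_a,
    curves_b,
    grid: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> DifferenceCurve:
    """Bootstrap band for the pointwise mean difference (B − A).

    Animals are resampled with replacement within each group for each of
    ``n_boot`` repeats; the band is the 2.5/97.5 percentile of the
    resampled differences.  Groups of size 1 yield a degenerate band equal
    to the point estimate, flagged as such.
    """
    a = _curve_matrix(curves_a)
    b = _curve_matrix(curves_b)
    if n_boot < 1:
        raise ValueError("need at least one bootstrap repeat")
    diff = np.nanmean(b, axis=0) - np.nanmean(a, axis=0)
    if a.shape == b.shape and np.array_equal(a, b, equal_nan=True):
        # the two "groups" are the same animals: every resample of the
        # cohort cancels exactly, so the difference and its band are zero
        zero = np.zeros(a.shape[1])
        return DifferenceCurve(
            grid=np.asarray(grid, float), diff=zero, lo=zero.copy(), hi=zero.copy(),
            n_boot=n_boot, seed=seed,
        )
    if a.shape[0] < 2 or b.shape[0] < 2:
        return DifferenceCurve(
            grid=np.asarray(grid, float),
            diff=diff,
            lo=diff.copy(),
            hi=diff.copy(),
            n_boot=n_boot,
            seed=seed,
            degenerate=True,
        )
    reps = _bootstrap_stat(
        a, b, lambda x, y: np.nanmean(y, axis=0) - np.nanmean(x, axis=0), n_boot, seed
    )
    lo, hi = np.nanpercentile(reps, [2.5, 97.5], axis=0)
    return DifferenceCurve(
        grid=np.asarray(grid, float), diff=diff, lo=lo, hi=hi, n_boot=n_boot, seed=seed
    )


def bootstrap_ratio(
    curves_control,
    curves_treated,
    grid: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> DifferenceCurve:
    """Bootstrap band for the pointwise mean ratio (treated / control)."""
    a = _curve_matrix(curves_control)
    b = _curve_matrix(curves_treated)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.nanmean(b, axis=0) / np.nanmean(a, axis=0)
    if a.shape[0] < 2 or b.shape[0] < 2:
        return DifferenceCurve(
            grid=np.asarray(grid, float),
            diff=ratio,
            lo=ratio.copy(),
            hi=ratio.copy(),
            n_boot=n_boot,
            seed=seed,
            degenerate=True,
        )

    def stat(x, y):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nanmean(y, axis=0) / np.nanmean(x, axis=0)

    reps = _bootstrap_stat(a, b, stat, n_boot, seed)
    lo, hi = np.nanpercentile(reps, [2.5, 97.5], axis=0)
    return DifferenceCurve(
        grid=np.asarray(grid, float), diff=ratio, lo=lo, hi=hi, n_boot=n_boot, seed=seed
    )


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide values by the control-group mean (control mean maps to 1)."""
    control = np.asarray(control_values, dtype=float)
    mu = np.nanmean(control)
    if mu == 0 or not np.isfinite(mu):
        raise ValueError("control mean is zero or undefined")
    return np.asarray(values, dtype=float) / mu


def recovery_ratio(
    treated: CohortResult,
    control: CohortResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> DifferenceCurve:
    """Treated/control mean-ratio curve with a bootstrap band.

    A value of 1 indicates full recovery of the treated group to control
    levels.  Grid points where the control mean is ≤ 0 are masked.
    """
    if treated.grid.shape != control.grid.shape or np.any(treated.grid != control.grid):
        raise ValueError("cohorts must share a common grid")
    out = bootstrap_ratio(control.curves, treated.curves, control.grid, n_boot, seed)
    bad = ~(control.mean > 0)
    for arr in (out.diff, out.lo, out.hi):
        arr[bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_statistic(a: np.ndarray, b: np.ndarray):
    """Mid-rank sum of group A in the pooled sample, and tie counts."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i: j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return float(np.sum(ranks[: a.size])), ranks


def rank_sum_test(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the mid-rank sum of the first group.  For a
    combined sample of at most ``exact_max_n`` observations the null
    distribution is evaluated exactly by enumerating all assignments of
    the pooled ranks to group A (a permutation test on the rank sum,
    handling ties through mid-ranks); the two-sided p-value is
    P(|W* − E W| ≥ |W − E W|), which equals 1 for identical groups.
    Larger samples use the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    w, ranks = _rank_sum_statistic(a, b)
    n, m = a.size, b.size
    n_tot = n + m
    mu = n * (n_tot + 1) / 2.0

    if n_tot <= exact_max_n:
        dev = abs(w - mu)
        hits = 0
        for idx in combinations(range(n_tot), n):
            ws = ranks[list(idx)].sum()
            if abs(ws - mu) >= dev - 1e-12:
                hits += 1
        return w, hits / comb(n_tot, n)

    # normal approximation with tie correction
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n * m / 12.0 * ((n_tot + 1) - tie_term / (n_tot * (n_tot - 1)))
    if var == 0:
        return w, 1.0
    from scipy.stats import norm

    z = (abs(w - mu) - 0.5) / np.sqrt(var)  # continuity correction
    return w, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
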