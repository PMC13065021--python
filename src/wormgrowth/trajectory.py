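"""Per-animal developmental analytics from per-frame morphometry.

Converts a time series of volume/fluorescence measurements into the
quantities growth studies report: smoothed trajectories, hatch and molt
times, volumes at stage boundaries, volume-specific growth rates
g = dV/dt/V = dlog(V)/dt, windowed robust summaries, and trajectories
rescaled to percent of larval stage so animals with different stage
durations can be averaged.

Molts are identified by the maximum of the second time derivative of
log-volume: growth halts in a plateau (lethargus) before each ecdysis and
resumes sharply after it, producing a curvature peak at the stage
transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded
import statsmodels.api as sm

__all__ = [
    "AnimalTrajectory",
    "MoltAnnotation",
    "StageScaledTrajectory",
    "AnalysisConfig",
    "median_filter",
    "rlowess_smooth",
    "whittaker_smooth",
    "detect_hatch",
    "detect_molts",
    "boundary_volume",
    "specific_growth_rate",
    "absolute_growth_rate",
    "windowed_summary",
    "exclude_outliers",
    "rescale_stages",
]


@dataclass
class AnimalTrajectory:
    """Per-frame record for one animal; NaN marks QC-excluded frames."""

    times: np.ndarray  # h, strictly increasing, constant spacing
    volume: np.ndarray  # µm³
    area: np.ndarray | None = None  # px
    total_fluor: np.ndarray | None = None
    concentration: np.ndarray | None = None  # per-pixel, a.u.
    qc_pass: np.ndarray | None = None  # bool per frame
    animal_id: str = ""
    group: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.volume.size:
            raise ValueError("times and volume must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.qc_pass is None:
            self.qc_pass = np.isfinite(self.volume)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class MoltAnnotation:
    """Hatch and molt times with detection scores (log-volume curvature)."""

    hatch_time: float
    molt_times: np.ndarray  # τ_M1..τ_M4; NaN where undetected
    scores: np.ndarray  # second-derivative magnitude at each molt
    method: str = "auto"  # auto / override

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.molt_times)))


@dataclass
class StageScaledTrajectory:
    """A signal resampled onto a fixed stage-progression grid.

    ``progression`` is in percent of stage (K points per completed stage,
    plus an optional extension into the following stage, e.g. 100–120%).
    """

    stage_index: np.ndarray  # which stage each grid point belongs to
    progression: np.ndarray  # % of that stage (extension runs past 100)
    values: np.ndarray
    stage_durations: np.ndarray  # h, for back-transformation
    stages_present: np.ndarray  # bool per requested stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the per-animal analytics.

    Defaults follow the conventions of microchamber growth assays: 3-point
    median prefilter, 15-point robust lowess, 10-point boundary
    regressions, Whittaker smoothing strength λ = 0.75 on an hour-valued
    time axis, a 3.7 h summary window centred 4.3 h after hatch, 3-SD
    outlier cut and a 100-point stage grid.
    """

    median_window: int = 3
    rlowess_window: int = 15
    boundary_points: int = 10
    whittaker_lambda: float = 0.75
    whittaker_order: int = 2
    summary_center_h: float = 4.3
    summary_halfwidth_h: float = 3.7 / 2.0
    outlier_sd: float = 3.0
    stage_points: int = 100
    stage_extension: float = 0.2
    min_molt_separation_h: float = 5.0
    plateau_lookback_h: float = 3.0
    plateau_slope_frac: float = 0.5
    n_molts: int = 4

    def __post_init__(self):
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median window must be odd and >= 1")
        if self.rlowess_window < 1:
            raise ValueError("rlowess window must be >= 1")
        if self.whittaker_lambda < 0:
            raise ValueError("Whittaker lambda must be >= 0")
        if self.stage_points < 2:
            raise ValueError("stage grid needs at least 2 points")


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _nan_runs(values: np.ndarray):
    """Contiguous runs of finite samples (gaps are never bridged)."""
    finite = np.isfinite(values)
    edges = np.flatnonzero(np.diff(finite.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [values.size]])
    return [(s, e) for s, e in zip(starts, ends) if finite[s]]


def median_filter(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred running median with shrunken windows at the edges.

    QC gaps (NaN) split the series; the filter never bridges across them.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    half = window // 2
    for s, e in _nan_runs(series):
        seg = series[s:e]
        for i in range(seg.size):
            # shrink symmetrically near edges so windows stay odd and
            # centred; edge points keep their own value
            h = min(half, i, seg.size - 1 - i)
            out[s + i] = np.median(seg[i - h: i + h + 1])
    return out


def rlowess_smooth(series: np.ndarray, window: int = 15) -> np.ndarray:
    """Robust local linear regression ('rlowess') over ``window`` points.

    For each point, a weighted linear fit over its ``window`` nearest
    neighbours (tricube distance weights on the index axis) is combined
    with bisquare robustness reweighting over 5 iterations; residual scale
    is 6·MAD, and when the MAD collapses to zero only exact-fit points
    keep weight, so isolated gross outliers on otherwise exact data are
    excluded entirely.  Runs shorter than the window fall back to a local
    linear fit over all available points; NaN gaps split the series and
    are never bridged.
    """
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    for s, e in _nan_runs(series):
        out[s:e] = _rlowess_run(series[s:e], window)
    return out


def _rlowess_run(y: np.ndarray, window: int, n_robust: int = 5) -> np.ndarray:
    n = y.size
    if n < 3:
        return y.copy()
    w = min(window, n)
    x = np.arange(n, dtype=float)
    # nearest-w neighbourhoods: contiguous on the index axis, shifted
    # inward at the edges so every point sees a full window
    lo = np.clip(np.arange(n) - (w - 1) // 2, 0, n - w)
    idx = lo[:, None] + np.arange(w)[None, :]  # (n, w)
    d = np.abs(idx - np.arange(n)[:, None]).astype(float)
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    tric = (1.0 - (d / dmax) ** 3) ** 3
    tric = np.clip(tric, 0.0, None)

    robust = np.ones(n)
    fitted = y.copy()
    for _ in range(n_robust + 1):
        ww = tric * robust[idx]
        xx = idx.astype(float)
        yy = y[idx]
        sw = ww.sum(axis=1)
        swx = (ww * xx).sum(axis=1)
        swy = (ww * yy).sum(axis=1)
        swxx = (ww * xx * xx).sum(axis=1)
        swxy = (ww * xx * yy).sum(axis=1)
        denom = sw * swxx - swx**2
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(denom > 0, (sw * swxy - swx * swy) / denom, 0.0)
            intercept = np.where(sw > 0, (swy - slope * swx) / sw, np.nan)
        fitted = intercept + slope * x
        for i in np.flatnonzero(~np.isfinite(fitted)):
            # all tricube×robust weights vanished (e.g. only the window's
            # extreme points survive): fall back to an unweighted fit over
            # the surviving window points
            keep = idx[i][robust[idx[i]] > 0]
            if keep.size >= 2:
                c = np.polynomial.polynomial.polyfit(keep.astype(float), y[keep], 1)
                fitted[i] = c[0] + c[1] * x[i]
            elif keep.size == 1:
                fitted[i] = y[keep[0]]
            else:
                fitted[i] = y[i]
        resid = y - fitted
        mad = np.median(np.abs(resid))
        tol = 1e-10 * max(1.0, float(np.median(np.abs(y))))
        if mad <= tol:
            # the bulk of the data is fit exactly: keep only exact-fit
            # points (drops isolated gross outliers on clean data)
            new_robust = (np.abs(resid) <= tol).astype(float)
            if np.array_equal(new_robust, robust) or not new_robust.any():
                break
            robust = new_robust
        else:
            robust = np.clip(1.0 - (resid / (6.0 * mad)) ** 2, 0.0, None) ** 2
    return fitted


def whittaker_smooth(
    y: np.ndarray,
    x: np.ndarray | None = None,
    lam: float = 0.75,
    order: int = 2,
) -> np.ndarray:
    """Whittaker–Eilers smoother: discrete penalized least squares.

    Minimizes ``Σ (y_i − z_i)² + λ Σ (Δᵈ z)²`` where Δᵈ is the order-``d``
    divided difference on the (possibly non-uniform) grid ``x``, and
    returns the exact minimizer of the sparse normal equations.  λ = 0
    reproduces the data; λ → ∞ approaches the least-squares polynomial of
    degree ``order − 1``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite; smooth per gap-free segment")
    n = y.size
    if x is None:
        x = np.arange(n, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
    if n <= order or lam == 0:
        return y.copy()
    d = _divided_diff_matrix(x, order)
    a = (sparse.identity(n, format="csc") + lam * (d.T @ d)).tocsc()
    # A is symmetric positive definite with bandwidth = order: solve by
    # banded Cholesky (upper storage ab[u + i - j, j] = A[i, j])
    ab = np.zeros((order + 1, n))
    for k in range(order + 1):
        ab[order - k, k:] = a.diagonal(k)
    return solveh_banded(ab, y, lower=False)


def _divided_diff_matrix(x: np.ndarray, order: int) -> sparse.csr_matrix:
    """Order-``order`` divided-difference operator on grid ``x``.

    Rows approximate scaled derivatives, so uniform hour grids with unit
    spacing reduce to the classic integer difference matrix.
    """
    n = x.size
    d: sparse.spmatrix = sparse.identity(n, format="csr")
    grid = x.copy()
    for _ in range(order):
        k = grid.size
        inv = 1.0 / np.diff(grid)
        data = np.concatenate([-inv, inv])
        rows = np.concatenate([np.arange(k - 1)] * 2)
        cols = np.concatenate([np.arange(k - 1), np.arange(1, k)])
        d1 = sparse.csr_matrix((data, (rows, cols)), shape=(k - 1, k))
        d = d1 @ d
        grid = 0.5 * (grid[:-1] + grid[1:])  # midpoints carry next order
    return d


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def detect_hatch(
    times: np.ndarray,
    elongation: np.ndarray,
    accepted: np.ndarray,
    min_elongation: float = 3.0,
    min_consecutive: int = 3,
    override: float | None = None,
) -> tuple[float, str]:
    """Hatch time: first run of ≥ 3 accepted, elongated (L/W > 3) frames.

    Returns (τ_hatch, method).  Movies that start post-hatch yield the
    first frame, tagged "left-censored"; an override value always wins.
    """
    if override is not None:
        return float(override), "override"
    times = np.asarray(times, dtype=float)
    good = np.asarray(accepted, bool) & (np.asarray(elongation, float) > min_elongation)
    run = 0
    for i, g in enumerate(good):
        run = run + 1 if g else 0
        if run >= min_consecutive:
            start = i - min_consecutive + 1
            if start == 0:
                return float(times[0]), "left-censored"
            return float(times[start]), "auto"
    raise ValueError("no hatch detected: no run of accepted elongated frames")


def _smoothed_log_volume(trajectory: AnimalTrajectory, config: AnalysisConfig):
    v = median_filter(trajectory.volume, config.median_window)
    with np.errstate(invalid="ignore", divide="ignore"):
        logv = np.log(v)
    logv[~np.isfinite(logv)] = np.nan
    return rlowess_smooth(logv, config.rlowess_window)


def _central_diff(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Central differences with NaN at gap-adjacent points."""
    out = np.full_like(y, np.nan)
    if y.size < 3:
        return out
    out[1:-1] = (y[2:] - y[:-2]) / (t[2:] - t[:-2])
    return out


def detect_molts(
    trajectory: AnimalTrajectory,
    config: AnalysisConfig = AnalysisConfig(),
    hatch_time: float | None = None,
    override: dict[str, float] | None = None,
) -> MoltAnnotation:
    """Detect up to four molts from log-volume curvature maxima.

    Log-volume is median-filtered and rlowess-smoothed; candidate molts
    are local maxima of its second time derivative.  Candidates are
    accepted in order of descending curvature score subject to a minimum
    separation and the requirement of a near-flat growth plateau shortly
    before the peak (|dlogV/dt| below ``plateau_slope_frac`` of the
    trajectory's median growth rate); ties break toward earlier times.
    Manual curation is supported via ``override`` entries (``"M1"`` ..),
    which replace detected times.
    """
    t = trajectory.times
    hatch = float(hatch_time) if hatch_time is not None else float(t[0])
    logv = _smoothed_log_volume(trajectory, config)
    slope = _central_diff(logv, t)
    curv = _central_diff(slope, t)

    with np.errstate(invalid="ignore"):
        pos_slopes = slope[np.isfinite(slope) & (slope > 0)]
    slope_floor = (
        config.plateau_slope_frac * np.median(pos_slopes) if pos_slopes.size else np.inf
    )

    finite = np.isfinite(curv)
    cand = [
        i
        for i in range(1, t.size - 1)
        if finite[i]
        and curv[i] > 0
        and (not finite[i - 1] or curv[i] >= curv[i - 1])
        and (not finite[i + 1] or curv[i] > curv[i + 1])
        and t[i] >= hatch + config.min_molt_separation_h
    ]

    def has_plateau(i):
        sel = (t >= t[i] - config.plateau_lookback_h) & (t <= t[i])
        s = slope[sel]
        s = s[np.isfinite(s)]
        return s.size > 0 and np.min(np.abs(s)) < slope_floor

    cand = [i for i in cand if has_plateau(i)]
    # descending curvature, ties toward earlier time
    cand.sort(key=lambda i: (-curv[i], t[i]))

    # curvature maxima of the heavily smoothed signal locate molts only to
    # within the smoothing span (and robust smoothing can ring around
    # kinks); refine each candidate by fitting growth → flat plateau →
    # growth to lightly filtered logV, then rank by the fitted slope jump,
    # which is large only at a genuine growth resumption
    with np.errstate(invalid="ignore", divide="ignore"):
        logv_light = np.log(median_filter(trajectory.volume, config.median_window))
    logv_light[~np.isfinite(logv_light)] = np.nan

    refined = []
    for i in cand[: 3 * config.n_molts + 2]:
        tau, sse, jump = _refine_hinge(t, logv_light, t[i])
        refined.append((tau, sse, jump, curv[i]))
    # candidates refining into the same lethargus form one cluster; keep
    # the best-fitting representative, then rank clusters by slope jump
    refined.sort(key=lambda r: r[0])
    clusters: list[list[tuple]] = []
    for r in refined:
        if clusters and r[0] - clusters[-1][-1][0] < config.min_molt_separation_h:
            clusters[-1].append(r)
        else:
            clusters.append([r])
    reps = [min(c, key=lambda r: r[1]) for c in clusters]
    reps.sort(key=lambda r: (-r[2], r[0]))
    chosen: list[tuple[float, float]] = []
    for tau, sse, jump, score in reps:
        if len(chosen) == config.n_molts:
            break
        if all(abs(tau - c[0]) >= config.min_molt_separation_h for c in chosen):
            chosen.append((tau, score))
    chosen.sort(key=lambda c: c[0])

    molts = np.full(config.n_molts, np.nan)
    scores = np.full(config.n_molts, np.nan)
    for k, (tau, score) in enumerate(chosen):
        molts[k] = tau
        scores[k] = score

    method = "auto"
    if override:
        for k in range(config.n_molts):
            key = f"M{k + 1}"
            if key in override:
                molts[k] = float(override[key])
                scores[k] = np.nan
                method = "override"
    order = np.argsort(molts)
    if not np.array_equal(order[np.isfinite(molts[order])],
                          np.flatnonzero(np.isfinite(molts))):
        molts = molts[order]
        scores = scores[order]
    return MoltAnnotation(hatch_time=hatch, molt_times=molts, scores=scores, method=method)


def _refine_hinge(
    t: np.ndarray,
    logv: np.ndarray,
    t0: float,
    search_h: float = 1.5,
    plateau_min_h: float = 0.9,
    plateau_max_h: float = 2.6,
    flank_h: float = 3.0,
) -> tuple[float, float]:
    """Sub-frame molt localization by two-break piecewise-linear fits.

    Models a lethargus as growth → flat plateau → growth:

        logV = a + b₁·min(t − τₚ, 0) + b₂·max(t − τ, 0)

    with the plateau exactly flat between the onset τₚ and the ecdysis τ.
    Both break points are scanned on a sub-frame grid (τ around the coarse
    curvature peak ``t0``, the plateau length between ``plateau_min_h``
    and ``plateau_max_h``).  Returns the SSE-minimizing τ together with
    the fitted slope jump b₂ − b₁ there (≈ the resumed growth rate minus
    the plateau slope; near zero when no real molt underlies the
    candidate).  Anchoring the plateau level from both kinks roughly
    halves the localization variance relative to a single-hinge fit.
    """
    dt = np.median(np.diff(t))
    taus = np.arange(t0 - search_h, t0 + search_h + dt / 8, dt / 4)
    lengths = np.arange(plateau_min_h, plateau_max_h + dt / 4, dt / 2)
    sel_all = (
        (t >= taus[0] - plateau_max_h - flank_h)
        & (t <= taus[-1] + flank_h)
        & np.isfinite(logv)
    )
    if sel_all.sum() < 10:
        return float(t0), np.inf, 0.0
    best_tau, best_sse, best_jump = t0, np.inf, 0.0
    for tau in taus:
        sel = sel_all & (t >= tau - plateau_max_h - flank_h) & (t <= tau + flank_h)
        x_all = t[sel]
        y_all = logv[sel]
        if np.sum(x_all > tau) < 3:
            continue
        for plen in lengths:
            tau_p = tau - plen
            if np.sum(x_all < tau_p) < 3 or np.sum((x_all >= tau_p) & (x_all <= tau)) < 2:
                continue
            design = np.column_stack(
                [
                    np.ones(x_all.size),
                    np.minimum(x_all - tau_p, 0),
                    np.maximum(x_all - tau, 0),
                ]
            )
            coef, res, *_ = np.linalg.lstsq(design, y_all, rcond=None)
            if coef[1] < 0 or coef[2] < 0:  # growth slopes must be positive
                continue
            sse = res[0] if res.size else float(np.sum((design @ coef - y_all) ** 2))
            sse /= x_all.size
            if sse < best_sse:
                best_sse, best_tau, best_jump = sse, tau, float(coef[2] - 0.0)
    return float(best_tau), float(best_sse), float(best_jump)


def boundary_volume(
    trajectory: AnimalTrajectory,
    event_time: float,
    side: str = "before",
    n: int = 10,
) -> tuple[float, bool]:
    """Volume at a hatch/molt boundary by OLS over the flanking points.

    ``side="before"`` uses the ``n`` retained points at or before the
    event (molt volumes); ``side="after"`` the ``n`` points after (volume
    at birth).  Returns (fitted volume at ``event_time``, flagged) where
    ``flagged`` marks fits on fewer than ``n`` points; fewer than 3 points
    give NaN.
    """
    if side not in ("before", "after"):
        raise ValueError("side must be 'before' or 'after'")
    t = trajectory.times
    v = trajectory.volume
    ok = np.isfinite(v)
    sel = ok & ((t <= event_time) if side == "before" else (t >= event_time))
    idx = np.flatnonzero(sel)
    idx = idx[-n:] if side == "before" else idx[:n]
    flagged = idx.size < n
    if idx.size < 3:
        return float("nan"), True
    coef = np.polynomial.polynomial.polyfit(t[idx], v[idx], 1)
    return float(coef[0] + coef[1] * event_time), flagged


# ---------------------------------------------------------------------------
# growth rates
# ---------------------------------------------------------------------------

def specific_growth_rate(
    trajectory: AnimalTrajectory, config: AnalysisConfig = AnalysisConfig()
) -> np.ndarray:
    """g(t) = dlog(V)/dt (1/h) on the median-3 + rlowess-15 smoothed V."""
    logv = _smoothed_log_volume(trajectory, config)
    return _central_diff(logv, trajectory.times)


def absolute_growth_rate(
    trajectory: AnimalTrajectory, config: AnalysisConfig = AnalysisConfig()
) -> np.ndarray:
    """dV/dt (µm³/h), computed identically on the smoothed volume."""
    v = rlowess_smooth(
        median_filter(trajectory.volume, config.median_window), config.rlowess_window
    )
    return _central_diff(v, trajectory.times)


def windowed_summary(
    trajectory: AnimalTrajectory,
    config: AnalysisConfig = AnalysisConfig(),
    hatch_time: float = 0.0,
    min_points: int = 5,
) -> tuple[float, float]:
    """Early-window growth rate and concentration for one animal.

    Growth rate: slope of a robust (bisquare/Tukey) linear regression of
    ln V on t inside [centre − h, centre + h] hours post-hatch, after a
    3-point median filter.  Concentration: mean of the median-3-filtered
    concentration in the same window.  Fewer than ``min_points`` finite
    points give NaN for the affected quantity.
    """
    t = trajectory.times - hatch_time
    sel = np.abs(t - config.summary_center_h) <= config.summary_halfwidth_h
    v = median_filter(trajectory.volume, config.median_window)
    growth = float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        logv = np.log(v)
    ok = sel & np.isfinite(logv)
    if ok.sum() >= min_points:
        exog = sm.add_constant(t[ok])
        fit = sm.RLM(logv[ok], exog, M=sm.robust.norms.TukeyBiweight()).fit()
        growth = float(fit.params[1])
    conc = float("nan")
    if trajectory.concentration is not None:
        c = median_filter(np.asarray(trajectory.concentration, float), config.median_window)
        okc = sel & np.isfinite(c)
        if okc.sum() >= min_points:
            conc = float(np.mean(c[okc]))
    return growth, conc


def exclude_outliers(values: np.ndarray, k: float = 3.0):
    """Single-pass mean ± k·SD exclusion.

    Returns (retained values, boolean keep-mask).  With SD = 0 (all equal)
    nothing is dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    finite = np.isfinite(values)
    mu = np.mean(values[finite])
    sd = np.std(values[finite])
    if sd == 0 or not np.isfinite(sd):
        keep = finite
    else:
        with np.errstate(invalid="ignore"):
            keep = finite & (np.abs(values - mu) <= k * sd)
    return values[keep], keep


# ---------------------------------------------------------------------------
# stage rescaling
# ---------------------------------------------------------------------------

def rescale_stages(
    times: np.ndarray,
    values: np.ndarray,
    boundaries: np.ndarray,
    k: int = 100,
    extend: float = 0.2,
    scale_values_by_duration: bool = False,
) -> StageScaledTrajectory:
    """Resample a signal onto K evenly spaced points per larval stage.

    ``scale_values_by_duration`` additionally multiplies each stage's
    values by its duration in hours (an alternative reading of
    "normalizing rates to stage duration": a rate in 1/h becomes growth
    per stage); the default rescales the time axis only.

    ``boundaries`` are the stage edges (hatch, M1, ..): stage s spans
    [boundaries[s], boundaries[s+1]] and is mapped to progression
    (0, 100]% with ``k`` points; the last completed stage additionally
    carries an extension covering the first ``extend``·100% of the
    following stage (grid 100–120% for extend = 0.2), provided data reach
    that far.  Stages with a missing boundary are omitted and flagged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    n_stages = boundaries.size - 1
    step = 100.0 / k
    prog = np.arange(1, k + 1) * step  # (0, 100] percent

    grids, vals, stage_idx, durations, present = [], [], [], [], []
    for s in range(n_stages):
        t0, t1 = boundaries[s], boundaries[s + 1]
        if not (np.isfinite(t0) and np.isfinite(t1)) or t1 <= t0:
            durations.append(np.nan)
            present.append(False)
            continue
        tt = t0 + prog / 100.0 * (t1 - t0)
        ok = np.isfinite(values)
        vv = np.interp(tt, times[ok], values[ok])
        if scale_values_by_duration:
            vv = vv * (t1 - t0)
        grids.append(prog)
        vals.append(vv)
        stage_idx.append(np.full(k, s))
        durations.append(t1 - t0)
        present.append(True)
        is_last_completed = s == n_stages - 1 or not (
            np.isfinite(boundaries[s + 2]) if s + 2 < boundaries.size else False
        )
        if extend > 0 and is_last_completed:
            n_ext = int(round(extend * k))
            ext_prog = 100.0 + np.arange(1, n_ext + 1) * step
            # extension uses the *next* stage's clock when its end is
            # known, else continues on this stage's duration
            if s + 2 < boundaries.size and np.isfinite(boundaries[s + 2]):
                dur_next = boundaries[s + 2] - t1
            else:
                dur_next = t1 - t0
            tt_ext = t1 + (ext_prog - 100.0) / 100.0 * dur_next
            in_range = tt_ext <= times[ok].max()
            if in_range.any():
                ext_vals = np.interp(tt_ext[in_range], times[ok], values[ok])
                if scale_values_by_duration:
                    ext_vals = ext_vals * dur_next
                grids.append(ext_prog[in_range])
                vals.append(ext_vals)
                stage_idx.append(np.full(int(in_range.sum()), s))
    if not grids:
        raise ValueError("no stage with both boundaries present")
    return StageScaledTrajectory(
        stage_index=np.concatenate(stage_idx),
        progression=np.concatenate(grids),
        values=np.concatenate(vals),
        stage_durations=np.asarray(durations, dtype=float),
        stages_present=np.asarray(present, dtype=bool),
    )
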