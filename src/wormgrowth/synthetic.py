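"""Ground-truthed synthetic data for the imaging pipeline.

The simulator emulates the statistical structure the downstream analysis
assumes for a single *C. elegans* larva developing in an agarose
microchamber:

* piecewise-exponential volume growth over four larval stages, each ending
  in a growth plateau (lethargus) before cuticular ecdysis;
* a per-pixel fluorescence concentration that relaxes exponentially from
  its value at hatch ``C0`` toward a plateau ``C_inf`` during L1 (the
  recovery seen in maternally perturbed animals);
* optional coupling of the L1 growth rate to the instantaneous
  concentration, so that growth recovers in step with fluorescence;
* cohorts in which a treated group carries relative offsets in hatch
  volume and initial concentration, mimicking maternal-diet effects;
* rendered chamber movies in which a curved, tapered tube is drawn so that
  its rotational-symmetry volume equals the true volume exactly, giving an
  analytic oracle for the volumetry code;
* deliberately corrupted masks (truncation, merged blobs, mid-body bulges,
  fragmentation) for training the frame-QC classifier.

All randomness is driven by explicit integer seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

__all__ = [
    "SimParams",
    "SimGroundTruth",
    "CohortSpec",
    "ChamberMovie",
    "QcTrainingSet",
    "simulate_trajectory",
    "render_movie",
    "render_worm_frame",
    "simulate_cohort",
    "make_qc_training_set",
    "CORRUPTION_CLASSES",
]

STAGE_NAMES = ("L1", "L2", "L3", "L4")


@dataclass(frozen=True)
class SimParams:
    """Parameters of a single simulated animal.

    Defaults describe a well-fed control animal at standard growth
    conditions: ~30,000 µm³ at hatch, stage-specific growth rates rising
    from 0.10 to 0.16 h⁻¹, stage durations of 12/8/8/10 h with a 1.5 h
    lethargus plateau before each molt, and fluorescence already at its
    plateau (no recovery).  Frames are 10 min apart.
    """

    hatch_volume: float = 3.0e4  # µm³
    stage_growth_rates: tuple[float, ...] = (0.10, 0.12, 0.14, 0.16)  # 1/h
    stage_durations: tuple[float, ...] = (12.0, 8.0, 8.0, 10.0)  # h
    plateau_duration: float = 1.5  # h of zero growth before each ecdysis
    conc_initial: float = 100.0  # C0, per-pixel fluorescence (a.u.)
    conc_plateau: float = 100.0  # C_inf
    conc_recovery_rate: float = 0.25  # k, 1/h
    coupling: bool = False  # L1 growth rate tracks C(t)/C_inf
    noise_sd_logV: float = 0.02  # SD of multiplicative volume noise
    noise_sd_conc: float = 2.0  # SD of additive concentration noise (a.u.)
    frame_interval: float = 1.0 / 6.0  # h
    pre_hatch: float = 0.0  # h of egg frames before hatch
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [
            self.hatch_volume,
            *self.stage_growth_rates,
            *self.stage_durations,
            self.plateau_duration,
            self.conc_initial,
            self.conc_plateau,
            self.conc_recovery_rate,
            self.noise_sd_logV,
            self.noise_sd_conc,
            self.frame_interval,
            self.pre_hatch,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("SimParams contains non-finite values")
        if len(self.stage_growth_rates) != len(self.stage_durations):
            raise ValueError("need one growth rate per stage")
        if any(g < 0 for g in self.stage_growth_rates):
            raise ValueError("growth rates must be >= 0")
        if any(d <= 0 for d in self.stage_durations):
            raise ValueError("stage durations must be > 0")
        if self.plateau_duration < 0:
            raise ValueError("plateau duration must be >= 0")
        if any(self.plateau_duration >= d for d in self.stage_durations):
            raise ValueError("plateau must be shorter than every stage")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")
        if self.hatch_volume <= 0:
            raise ValueError("hatch volume must be > 0")
        if min(self.conc_initial, self.conc_plateau) < 0:
            raise ValueError("concentrations must be >= 0")
        if self.conc_recovery_rate < 0 or self.noise_sd_logV < 0 or self.noise_sd_conc < 0:
            raise ValueError("rates and noise SDs must be >= 0")
        if self.pre_hatch < 0:
            raise ValueError("pre-hatch duration must be >= 0")

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


@dataclass
class SimGroundTruth:
    """Noise-free truth plus noisy observations for one simulated animal.

    Times are hours since the start of the movie; ``hatch_time`` marks the
    hatch (0 unless ``pre_hatch`` > 0).  ``volume``/``concentration`` are
    the noiseless signals, ``observed_*`` carry the measurement noise the
    analysis sees.  Pre-hatch frames hold the egg volume and ``C0``.
    """

    params: SimParams
    times: np.ndarray  # h since movie start
    volume: np.ndarray  # true V(t), µm³
    concentration: np.ndarray  # true C(t), a.u. per pixel
    observed_volume: np.ndarray
    observed_concentration: np.ndarray
    stage: np.ndarray  # per-frame labels: egg/L1..L4/adult
    hatch_time: float
    molt_times: np.ndarray  # τ_M1..τ_M4 (h since movie start)

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with maternal-effect offsets on the treated group.

    Default offsets mirror a maternal dietary-restriction effect: treated
    animals hatch with 13% less volume and 11% lower initial fluorescence
    concentration than controls, then recover during L1.
    """

    n_animals: int = 12
    group_labels: tuple[str, str] = ("control", "treated")
    offset_hatch_volume: float = -0.13  # relative, treated vs control
    offset_conc_initial: float = -0.11
    base: SimParams = field(default_factory=SimParams)
    jitter_cv: float = 0.05  # lognormal CV on rates/durations/volumes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need at least one animal per group")
        if not (-1 < self.offset_hatch_volume and -1 < self.offset_conc_initial):
            raise ValueError("relative offsets must be > -1")
        if self.jitter_cv < 0:
            raise ValueError("jitter CV must be >= 0")


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _log_volume_since_hatch(u: np.ndarray, p: SimParams) -> np.ndarray:
    """Integrated log-volume at times ``u`` (hours since hatch), noiseless.

    Within each stage the specific growth rate is constant (``g_s``) except
    during the terminal plateau, where it is zero.  With coupling on, the
    L1 rate is g_L1 · C(u)/C_inf, integrated in closed form.
    """
    u = np.asarray(u, dtype=float)
    logv = np.full(u.shape, np.log(p.hatch_volume))
    stage_starts = np.concatenate([[0.0], np.cumsum(p.stage_durations)])
    log_at_start = np.log(p.hatch_volume)
    for s, (g, dur) in enumerate(zip(p.stage_growth_rates, p.stage_durations)):
        t0 = stage_starts[s]
        grow = dur - p.plateau_duration
        tau = np.clip(u - t0, 0.0, grow)  # time spent growing in this stage
        if s == 0 and p.coupling:
            gain = _coupled_l1_integral(t0 + tau, p) - _coupled_l1_integral(t0, p)
        else:
            gain = g * tau
        logv = np.where(u > t0, log_at_start + gain, logv)
        if s == 0 and p.coupling:
            stage_gain = _coupled_l1_integral(t0 + grow, p) - _coupled_l1_integral(t0, p)
        else:
            stage_gain = g * grow
        log_at_start += stage_gain
    # young adults keep growing after the final ecdysis; continue at the
    # last larval rate so the M4 transition shows the same slope resumption
    # as the earlier molts
    t_adult = stage_starts[-1]
    adult = u > t_adult
    if np.any(adult):
        logv[adult] = log_at_start + p.stage_growth_rates[-1] * (u[adult] - t_adult)
    return logv


def _coupled_l1_integral(t: np.ndarray, p: SimParams) -> np.ndarray:
    """∫₀ᵗ g₁·C(v)/C_inf dv with C(v) = C_inf − (C_inf − C0)·e^{−kv}."""
    g = p.stage_growth_rates[0]
    if p.conc_plateau == 0:
        return g * np.asarray(t, dtype=float)
    frac = 1.0 - p.conc_initial / p.conc_plateau
    k = p.conc_recovery_rate
    t = np.asarray(t, dtype=float)
    if k == 0:
        return g * (1.0 - frac) * t
    return g * (t + frac / k * (np.exp(-k * t) - 1.0))


def concentration_curve(u: np.ndarray, p: SimParams) -> np.ndarray:
    """C(u) = C_inf − (C_inf − C0)·exp(−k·u), for u hours since hatch."""
    u = np.asarray(u, dtype=float)
    return p.conc_plateau - (p.conc_plateau - p.conc_initial) * np.exp(
        -p.conc_recovery_rate * np.maximum(u, 0.0)
    )


def simulate_trajectory(params: SimParams) -> SimGroundTruth:
    """Simulate one animal's volume and concentration trajectory.

    Molt times are recorded exactly (stage boundaries); the reported
    (observed) signals carry multiplicative lognormal volume noise and
    additive Gaussian concentration noise, while the true signals stay
    noise-free.
    """
    p = params
    total = p.pre_hatch + float(np.sum(p.stage_durations)) + 2.0  # 2 h of adult tail
    n = int(np.floor(total / p.frame_interval)) + 1
    times = np.arange(n) * p.frame_interval
    u = times - p.pre_hatch  # hours since hatch

    volume = np.exp(_log_volume_since_hatch(np.maximum(u, 0.0), p))
    conc = concentration_curve(u, p)
    conc[u < 0] = p.conc_initial

    molt_times = p.pre_hatch + np.cumsum(p.stage_durations)
    stage = np.empty(n, dtype=object)
    stage[:] = "adult"
    bounds = np.concatenate([[p.pre_hatch], molt_times])
    for s, name in enumerate(STAGE_NAMES[: len(p.stage_durations)]):
        stage[(times >= bounds[s]) & (times < bounds[s + 1])] = name
    stage[u < 0] = "egg"

    rng = np.random.default_rng(p.seed)
    obs_v = volume * np.exp(rng.normal(0.0, p.noise_sd_logV, size=n))
    obs_c = conc + rng.normal(0.0, p.noise_sd_conc, size=n)

    return SimGroundTruth(
        params=p,
        times=times,
        volume=volume,
        concentration=conc,
        observed_volume=obs_v,
        observed_concentration=obs_c,
        stage=stage.astype(str),
        hatch_time=p.pre_hatch,
        molt_times=np.asarray(molt_times, dtype=float),
    )


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

@dataclass
class ChamberMovie:
    """A rendered single-chamber movie with per-frame ground truth."""

    frames: np.ndarray  # (T, H, W) float32 intensities
    masks: np.ndarray  # (T, H, W) bool true masks
    analytic_volumes: np.ndarray  # µm³, drawn-shape volume per frame
    pixel_size_um: float
    frame_interval_h: float
    times: np.ndarray  # h since movie start
    hatch_frame: int | None
    seed: int


def _tapered_radius_profile(n_rows: int, taper_frac: float = 0.10) -> np.ndarray:
    """Unit radius profile: 1 in the body, cosine-tapered over each tip."""
    s = np.arange(n_rows, dtype=float)
    prof = np.ones(n_rows)
    n_tip = max(2, int(round(taper_frac * n_rows)))
    ramp = np.sin(0.5 * np.pi * (s[:n_tip] + 0.5) / n_tip)
    prof[:n_tip] = ramp
    prof[-n_tip:] = ramp[::-1]
    return prof


def worm_geometry(volume_um3: float, pixel_size_um: float, aspect: float = 10.0):
    """Length (px) and unit-profile scale for a worm of given volume.

    The worm is a tube of aspect ratio ``aspect`` = length / diameter.  The
    radius profile is cosine-tapered over 10% of the length at each tip and
    scaled so the rotational-symmetry volume of the drawn shape equals
    ``volume_um3`` exactly.
    """
    v_px = volume_um3 / pixel_size_um**3
    # nominal cylinder: V = π r² L, a = L / (2 r)  =>  L = (4 a² V / π)^{1/3}
    length = (4.0 * aspect**2 * v_px / np.pi) ** (1.0 / 3.0)
    n_rows = max(8, int(round(length)))
    prof = _tapered_radius_profile(n_rows)
    r_max = np.sqrt(v_px / (np.pi * np.sum(prof**2)))  # Δs = 1 px
    return n_rows, r_max * prof


def _random_midline(
    rng: np.random.Generator,
    length_px: int,
    shape: tuple[int, int],
    margin: float,
    max_tries: int = 25,
) -> np.ndarray:
    """Smooth random midline of given arc length fitting inside the frame.

    The heading is a sum of two low-frequency sinusoids with bounded
    amplitude, giving gentle, curvature-bounded bends; the curve is
    recentred in the frame and retried with shrinking amplitude until it
    fits with the requested margin.
    """
    h, w = shape
    s = np.arange(length_px, dtype=float)
    for trial in range(max_tries):
        shrink = 0.75**trial
        theta0 = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.2, 0.9, size=2) * shrink
        freq = rng.uniform(0.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        theta = theta0 + sum(
            a * np.sin(2 * np.pi * f * s / length_px + ph)
            for a, f, ph in zip(amp, freq, phase)
        )
        pts = np.cumsum(np.stack([np.sin(theta), np.cos(theta)], axis=1), axis=0)
        pts -= (pts.max(axis=0) + pts.min(axis=0)) / 2.0
        pts += np.array([h / 2.0, w / 2.0])
        ext = pts.max(axis=0) - pts.min(axis=0)
        if (
            pts[:, 0].min() >= margin
            and pts[:, 1].min() >= margin
            and pts[:, 0].max() <= h - 1 - margin
            and pts[:, 1].max() <= w - 1 - margin
            and max(ext) > 0
        ):
            return pts
    raise ValueError(
        f"worm of length {length_px} px does not fit in frame {shape} "
        f"with margin {margin:.1f} px"
    )


def _rasterize_tube(
    midline: np.ndarray,
    radii: np.ndarray,
    shape: tuple[int, int],
):
    """Rasterize a tube around ``midline`` with per-row radius ``radii``.

    Returns the boolean mask and a unit intensity-profile image: flat (1)
    inside the tube, 0 outside.  A flat interior makes the per-pixel
    concentration of the drawn animal equal ``C`` exactly and gives a step
    edge whose blurred gradient ridge coincides with the true boundary,
    mimicking the fairly uniform cytoplasmic signal of tagged worms.
    """
    h, w = shape
    r_max = float(radii.max())
    lo = np.maximum(np.floor(midline.min(axis=0) - r_max - 2).astype(int), 0)
    hi = np.minimum(np.ceil(midline.max(axis=0) + r_max + 3).astype(int), [h, w])
    yy, xx = np.mgrid[lo[0]: hi[0], lo[1]: hi[1]]
    pix = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    tree = cKDTree(midline)
    dist, idx = tree.query(pix, k=1)
    r_here = radii[idx]
    inside = dist <= r_here
    thick = inside.astype(float)
    mask = np.zeros(shape, dtype=bool)
    thickness = np.zeros(shape, dtype=float)
    mask[lo[0]: hi[0], lo[1]: hi[1]] = inside.reshape(yy.shape)
    thickness[lo[0]: hi[0], lo[1]: hi[1]] = thick.reshape(yy.shape)
    return mask, thickness


def render_worm_frame(
    volume_um3: float,
    conc: float,
    shape: tuple[int, int],
    pixel_size_um: float,
    background_level: float,
    noise_sd: float,
    rng: np.random.Generator,
    aspect: float = 10.0,
    blur_sigma: float = 1.0,
):
    """Render one frame; returns (image, true mask, midline)."""
    n_rows, radii = worm_geometry(volume_um3, pixel_size_um, aspect)
    midline = _random_midline(rng, n_rows, shape, margin=float(radii.max()) + 3)
    mask, thickness = _rasterize_tube(midline, radii, shape)
    img = background_level + conc * thickness
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32), mask, midline


def render_cylinder(
    radius_px: float,
    length_px: int,
    shape: tuple[int, int] = (160, 220),
    offset: tuple[float, float] = (0.37, 0.18),
    intensity: float = 100.0,
    background_level: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned flat-ended cylinder fixture for the volumetry oracle.

    The tube axis runs horizontally at a sub-pixel row offset; the mask
    covers pixels whose centre lies within ``radius_px`` of the axis over
    ``length_px`` columns, so the analytic rotational-symmetry volume is
    π r² L (in px³).  Returns (image, mask).
    """
    h, w = shape
    y0 = h / 2.0 + offset[0]
    x0 = (w - length_px) / 2.0 + offset[1]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (np.abs(yy - y0) <= radius_px) & (xx >= x0) & (xx < x0 + length_px)
    img = background_level + intensity * mask.astype(float)
    return img.astype(np.float32), mask


def _render_egg_frame(
    conc: float,
    shape: tuple[int, int],
    pixel_size_um: float,
    background_level: float,
    noise_sd: float,
    rng: np.random.Generator,
    blur_sigma: float = 1.0,
):
    """Eggs are drawn as small ellipses (~50 × 30 µm) near the frame centre."""
    h, w = shape
    a = 25.0 / pixel_size_um
    b = 15.0 / pixel_size_um
    cy = h / 2.0 + rng.uniform(-5, 5)
    cx = w / 2.0 + rng.uniform(-5, 5)
    ang = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dy * np.cos(ang) + dx * np.sin(ang)
    v = -dy * np.sin(ang) + dx * np.cos(ang)
    rad2 = (u / a) ** 2 + (v / b) ** 2
    mask = rad2 <= 1.0
    img = background_level + conc * mask.astype(float)
    if blur_sigma > 0:
        img = gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32), mask


def render_movie(
    truth: SimGroundTruth,
    image_shape: tuple[int, int] = (160, 160),
    pixel_size_um: float = 2.5,
    background_level: float = 20.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    aspect: float = 10.0,
    blur_sigma: float = 1.0,
    frame_slice: slice | None = None,
) -> ChamberMovie:
    """Render a simulated animal into a chamber movie with true masks.

    Each frame draws a fresh random pose; the drawn shape's analytic
    rotational-symmetry volume equals ``truth.volume`` at that frame
    exactly, independent of the pose.  ``frame_slice`` restricts rendering
    to a time window (e.g. the L1 stage) without altering the truth.
    """
    sel = np.arange(truth.n_frames) if frame_slice is None else np.arange(truth.n_frames)[frame_slice]
    rng = np.random.default_rng(seed)
    frames = np.empty((sel.size, *image_shape), dtype=np.float32)
    masks = np.zeros((sel.size, *image_shape), dtype=bool)
    hatch_frame = None
    for j, i in enumerate(sel):
        # one child generator per frame keeps pose streams independent of
        # whether earlier frames were rendered
        frame_rng = np.random.default_rng(np.random.SeedSequence([seed, int(i)]))
        if truth.times[i] < truth.hatch_time:
            frames[j], masks[j] = _render_egg_frame(
                truth.concentration[i], image_shape, pixel_size_um,
                background_level, noise_sd, frame_rng, blur_sigma,
            )
        else:
            if hatch_frame is None:
                hatch_frame = j
            frames[j], masks[j], _ = render_worm_frame(
                truth.volume[i], truth.concentration[i], image_shape,
                pixel_size_um, background_level, noise_sd, frame_rng,
                aspect, blur_sigma,
            )
    return ChamberMovie(
        frames=frames,
        masks=masks,
        analytic_volumes=truth.volume[sel].copy(),
        pixel_size_um=pixel_size_um,
        frame_interval_h=truth.params.frame_interval,
        times=truth.times[sel].copy(),
        hatch_frame=hatch_frame,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _jitter_params(
    base: SimParams, rng: np.random.Generator, cv: float, noise_seed: int
) -> SimParams:
    """Per-animal lognormal jitter (CV ``cv``) on rates, durations, volume."""
    sigma = np.sqrt(np.log(1.0 + cv**2))

    def factor(size=None):
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))

    n = len(base.stage_growth_rates)
    return base.replace(
        hatch_volume=base.hatch_volume * factor(),
        stage_growth_rates=tuple(base.stage_growth_rates * factor(n)),
        stage_durations=tuple(base.stage_durations * factor(n)),
        conc_initial=base.conc_initial * factor(),
        seed=noise_seed,
    )


def simulate_cohort(spec: CohortSpec) -> dict[str, list[SimGroundTruth]]:
    """Simulate a control and a treated group with known offsets.

    Per-animal jitter uses one stream per animal index, shared between the
    groups, so that with zero offsets the two groups are exchangeable; the
    treated group's hatch volume and initial concentration are then scaled
    by ``1 + offset``.  Measurement-noise seeds differ between groups.
    """
    out: dict[str, list[SimGroundTruth]] = {}
    for gi, label in enumerate(spec.group_labels):
        animals = []
        for ai in range(spec.n_animals):
            jit_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, ai, 7]))
            noise_seed = int(
                np.random.SeedSequence([spec.seed, gi, ai, 11]).generate_state(1)[0]
                % (2**31)
            )
            p = _jitter_params(spec.base, jit_rng, spec.jitter_cv, noise_seed)
            if gi == 1:
                p = p.replace(
                    hatch_volume=p.hatch_volume * (1.0 + spec.offset_hatch_volume),
                    conc_initial=p.conc_initial * (1.0 + spec.offset_conc_initial),
                )
            animals.append(simulate_trajectory(p))
        out[label] = animals
    return out


# ---------------------------------------------------------------------------
# QC training data
# ---------------------------------------------------------------------------

CORRUPTION_CLASSES = ("truncated", "blob_merge", "coil_bulge", "fragmented")


@dataclass
class QcTrainingSet:
    """Labelled masks for QC-classifier training (1 = faulty)."""

    masks: list[np.ndarray]
    labels: np.ndarray  # 0 good / 1 faulty
    classes: list[str]  # "good" or a corruption class name
    seed: int


def _base_worm_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    volume_um3: float,
    pixel_size_um: float,
    margin_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_rows, radii = worm_geometry(volume_um3, pixel_size_um)
    midline = _random_midline(
        rng, n_rows, shape, margin=(float(radii.max()) + 3) * margin_scale
    )
    mask, _ = _rasterize_tube(midline, radii, shape)
    return mask, midline, radii


def make_qc_training_set(
    n_good: int,
    n_faulty: int,
    seed: int = 0,
    image_shape: tuple[int, int] = (160, 160),
    pixel_size_um: float = 2.5,
) -> QcTrainingSet:
    """Generate good and corrupted worm masks with exact labels.

    Corruption classes (cycled over the faulty examples):

    * ``truncated`` — the worm is shifted so 15–40% of its length leaves
      the frame; the straightened width profile then ends at full body
      width instead of tapering.
    * ``blob_merge`` — a bright blob artifact merged onto the body.
    * ``coil_bulge`` — a mid-body bulge as produced by a self-overlapping
      coil collapsing into one mask.
    * ``fragmented`` — the mask is split into pieces by erasing a band.
    """
    if n_good < 1 or n_faulty < 1:
        raise ValueError("need at least one example of each class")
    rng = np.random.default_rng(seed)
    masks: list[np.ndarray] = []
    classes: list[str] = []

    def draw_volume():
        return float(rng.uniform(1.8e4, 1.6e5))

    for _ in range(n_good):
        m, _, _ = _base_worm_mask(rng, image_shape, draw_volume(), pixel_size_um)
        masks.append(m)
        classes.append("good")

    for i in range(n_faulty):
        kind = CORRUPTION_CLASSES[i % len(CORRUPTION_CLASSES)]
        vol = draw_volume()
        if kind == "truncated":
            m = _truncate_worm(rng, image_shape, vol, pixel_size_um)
        elif kind == "blob_merge":
            m, midline, radii = _base_worm_mask(rng, image_shape, vol, pixel_size_um)
            m = _merge_blob(rng, m, midline, radii, image_shape)
        elif kind == "coil_bulge":
            m = _bulge_worm(rng, image_shape, vol, pixel_size_um)
        else:
            m, midline, _ = _base_worm_mask(rng, image_shape, vol, pixel_size_um)
            m = _fragment_worm(rng, m, midline)
        masks.append(m)
        classes.append(kind)

    labels = np.array([0] * n_good + [1] * n_faulty, dtype=int)
    return QcTrainingSet(masks=masks, labels=labels, classes=classes, seed=seed)


def _truncate_worm(rng, shape, vol, pixel_size_um, frac=None):
    """Worm whose tail ``frac`` left the frame, cut flat at the border.

    The tube is rasterized only up to the cut position, rotated so the cut
    face is perpendicular to the frame edge (as when a worm slides out of
    the imaged chamber area), and cropped with the cut on the border: the
    straightened width profile then ends at full body width instead of
    tapering.  Larger ``frac`` (default U(0.15, 0.40)) is more severe.
    """
    from scipy.ndimage import rotate as nd_rotate

    if frac is None:
        frac = rng.uniform(0.15, 0.40)
    pad = shape[0] // 2
    big = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    n_rows, radii = worm_geometry(vol, pixel_size_um)
    midline = _random_midline(rng, n_rows, big, margin=float(radii.max()) + 3)
    n_cut = max(int((1 - frac) * n_rows), 8)
    mask, _ = _rasterize_tube(midline[:n_cut], radii[:n_cut], big)
    # rotate so the tangent at the cut points along +x, then crop with the
    # cut face on the right frame edge
    tangent = midline[n_cut - 1] - midline[max(n_cut - 6, 0)]
    ang = np.degrees(np.arctan2(tangent[0], tangent[1]))
    mask = nd_rotate(mask.astype(np.uint8), ang, reshape=False, order=0).astype(bool)
    centre = np.array([big[0] / 2.0, big[1] / 2.0])
    rel = midline[n_cut - 1] - centre
    rad = np.deg2rad(ang)
    rot = np.array([[np.cos(rad), -np.sin(rad)], [np.sin(rad), np.cos(rad)]])
    cut = centre + rot @ rel
    oy = int(np.clip(cut[0] - shape[0] / 2, 0, big[0] - shape[0]))
    ox = int(np.clip(np.ceil(cut[1]) - shape[1] + 1, 0, big[1] - shape[1]))
    out = mask[oy: oy + shape[0], ox: ox + shape[1]]
    if out.sum() < 50:  # degenerate crop: fall back to a simple half cut
        out = mask[pad: pad + shape[0], pad: pad + shape[1]].copy()
        out[:, shape[1] // 2:] = False
    return out


def truncated_worm_mask(
    seed: int,
    frac: float,
    image_shape: tuple[int, int] = (160, 160),
    volume_um3: float = 8.0e4,
    pixel_size_um: float = 2.5,
) -> np.ndarray:
    """A border-truncated worm mask with a controlled truncation fraction.

    Used to probe how the QC score responds to corruption severity.
    """
    rng = np.random.default_rng(seed)
    return _truncate_worm(rng, image_shape, volume_um3, pixel_size_um, frac=frac)


def _merge_blob(rng, mask, midline, radii, shape):
    r_blob = float(radii.max()) * rng.uniform(1.2, 2.0)
    anchor = midline[rng.integers(len(midline) // 4, 3 * len(midline) // 4)]
    ang = rng.uniform(0, 2 * np.pi)
    cy = anchor[0] + 0.8 * r_blob * np.sin(ang)
    cx = anchor[1] + 0.8 * r_blob * np.cos(ang)
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_blob**2
    return mask | blob


def _bulge_worm(rng, shape, vol, pixel_size_um):
    n_rows, radii = worm_geometry(vol, pixel_size_um)
    centre = rng.uniform(0.35, 0.65) * n_rows
    width = rng.uniform(0.05, 0.12) * n_rows
    bump = 1.0 + 1.2 * np.exp(-0.5 * ((np.arange(n_rows) - centre) / width) ** 2)
    radii = radii * bump
    midline = _random_midline(rng, n_rows, shape, margin=float(radii.max()) + 3)
    mask, _ = _rasterize_tube(midline, radii, shape)
    return mask


def _fragment_worm(rng, mask, midline):
    out = mask.copy()
    n = len(midline)
    for cut in rng.uniform(0.25, 0.75, size=rng.integers(1, 3)):
        c = midline[int(cut * (n - 1))]
        yy, xx = np.mgrid[0: mask.shape[0], 0: mask.shape[1]]
        gap = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= rng.uniform(2.5, 4.0) ** 2
        out[gap] = False
    return out
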