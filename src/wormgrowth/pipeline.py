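"""Configured, seeded, resumable end-to-end runs.

The pipeline chains the package's stages over a cohort of chamber movies:

    simulate → segment → measure → events → cohort

Each stage writes its outputs under the run directory together with a
content hash of everything it depends on (configuration section plus
input files); a rerun with unchanged inputs skips stages whose hash still
matches.  One global seed determines every stochastic choice (simulation,
QC-classifier bagging, bootstrap), so two runs with the same configuration
agree on all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wormgrowth import cohort as cohort_mod
from wormgrowth import io as wio
from wormgrowth import morphometry, segmentation, synthetic, trajectory

__all__ = ["RunConfig", "SimulationSpec", "PipelineError", "validate_config", "run_pipeline"]

log = logging.getLogger("wormgrowth")

STAGES = ("simulate", "segment", "measure", "events", "cohort")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage / animal / frame that caused it."""

    def __init__(self, stage: str, message: str, animal: str = "", frame: int | None = None):
        self.stage = stage
        self.animal = animal
        self.frame = frame
        where = f"stage={stage}" + (f" animal={animal}" if animal else "")
        if frame is not None:
            where += f" frame={frame}"
        super().__init__(f"[{where}] {message}")


@dataclass(frozen=True)
class SimulationSpec:
    """What the simulate stage generates (a two-group cohort of movies)."""

    n_animals: int = 12
    offset_hatch_volume: float = -0.13
    offset_conc_initial: float = -0.11
    conc_recovery_rate: float = 0.25
    coupling: bool = True
    pre_hatch_h: float = 1.0
    render_post_m1_h: float = 4.0
    image_shape: tuple[int, int] = (160, 160)
    background_level: float = 20.0
    noise_sd: float = 2.0
    blur_sigma: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with all defaults resolved."""

    output_dir: str = "wormgrowth_run"
    seed: int = 0
    pixel_size_um: float = 2.5
    frame_interval_h: float = 1.0 / 6.0
    log_level: str = "INFO"
    inputs: tuple[str, ...] | None = None  # movie TIFFs; None => simulate
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    analysis: trajectory.AnalysisConfig = field(default_factory=trajectory.AnalysisConfig)
    n_molts: int = 1  # molts within the rendered window
    n_boot: int = 1000
    qc_train_good: int = 60
    qc_train_faulty: int = 60

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _update_dataclass(cls, base, data: dict, errors: list[str], prefix: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            errors.append(f"unknown key '{prefix}{key}'")
            continue
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    try:
        return dataclasses.replace(base, **kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{prefix[:-1] or 'config'}: {exc}")
        return base


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    All defaults are resolved; unknown keys and invalid values are
    aggregated into a single ``ValueError``.  An empty file yields the
    defaults-only configuration (simulation mode).
    """
    if data is None:
        text = Path(path).read_text() if path is not None else ""
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    errors: list[str] = []
    sim = _update_dataclass(
        SimulationSpec, SimulationSpec(), data.pop("simulation", {}) or {}, errors, "simulation."
    )
    ana = _update_dataclass(
        trajectory.AnalysisConfig,
        trajectory.AnalysisConfig(),
        data.pop("analysis", {}) or {},
        errors,
        "analysis.",
    )
    cfg = _update_dataclass(RunConfig, RunConfig(), data, errors, "")
    cfg = dataclasses.replace(cfg, simulation=sim, analysis=ana)
    if cfg.frame_interval_h <= 0:
        errors.append("frame_interval_h must be > 0")
    if cfg.pixel_size_um <= 0:
        errors.append("pixel_size_um must be > 0")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# hashing / skipping
# ---------------------------------------------------------------------------

def _hash_payload(payload) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _hash_files(paths) -> list[str]:
    out = []
    for p in sorted(str(p) for p in paths):
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
        out.append(f"{Path(p).name}:{h}")
    return out


def _stage_current(stage_dir: Path, payload) -> bool:
    marker = stage_dir / "_hash.json"
    if not marker.exists():
        return False
    return json.loads(marker.read_text()).get("hash") == _hash_payload(payload)


def _mark_stage(stage_dir: Path, payload) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "_hash.json").write_text(json.dumps({"hash": _hash_payload(payload)}))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, run_dir: Path) -> dict:
    sim = config.simulation
    base = synthetic.SimParams(
        conc_recovery_rate=sim.conc_recovery_rate,
        coupling=sim.coupling,
        pre_hatch=sim.pre_hatch_h,
        frame_interval=config.frame_interval_h,
    )
    spec = synthetic.CohortSpec(
        n_animals=sim.n_animals,
        offset_hatch_volume=sim.offset_hatch_volume,
        offset_conc_initial=sim.offset_conc_initial,
        base=base,
        seed=config.seed,
    )
    cohorts = synthetic.simulate_cohort(spec)
    out = run_dir / "movies"
    n_frames = 0
    for gi, (group, animals) in enumerate(cohorts.items()):
        for ai, truth in enumerate(animals):
            animal = f"{group}_{ai:02d}"
            t_end = truth.molt_times[0] + sim.render_post_m1_h
            n = int(np.searchsorted(truth.times, t_end, side="right"))
            render_seed = int(
                np.random.SeedSequence([config.seed, gi, ai, 23]).generate_state(1)[0]
                % (2**31)
            )
            movie = synthetic.render_movie(
                truth,
                image_shape=sim.image_shape,
                pixel_size_um=config.pixel_size_um,
                background_level=sim.background_level,
                noise_sd=sim.noise_sd,
                seed=render_seed,
                blur_sigma=sim.blur_sigma,
                frame_slice=slice(0, n),
            )
            truth_path = out / f"{animal}.truth.csv"
            wio.write_truth(truth_path, truth)
            wio.write_movie(
                out / f"{animal}.tif",
                movie.frames,
                config.pixel_size_um,
                config.frame_interval_h,
                seed=render_seed,
                truth_path=str(truth_path.name),
            )
            n_frames += movie.frames.shape[0]
    return {"animals": 2 * sim.n_animals, "frames": n_frames}


def _movie_paths(config: RunConfig, run_dir: Path) -> list[Path]:
    if config.inputs:
        return [Path(p) for p in config.inputs]
    return sorted((run_dir / "movies").glob("*.tif"))


def _stage_segment(config: RunConfig, run_dir: Path) -> dict:
    qc_seed = int(np.random.SeedSequence([config.seed, 31]).generate_state(1)[0] % (2**31))
    train = synthetic.make_qc_training_set(
        config.qc_train_good,
        config.qc_train_faulty,
        seed=qc_seed,
        pixel_size_um=config.pixel_size_um,
    )
    feats = np.array([segmentation.features_from_mask(m).values for m in train.masks])
    clf = segmentation.train_qc_classifier(feats, train.labels, seed=qc_seed)

    out = run_dir / "segmentation"
    out.mkdir(parents=True, exist_ok=True)
    counts = {"frames": 0, "failed": 0, "qc_fail": 0}
    for movie_path in _movie_paths(config, run_dir):
        frames, _ = wio.read_movie(movie_path)
        masks = np.zeros(frames.shape, dtype=bool)
        rows = []
        for fi, frame in enumerate(frames):
            wm = segmentation.segment_frame(frame.astype(float))
            label, score = "fail", 1.0
            if not wm.failed:
                f = segmentation.features_from_mask(wm.mask, frame.astype(float))
                label, score = segmentation.classify_frame(clf, f)
                masks[fi] = wm.mask
            counts["frames"] += 1
            counts["failed"] += int(wm.failed)
            counts["qc_fail"] += int(label == "fail")
            rows.append(
                {"frame": fi, "qc_label": label, "qc_score": score, "area_px": wm.area}
            )
        stem = movie_path.stem
        wio.write_masks(out / f"{stem}.masks.tif", masks)
        pd.DataFrame(rows).to_csv(out / f"{stem}.qc.csv", index=False)
    counts["oob_accuracy"] = round(clf.oob_accuracy, 4)
    return counts


def _stage_measure(config: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "morphometry"
    out.mkdir(parents=True, exist_ok=True)
    n_rows = 0
    for movie_path in _movie_paths(config, run_dir):
        stem = movie_path.stem
        frames, sidecar = wio.read_movie(movie_path)
        masks = wio.read_masks(run_dir / "segmentation" / f"{stem}.masks.tif")
        qc = pd.read_csv(run_dir / "segmentation" / f"{stem}.qc.csv")
        px = float(sidecar.get("pixel_size_um", config.pixel_size_um))
        dt = float(sidecar.get("frame_interval_h", config.frame_interval_h))
        rows = []
        for fi, frame in enumerate(frames):
            rec = {
                "frame": fi,
                "time_h": fi * dt,
                "length_px": np.nan,
                "width_mean_px": np.nan,
                "volume_um3": np.nan,
                "area_px": np.nan,
                "total_fluor": np.nan,
                "concentration": np.nan,
                "background": np.nan,
                "qc_label": qc.loc[fi, "qc_label"],
                "qc_score": qc.loc[fi, "qc_score"],
            }
            mask = masks[fi]
            if rec["qc_label"] == "pass" and mask.any():
                img = frame.astype(float)
                try:
                    midline = morphometry.extract_midline(mask)
                    st = morphometry.straighten(img, mask, midline, frame_index=fi)
                except morphometry.StraighteningError:
                    rec["qc_label"] = "fail"
                    rows.append(rec)
                    continue
                bg = morphometry.estimate_background(img, mask)
                fluor = morphometry.measure_fluorescence(img, mask, bg)
                core = st.width[st.width > 0]
                rec.update(
                    length_px=st.length,
                    width_mean_px=core.mean() if core.size else np.nan,
                    volume_um3=morphometry.estimate_volume(st, px),
                    area_px=fluor.area,
                    total_fluor=fluor.total,
                    concentration=fluor.concentration,
                    background=bg,
                )
            rows.append(rec)
        n_rows += len(rows)
        pd.DataFrame(rows).to_csv(out / f"{stem}.morphometry.csv", index=False)
    return {"rows": n_rows}


def _load_animal(config: RunConfig, run_dir: Path, stem: str) -> trajectory.AnimalTrajectory:
    table = pd.read_csv(run_dir / "morphometry" / f"{stem}.morphometry.csv")
    group = stem.split("_")[0]
    return trajectory.AnimalTrajectory(
        times=table["time_h"].to_numpy(),
        volume=table["volume_um3"].to_numpy(),
        concentration=table["concentration"].to_numpy(),
        qc_pass=(table["qc_label"] == "pass").to_numpy(),
        animal_id=stem,
        group=group,
    ), table


def _stage_events(config: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "events"
    out.mkdir(parents=True, exist_ok=True)
    ana = dataclasses.replace(config.analysis, n_molts=config.n_molts)
    n_ok = 0
    excluded = []
    for movie_path in _movie_paths(config, run_dir):
        stem = movie_path.stem
        animal, table = _load_animal(config, run_dir, stem)
        elong = table["length_px"] / table["width_mean_px"]
        try:
            hatch, method = trajectory.detect_hatch(
                animal.times, elong.to_numpy(), animal.qc_pass
            )
        except ValueError as exc:
            excluded.append(stem)
            wio.write_events(out / f"{stem}.events.json", {"excluded": str(exc)})
            continue
        ann = trajectory.detect_molts(animal, ana, hatch_time=hatch)
        wio.write_events(
            out / f"{stem}.events.json",
            {
                "hatch_time_h": hatch,
                "hatch_method": method,
                "molt_times_h": [None if not np.isfinite(m) else m for m in ann.molt_times],
                "scores": [None if not np.isfinite(s) else s for s in ann.scores],
                "method": ann.method,
            },
        )
        n_ok += 1
    return {"animals": n_ok, "excluded": excluded}


def _stage_cohort(config: RunConfig, run_dir: Path) -> dict:
    out = run_dir / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    per_animal = []
    curves: dict[str, list] = {}
    grid = None
    for movie_path in _movie_paths(config, run_dir):
        stem = movie_path.stem
        events = wio.read_events(run_dir / "events" / f"{stem}.events.json")
        if "excluded" in events:
            continue
        animal, table = _load_animal(config, run_dir, stem)
        hatch = events["hatch_time_h"]
        m1 = events["molt_times_h"][0]
        v_hatch, _ = trajectory.boundary_volume(
            animal, hatch, side="after", n=ana.boundary_points
        )
        conc = trajectory.median_filter(animal.concentration, ana.median_window)
        # initial concentration: back-extrapolate the early recovery to the
        # hatch time with an OLS line over the first 1.5 h (a plain window
        # mean would sit mid-recovery and understate the hatch deficit)
        early = (animal.times >= hatch) & (animal.times <= hatch + 1.5) & np.isfinite(conc)
        if early.sum() >= 4:
            cc = np.polynomial.polynomial.polyfit(animal.times[early], conc[early], 1)
            c_init = float(cc[0] + cc[1] * hatch)
        elif np.isfinite(conc[early]).any():
            c_init = float(np.nanmean(conc[early]))
        else:
            c_init = np.nan
        growth, c_window = trajectory.windowed_summary(animal, ana, hatch_time=hatch)
        per_animal.append(
            {
                "animal": stem,
                "group": animal.group,
                "hatch_time_h": hatch,
                "m1_time_h": m1,
                "hatch_volume_um3": v_hatch,
                "initial_concentration": c_init,
                "window_growth_rate_per_h": growth,
                "window_concentration": c_window,
            }
        )
        # concentration vs hours-post-hatch on the frame grid
        t_rel = animal.times - hatch
        g = np.arange(0.0, 14.0 + 1e-9, animal.dt)
        ok = np.isfinite(conc)
        ci = np.interp(g, t_rel[ok], conc[ok], left=np.nan, right=np.nan)
        curves.setdefault(animal.group, []).append(ci)
        grid = g

    df = pd.DataFrame(per_animal)
    df.to_csv(out / "per_animal.csv", index=False)
    summary: dict = {"n": df.groupby("group").size().to_dict()}
    med = df.groupby("group").median(numeric_only=True)
    summary["medians"] = med.to_dict()
    if {"control", "treated"} <= set(med.index):
        for col, name in [
            ("hatch_volume_um3", "offset_hatch_volume"),
            ("initial_concentration", "offset_initial_concentration"),
            ("window_growth_rate_per_h", "offset_window_growth_rate"),
        ]:
            summary[name] = float(med.loc["treated", col] / med.loc["control", col] - 1.0)
        for col in ("hatch_volume_um3", "initial_concentration"):
            a = df.loc[df.group == "control", col].dropna()
            b = df.loc[df.group == "treated", col].dropna()
            w, p = cohort_mod.rank_sum_test(a, b)
            summary[f"ranksum_p_{col}"] = p
        summary["m1_delay_h"] = float(
            med.loc["treated", "m1_time_h"] - med.loc["control", "m1_time_h"]
        )
        boot_seed = int(
            np.random.SeedSequence([config.seed, 47]).generate_state(1)[0] % (2**31)
        )
        ratio = cohort_mod.bootstrap_ratio(
            np.array(curves["control"]),
            np.array(curves["treated"]),
            grid,
            n_boot=config.n_boot,
            seed=boot_seed,
        )
        pd.DataFrame(
            {"hours_post_hatch": grid, "ratio": ratio.diff, "lo": ratio.lo, "hi": ratio.hi}
        ).to_csv(out / "concentration_ratio.csv", index=False)
        m1_control = float(med.loc["control", "m1_time_h"] - med.loc["control", "hatch_time_h"])
        i_m1 = int(np.argmin(np.abs(grid - m1_control)))
        summary["concentration_ratio_at_m1"] = float(ratio.diff[i_m1])
        for group, mat in curves.items():
            res = cohort_mod.average_trajectories(np.array(mat), grid, group)
            pd.DataFrame(
                {"hours_post_hatch": grid, "mean": res.mean, "lo": res.lo, "hi": res.hi}
            ).to_csv(out / f"concentration_{group}.csv", index=False)
    wio.write_events(out / "summary.json", summary)
    return {"animals": int(df.shape[0])}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages, skipping those whose inputs are unchanged.

    Returns the run manifest (also written to ``manifest.json``): seeds,
    configuration hash, per-stage counts and timings.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    cfg_dict = config.to_dict()
    manifest: dict = {
        "config": cfg_dict,
        "config_hash": _hash_payload(cfg_dict),
        "seed": config.seed,
        "stages": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "segment": _stage_segment,
        "measure": _stage_measure,
        "events": _stage_events,
        "cohort": _stage_cohort,
    }
    prev_outputs: list[Path] = []
    for stage in STAGES:
        if stage == "simulate" and config.inputs:
            continue
        stage_dir = run_dir / {
            "simulate": "movies",
            "segment": "segmentation",
            "measure": "morphometry",
            "events": "events",
            "cohort": "cohort",
        }[stage]
        payload = {
            "stage": stage,
            "config": cfg_dict,
            "inputs": _hash_files(prev_outputs) if stage != "simulate" else [],
        }
        t0 = time.time()
        if not force and _stage_current(stage_dir, payload):
            log.info("stage %s: up to date, skipped", stage)
            manifest["stages"][stage] = {"skipped": True}
        else:
            log.info("stage %s: running", stage)
            try:
                counts = runners[stage](config, run_dir)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            _mark_stage(stage_dir, payload)
            counts["runtime_s"] = round(time.time() - t0, 2)
            manifest["stages"][stage] = counts
        if stage == "simulate":
            prev_outputs = sorted((run_dir / "movies").glob("*.tif"))
        elif stage == "segment":
            prev_outputs = sorted((run_dir / "segmentation").glob("*.csv"))
        elif stage == "measure":
            prev_outputs = sorted((run_dir / "morphometry").glob("*.csv"))
        elif stage == "events":
            prev_outputs = sorted((run_dir / "events").glob("*.json"))
    wio.write_events(run_dir / "manifest.json", manifest)
    return manifest
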