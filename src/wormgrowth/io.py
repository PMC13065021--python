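"""File formats: TIFF movies with JSON sidecars, CSV tables, event JSON.

Movies are multi-page TIFFs accompanied by a JSON sidecar recording the
calibration (pixel size, frame interval), the generator seed and the path
of the ground-truth table when the movie is synthetic.  Tabular outputs
are plain CSV (pandas); events and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_movie",
    "read_movie",
    "write_truth",
    "read_truth",
    "write_masks",
    "read_masks",
    "write_events",
    "read_events",
]


def write_movie(
    path: str | Path,
    frames: np.ndarray,
    pixel_size_um: float,
    frame_interval_h: float,
    seed: int | None = None,
    truth_path: str | None = None,
) -> Path:
    """Write a (T, H, W) stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))
    sidecar = {
        "pixel_size_um": float(pixel_size_um),
        "frame_interval_h": float(frame_interval_h),
        "seed": seed,
        "truth": truth_path,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_movie(path: str | Path):
    """Read a movie stack and its sidecar; returns (frames, sidecar dict)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return frames, sidecar


def write_truth(path: str | Path, truth) -> Path:
    """Ground truth as CSV (per-frame) plus JSON molt times."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_h": truth.times,
            "true_volume_um3": truth.volume,
            "true_conc": truth.concentration,
            "observed_volume_um3": truth.observed_volume,
            "observed_conc": truth.observed_concentration,
            "stage_label": truth.stage,
        }
    ).to_csv(path, index=False)
    events = {
        "hatch_time_h": float(truth.hatch_time),
        "molt_times_h": [float(m) for m in truth.molt_times],
    }
    path.with_suffix(".events.json").write_text(json.dumps(events, indent=1))
    return path


def read_truth(path: str | Path):
    path = Path(path)
    table = pd.read_csv(path)
    events = json.loads(path.with_suffix(".events.json").read_text())
    return table, events


def write_masks(path: str | Path, masks: np.ndarray) -> Path:
    """Per-frame mask stack as 8-bit multi-page TIFF (255 = foreground)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)))
    return path


def read_masks(path: str | Path) -> np.ndarray:
    m = tifffile.imread(path)
    if m.ndim == 2:
        m = m[None]
    return m > 127


def write_events(path: str | Path, events: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(events, indent=1, sort_keys=True))
    return path


def read_events(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
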