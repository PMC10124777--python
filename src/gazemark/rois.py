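"""Region-of-interest layouts: schema, geometry tests, and synthetic layouts.

The battery spec is a JSON-serializable description of every administered
trial: its regions (rect or polygon, with optional activity windows), its
duration, and trial-level metadata (affective flag, validation-target
position, flash time for pupil trials).  Coordinates use the display
convention: origin top-left, x right, y down, pixels, screen bounds half-open
``[0, W) x [0, H)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as MplPath

from .config import FACE_TASKS, Screen, SimulationConfig, Task

logger = logging.getLogger(__name__)

#: fixed precedence used to resolve overlapping regions (highest first)
PRECEDENCE: Tuple[str, ...] = (
    "face",
    "bio",
    "control",
    "body",
    "activity",
    "validation_target",
    "other",
)


@dataclass(frozen=True)
class Region:
    label: str
    shape: str  # "rect" | "poly"
    coords: Tuple[float, ...]  # rect: (x0, y0, x1, y1); poly: flat x,y pairs
    t_start_ms: float = 0.0
    t_end_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in PRECEDENCE:
            raise ValueError(f"unknown region label {self.label!r}")
        if self.shape == "rect":
            x0, y0, x1, y1 = self.coords
            if not (x1 > x0 and y1 > y0):
                raise ValueError("degenerate rectangle")
        elif self.shape == "poly":
            if len(self.coords) < 6 or len(self.coords) % 2:
                raise ValueError("polygon needs >= 3 (x, y) vertices")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")

    def active(self, t_ms: np.ndarray, duration_ms: float) -> np.ndarray:
        end = duration_ms if self.t_end_ms is None else self.t_end_ms
        return (t_ms >= self.t_start_ms) & (t_ms < end)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "rect":
            x0, y0, x1, y1 = self.coords
            return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        verts = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        path = MplPath(verts)
        pts = np.column_stack([np.ravel(x), np.ravel(y)])
        ok = np.isfinite(pts).all(axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            out[ok] = path.contains_points(pts[ok])
        return out.reshape(np.shape(x))

    def area_px2(self) -> float:
        if self.shape == "rect":
            x0, y0, x1, y1 = self.coords
            return (x1 - x0) * (y1 - y0)
        verts = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        x, y = verts[:, 0], verts[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class TrialROI:
    """Per-trial stimulus description."""

    task: Task
    day: int
    trial: int
    duration_ms: float
    regions: Tuple[Region, ...] = ()
    affective: bool = False
    target_px: Optional[Tuple[float, float]] = None  # validation trials
    flash_ms: Optional[float] = None  # pupil trials

    def key(self) -> Tuple[str, int, int]:
        return (self.task.value, self.day, self.trial)


@dataclass
class BatterySpec:
    """Everything the derivation stage needs to know about the stimuli."""

    screen: Screen
    sample_rate_hz: float
    plr_sample_rate_hz: float
    trials: List[TrialROI] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: Dict[Tuple[str, int, int], TrialROI] = {
            t.key(): t for t in self.trials
        }
        if len(self._index) != len(self.trials):
            raise ValueError("duplicate (task, day, trial) keys in battery spec")

    def lookup(self, task: str, day: int, trial: int) -> TrialROI:
        return self._index[(str(task), int(day), int(trial))]

    # ---- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "screen": self.screen.model_dump(),
            "sample_rate_hz": self.sample_rate_hz,
            "plr_sample_rate_hz": self.plr_sample_rate_hz,
            "trials": [
                {
                    "task": t.task.value,
                    "day": t.day,
                    "trial": t.trial,
                    "duration_ms": t.duration_ms,
                    "affective": t.affective,
                    "target_px": list(t.target_px) if t.target_px else None,
                    "flash_ms": t.flash_ms,
                    "regions": [
                        {
                            "label": r.label,
                            "shape": r.shape,
                            "coords": list(r.coords),
                            "t_start_ms": r.t_start_ms,
                            "t_end_ms": r.t_end_ms,
                        }
                        for r in t.regions
                    ],
                }
                for t in self.trials
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BatterySpec":
        required = {"screen", "sample_rate_hz", "plr_sample_rate_hz", "trials"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"battery spec missing keys: {sorted(missing)}")
        trials = [
            TrialROI(
                task=Task(t["task"]),
                day=int(t["day"]),
                trial=int(t["trial"]),
                duration_ms=float(t["duration_ms"]),
                affective=bool(t.get("affective", False)),
                target_px=tuple(t["target_px"]) if t.get("target_px") else None,
                flash_ms=t.get("flash_ms"),
                regions=tuple(
                    Region(
                        label=r["label"],
                        shape=r["shape"],
                        coords=tuple(r["coords"]),
                        t_start_ms=float(r.get("t_start_ms", 0.0)),
                        t_end_ms=r.get("t_end_ms"),
                    )
                    for r in t.get("regions", [])
                ),
            )
            for t in d["trials"]
        ]
        return cls(
            screen=Screen(**d["screen"]),
            sample_rate_hz=float(d["sample_rate_hz"]),
            plr_sample_rate_hz=float(d["plr_sample_rate_hz"]),
            trials=trials,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "BatterySpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def core_rect(rect: Sequence[float], shrink: float = 0.5) -> Tuple[float, float, float, float]:
    """Concentric sub-rectangle with linear dimensions scaled by ``shrink``.

    Gaze emitted from the core stays inside the full region under typical
    calibration offsets, so region membership survives the offset round trip.
    """
    x0, y0, x1, y1 = rect
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    hw, hh = (x1 - x0) / 2 * shrink, (y1 - y0) / 2 * shrink
    return (cx - hw, cy - hh, cx + hw, cy + hh)


def mirror_rect(rect: Sequence[float], width_px: float) -> Tuple[float, float, float, float]:
    x0, y0, x1, y1 = rect
    return (width_px - x1, y0, width_px - x0, y1)


def _band_rect(
    screen: Screen, area_frac: float, band: Tuple[float, float], max_aspect: float = 1.2
) -> Tuple[float, float, float, float]:
    """Horizontally centred rectangle of the given area inside a vertical band."""
    w_scr, h_scr = screen.width_px, screen.height_px
    area = area_frac * w_scr * h_scr
    band_h = (band[1] - band[0]) * h_scr
    h = min(band_h, (area / max_aspect) ** 0.5)
    w = area / h
    if w > 0.96 * w_scr:
        w = 0.96 * w_scr
        h = area / w
    cy = (band[0] + band[1]) / 2 * h_scr
    cx = w_scr / 2
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


_FACE_BAND = (0.08, 0.42)
_BODY_BAND = (0.46, 0.78)
_ACTIVITY_BAND = (0.82, 0.98)
_BODY_AREA = 0.10
_ACTIVITY_AREA = 0.08

_VALIDATION_POINTS = (
    (0.5, 0.5),
    (0.2, 0.2),
    (0.8, 0.2),
    (0.2, 0.8),
    (0.8, 0.8),
)


def face_task_layout(screen: Screen, face_area_frac: float) -> Dict[str, Tuple[float, float, float, float]]:
    """Static face/body/activity rectangles for one social-viewing task."""
    return {
        "face": _band_rect(screen, face_area_frac, _FACE_BAND),
        "body": _band_rect(screen, _BODY_AREA, _BODY_BAND, max_aspect=1.5),
        "activity": _band_rect(screen, _ACTIVITY_AREA, _ACTIVITY_BAND, max_aspect=5.0),
    }


def bm_layout(screen: Screen) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
    """Left and right panels for the side-by-side preference task."""
    w_px, h_px = screen.width_px, screen.height_px
    left = (0.06 * w_px, 0.25 * h_px, 0.46 * w_px, 0.75 * h_px)
    right = mirror_rect(left, w_px)
    return left, right


def build_battery_spec(config: SimulationConfig, rng: np.random.Generator) -> BatterySpec:
    """Construct the synthetic stimulus battery for one cohort.

    Deterministic given the generator state; the only random element is which
    side carries the biological motion on each BM trial and which BM trials
    are affective.
    """
    screen = config.screen
    trials: List[TrialROI] = []
    val_points = [
        (fx * screen.width_px, fy * screen.height_px) for fx, fy in _VALIDATION_POINTS
    ]

    for day in (1, 2):
        # social-viewing tasks -----------------------------------------
        for task in FACE_TASKS:
            layout = face_task_layout(screen, config.roi_area_fractions[task])
            if task == Task.SS and day == 2:
                layout = {
                    k: mirror_rect(v, screen.width_px) for k, v in layout.items()
                }
            regions = tuple(
                Region(label=lbl, shape="rect", coords=tuple(rect))
                for lbl, rect in layout.items()
            )
            trial_no = 0
            for block in config.blocks_for(task, day):
                for _ in range(block.n_trials):
                    trial_no += 1
                    trials.append(
                        TrialROI(
                            task=task,
                            day=day,
                            trial=trial_no,
                            duration_ms=block.duration_s * 1000.0,
                            regions=regions,
                        )
                    )

        # biological-motion preference ----------------------------------
        left, right = bm_layout(screen)
        trial_no = 0
        for block in config.blocks_for(Task.BM, day):
            bio_left = rng.random(block.n_trials) < 0.5
            affective = rng.random(block.n_trials) < config.bm_affective_fraction
            for i in range(block.n_trials):
                trial_no += 1
                bio_rect, ctl_rect = (left, right) if bio_left[i] else (right, left)
                trials.append(
                    TrialROI(
                        task=Task.BM,
                        day=day,
                        trial=trial_no,
                        duration_ms=block.duration_s * 1000.0,
                        affective=bool(affective[i]),
                        regions=(
                            Region(label="bio", shape="rect", coords=tuple(bio_rect)),
                            Region(label="control", shape="rect", coords=tuple(ctl_rect)),
                        ),
                    )
                )

        # pupil trials ---------------------------------------------------
        trial_no = 0
        for block in config.blocks_for(Task.PLR, day):
            for _ in range(block.n_trials):
                trial_no += 1
                trials.append(
                    TrialROI(
                        task=Task.PLR,
                        day=day,
                        trial=trial_no,
                        duration_ms=block.duration_s * 1000.0,
                        flash_ms=config.plr.flash_ms,
                    )
                )

        # validation-target probes ---------------------------------------
        for i in range(config.validation_trials_per_day):
            tx, ty = val_points[(i + (day - 1) * config.validation_trials_per_day) % len(val_points)]
            half = screen.px_per_degree / 2
            trials.append(
                TrialROI(
                    task=Task.VAL,
                    day=day,
                    trial=i + 1,
                    duration_ms=config.validation_duration_s * 1000.0,
                    target_px=(tx, ty),
                    regions=(
                        Region(
                            label="validation_target",
                            shape="rect",
                            coords=(tx - half, ty - half, tx + half, ty + half),
                        ),
                    ),
                )
            )

    return BatterySpec(
        screen=screen,
        sample_rate_hz=config.sample_rate_hz,
        plr_sample_rate_hz=config.plr_sample_rate_hz,
        trials=trials,
    )


def label_points(
    x: np.ndarray,
    y: np.ndarray,
    t_ms: np.ndarray,
    trial_roi: TrialROI,
    screen: Screen,
) -> np.ndarray:
    """Assign each sample the highest-precedence containing active region.

    Returns an integer array indexing :data:`PRECEDENCE`; -1 marks samples
    outside every region or off-screen.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    out = np.full(x.shape, -1, dtype=np.int8)
    on_screen = (
        np.isfinite(x)
        & np.isfinite(y)
        & (x >= 0)
        & (x < screen.width_px)
        & (y >= 0)
        & (y < screen.height_px)
    )
    regions = sorted(trial_roi.regions, key=lambda r: PRECEDENCE.index(r.label))
    for region in regions:
        code = PRECEDENCE.index(region.label)
        todo = on_screen & (out == -1)
        if not todo.any():
            break
        mask = todo & region.active(t_ms, trial_roi.duration_ms) & region.contains(x, y)
        out[mask] = code
    return out
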