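"""Per-trial derivation: ROI dwell proportions, acquisition metrics, and
pupil metrics, from raw sample tables plus the battery spec.

Percentage conventions:

* ``pct_valid_data`` is tracked-on-screen time as a percentage of the trial's
  stimulus presentation time;
* every ROI percentage uses *valid time* (tracked and on-screen) as its
  denominator, never raw trial duration;
* the preference percentage for the side-by-side task is
  ``bio / (bio + control)`` and is undefined when neither panel was fixated.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import Screen, Task
from .pupil import (
    PupilParams,
    constriction_matrix,
    latency_matrix,
    preprocess_matrix,
)
from .rois import PRECEDENCE, BatterySpec, TrialROI, label_points

logger = logging.getLogger(__name__)

_FACE = PRECEDENCE.index("face")
_BIO = PRECEDENCE.index("bio")
_CONTROL = PRECEDENCE.index("control")
_BODY = PRECEDENCE.index("body")
_ACTIVITY = PRECEDENCE.index("activity")

TRIAL_KEYS = ["participant_id", "group", "timepoint", "day", "task", "trial"]


def assign_sample_to_roi(
    x_px: float,
    y_px: float,
    t_ms: float,
    trial_roi: TrialROI,
    screen: Screen,
    tracked: bool = True,
) -> Optional[str]:
    """Label of the highest-precedence active region containing the sample.

    Returns None for untracked samples, off-screen samples, and samples
    outside every region.  Overlapping containing regions are resolved by the
    fixed precedence order and logged at debug level.
    """
    if not tracked:
        return None
    hits = [
        r.label
        for r in trial_roi.regions
        if r.active(np.asarray([t_ms]), trial_roi.duration_ms)[0]
        and bool(r.contains(np.asarray([x_px]), np.asarray([y_px]))[0])
    ]
    code = label_points(
        np.asarray([x_px]), np.asarray([y_px]), np.asarray([t_ms]), trial_roi, screen
    )[0]
    if len(set(hits)) > 1:
        logger.debug(
            "overlapping regions %s at (%s, %s); precedence chose %s",
            hits,
            x_px,
            y_px,
            PRECEDENCE[code],
        )
    return None if code < 0 else PRECEDENCE[code]


def compute_trial_metrics(
    samples: pd.DataFrame,
    trial_roi: TrialROI,
    screen: Screen,
    sample_rate_hz: float,
) -> Dict[str, float]:
    """Reference per-trial metric computation (single trial).

    ``samples`` needs columns t_ms, x_px, y_px, tracked_flag.
    """
    if trial_roi.duration_ms <= 0:
        raise ValueError("trial duration must be positive")
    dt = 1000.0 / sample_rate_hz
    n_expected = max(1, round(trial_roi.duration_ms / dt))
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    t = samples["t_ms"].to_numpy(dtype=float)
    tracked = samples["tracked_flag"].to_numpy() > 0

    on_screen = (
        np.isfinite(x)
        & np.isfinite(y)
        & (x >= 0)
        & (x < screen.width_px)
        & (y >= 0)
        & (y < screen.height_px)
    )
    valid = tracked & on_screen
    labels = label_points(x, y, t, trial_roi, screen)
    labels[~valid] = -1

    n_valid = int(valid.sum())
    out: Dict[str, float] = {
        "pct_valid_data": 100.0 * n_valid / n_expected,
        "affective_flag": float(trial_roi.affective),
    }
    if n_valid == 0:
        out.update(
            pct_face=np.nan,
            pct_body=np.nan,
            pct_activity=np.nan,
            pct_social=np.nan,
            bio_ms=0.0,
            control_ms=0.0,
            pct_bio=np.nan,
        )
        return out

    def pct(code: int) -> float:
        return 100.0 * float((labels == code).sum()) / n_valid

    out["pct_face"] = pct(_FACE)
    out["pct_body"] = pct(_BODY)
    out["pct_activity"] = pct(_ACTIVITY)
    out["pct_social"] = min(
        100.0, out["pct_face"] + out["pct_body"] + out["pct_activity"]
    )
    bio_n = float((labels == _BIO).sum())
    ctl_n = float((labels == _CONTROL).sum())
    out["bio_ms"] = bio_n * dt
    out["control_ms"] = ctl_n * dt
    out["pct_bio"] = (
        100.0 * bio_n / (bio_n + ctl_n) if (bio_n + ctl_n) > 0 else np.nan
    )
    return out


def estimate_cal_error(
    events: Sequence[Tuple[pd.DataFrame, Tuple[float, float]]],
    px_per_degree: float,
) -> float:
    """Median-of-medians angular distance between gaze and validation targets.

    ``events`` is a list of (samples, target_px) pairs; untracked samples are
    ignored.  Returns NaN when no event carries tracked samples.
    """
    per_event: List[float] = []
    for samples, (tx, ty) in events:
        x = samples["x_px"].to_numpy(dtype=float)
        y = samples["y_px"].to_numpy(dtype=float)
        tracked = samples["tracked_flag"].to_numpy() > 0
        ok = tracked & np.isfinite(x) & np.isfinite(y)
        if not ok.any():
            continue
        dist = np.hypot(x[ok] - tx, y[ok] - ty) / px_per_degree
        per_event.append(float(np.median(dist)))
    return float(np.median(per_event)) if per_event else np.nan


# ---------------------------------------------------------------------------
# vectorized table-level derivation
# ---------------------------------------------------------------------------

def _label_gaze(gaze: pd.DataFrame, battery: BatterySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample validity and region codes for a full gaze table."""
    screen = battery.screen
    x = gaze["x_px"].to_numpy(dtype=float)
    y = gaze["y_px"].to_numpy(dtype=float)
    t = gaze["t_ms"].to_numpy(dtype=float)
    tracked = gaze["tracked_flag"].to_numpy() > 0
    on_screen = (
        np.isfinite(x)
        & np.isfinite(y)
        & (x >= 0)
        & (x < screen.width_px)
        & (y >= 0)
        & (y < screen.height_px)
    )
    valid = tracked & on_screen
    labels = np.full(len(gaze), -1, dtype=np.int8)
    grouped = gaze.groupby(["task", "day", "trial"], observed=True, sort=False)
    for (task, day, trial), idx in grouped.indices.items():
        troi = battery.lookup(str(task), int(day), int(trial))
        labels[idx] = label_points(x[idx], y[idx], t[idx], troi, screen)
    labels[~valid] = -1
    return valid, labels


def session_cal_errors(gaze: pd.DataFrame, battery: BatterySpec) -> pd.DataFrame:
    """Session-level (participant x timepoint x day) calibration error from
    validation-target trials."""
    val = gaze[gaze["task"] == Task.VAL.value]
    cols = ["participant_id", "timepoint", "day"]
    if val.empty:
        return pd.DataFrame(columns=cols + ["cal_error_deg"])
    ppd = battery.screen.px_per_degree
    val = val.copy()
    tx = np.empty(len(val))
    ty = np.empty(len(val))
    for (day, trial), idx in val.groupby(["day", "trial"], observed=True).indices.items():
        troi = battery.lookup(Task.VAL.value, int(day), int(trial))
        tx[idx], ty[idx] = troi.target_px
    x = val["x_px"].to_numpy(dtype=float)
    y = val["y_px"].to_numpy(dtype=float)
    ok = (val["tracked_flag"].to_numpy() > 0) & np.isfinite(x) & np.isfinite(y)
    val["dist_deg"] = np.where(ok, np.hypot(x - tx, y - ty) / ppd, np.nan)
    per_event = (
        val.groupby(cols + ["trial"], observed=True)["dist_deg"].median().reset_index()
    )
    out = (
        per_event.groupby(cols, observed=True)["dist_deg"]
        .median()
        .rename("cal_error_deg")
        .reset_index()
    )
    return out


def derive_gaze_trials(gaze: pd.DataFrame, battery: BatterySpec) -> pd.DataFrame:
    """TrialDerived rows for every non-pupil, non-validation trial."""
    mask = ~gaze["task"].isin([Task.VAL.value, Task.PLR.value])
    g = gaze[mask].reset_index(drop=True)
    if g.empty:
        return pd.DataFrame(columns=TRIAL_KEYS)
    valid, labels = _label_gaze(g, battery)

    dt = 1000.0 / battery.sample_rate_hz
    agg = pd.DataFrame(
        {k: g[k] for k in TRIAL_KEYS}
    )
    agg["n_samples"] = 1
    agg["n_valid"] = valid.astype(np.int32)
    agg["n_face"] = (labels == _FACE).astype(np.int32)
    agg["n_body"] = (labels == _BODY).astype(np.int32)
    agg["n_activity"] = (labels == _ACTIVITY).astype(np.int32)
    agg["n_bio"] = (labels == _BIO).astype(np.int32)
    agg["n_control"] = (labels == _CONTROL).astype(np.int32)
    agg["n_tracked"] = (g["tracked_flag"].to_numpy() > 0).astype(np.int32)
    trials = (
        agg.groupby(TRIAL_KEYS, observed=True, sort=True).sum().reset_index()
    )

    n_expected = np.empty(len(trials))
    affective = np.zeros(len(trials))
    for i, row in enumerate(
        trials[["task", "day", "trial"]].itertuples(index=False)
    ):
        troi = battery.lookup(str(row.task), int(row.day), int(row.trial))
        n_expected[i] = max(1, round(troi.duration_ms / dt))
        affective[i] = float(troi.affective)

    nv = trials["n_valid"].to_numpy(dtype=float)
    safe_nv = np.where(nv > 0, nv, np.nan)
    trials["pct_valid_data"] = 100.0 * nv / n_expected
    trials["pct_face"] = 100.0 * trials["n_face"] / safe_nv
    trials["pct_body"] = 100.0 * trials["n_body"] / safe_nv
    trials["pct_activity"] = 100.0 * trials["n_activity"] / safe_nv
    trials["pct_social"] = np.minimum(
        100.0, trials["pct_face"] + trials["pct_body"] + trials["pct_activity"]
    )
    trials["bio_ms"] = trials["n_bio"] * dt
    trials["control_ms"] = trials["n_control"] * dt
    denom = (trials["n_bio"] + trials["n_control"]).to_numpy(dtype=float)
    trials["pct_bio"] = np.where(
        denom > 0, 100.0 * trials["n_bio"] / np.where(denom > 0, denom, 1.0), np.nan
    )
    trials["affective_flag"] = affective
    trials["latency_ms"] = np.nan
    trials["constriction"] = np.nan
    trials["plr_shape_valid"] = np.nan
    drop = [c for c in trials.columns if c.startswith("n_") and c != "n_valid"]
    return trials.drop(columns=drop + ["n_valid"])


def derive_plr_trials(
    pupil: pd.DataFrame,
    battery: BatterySpec,
    params: PupilParams = PupilParams(),
) -> pd.DataFrame:
    """TrialDerived rows for pupil trials (latency, constriction, validity)."""
    if pupil.empty:
        return pd.DataFrame(columns=TRIAL_KEYS)
    flashes = {
        (t.day, t.trial): (t.flash_ms, t.duration_ms)
        for t in battery.trials
        if t.task == Task.PLR
    }
    dt = 1000.0 / battery.plr_sample_rate_hz

    rows = []
    matrices: Dict[Tuple[float, int], List[np.ndarray]] = {}
    order: Dict[Tuple[float, int], List[int]] = {}
    p = pupil.sort_values(TRIAL_KEYS + ["t_ms"], kind="stable")
    grouped = p.groupby(TRIAL_KEYS, observed=True, sort=True)
    for key, sub in grouped:
        day, trial = int(key[3]), int(key[5])
        flash_ms, duration_ms = flashes[(day, trial)]
        n_steps = max(2, round(duration_ms / dt))
        diam = sub["pupil_au"].to_numpy(dtype=float)
        if len(diam) != n_steps:  # tolerate ragged input
            full = np.full(n_steps, np.nan)
            ix = np.clip(
                np.round(sub["t_ms"].to_numpy(dtype=float) / dt).astype(int),
                0,
                n_steps - 1,
            )
            full[ix] = diam
            diam = full
        bucket = (flash_ms, n_steps)
        matrices.setdefault(bucket, []).append(diam)
        order.setdefault(bucket, []).append(len(rows))
        rows.append(dict(zip(TRIAL_KEYS, key)))

    out = pd.DataFrame(rows)
    out["pct_valid_data"] = np.nan
    out["latency_ms"] = np.nan
    out["constriction"] = np.nan
    out["plr_shape_valid"] = np.nan
    for (flash_ms, n_steps), mats in matrices.items():
        t_ms = np.arange(n_steps) * dt
        m = np.vstack(mats)
        present = np.isfinite(m) & (m > 0)
        pct_valid = 100.0 * present.mean(axis=1)
        smoothed, valid, _n_interp, cov_b, cov_r = preprocess_matrix(
            m, t_ms, flash_ms, params
        )
        lat = latency_matrix(smoothed, t_ms, flash_ms, params)
        con = constriction_matrix(smoothed, t_ms, flash_ms, (0.0, flash_ms), params)
        ok = (
            valid
            & np.isfinite(lat)
            & (lat > 0)
            & (lat <= params.search_window_ms)
            & np.isfinite(con)
            & (con > 0)
            & (con < 1)
        )
        ix = order[(flash_ms, n_steps)]
        out.loc[ix, "pct_valid_data"] = pct_valid
        out.loc[ix, "latency_ms"] = lat
        out.loc[ix, "constriction"] = con
        out.loc[ix, "plr_shape_valid"] = ok.astype(float)

    for col in (
        "pct_face",
        "pct_body",
        "pct_activity",
        "pct_social",
        "bio_ms",
        "control_ms",
        "pct_bio",
        "affective_flag",
    ):
        out[col] = np.nan
    return out


def derive_trials(
    gaze: pd.DataFrame,
    pupil: pd.DataFrame,
    battery: BatterySpec,
    pupil_params: PupilParams = PupilParams(),
) -> pd.DataFrame:
    """Full TrialDerived table with session-level calibration error attached.

    Trial-level calibration error falls back to the session (participant-day)
    estimate from validation trials; trials in sessions without a usable
    estimate keep NaN and will fail QC.
    """
    gaze_trials = derive_gaze_trials(gaze, battery)
    plr_trials = derive_plr_trials(pupil, battery, pupil_params)
    trials = pd.concat([gaze_trials, plr_trials], ignore_index=True)
    if trials.empty:
        return trials
    cal = session_cal_errors(gaze, battery)
    trials = trials.merge(
        cal, on=["participant_id", "timepoint", "day"], how="left"
    )
    key_cols = ["participant_id", "timepoint", "day", "task", "trial"]
    trials = trials.sort_values(key_cols, kind="stable").reset_index(drop=True)
    return trials
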