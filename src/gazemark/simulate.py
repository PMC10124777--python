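"""Synthetic cohort simulator.

Generates per-sample gaze streams, pupil-flash traces, clinical tables, and a
ground-truth ledger with the statistical structure the analysis battery
assumes:

* per-participant face-gaze propensity on the logit scale, decomposed into a
  stable trait and a per-timepoint state with a configurable variance ratio
  (the population ICC of the realized task means);
* within trials, an in-face indicator following a two-state Markov chain
  whose stationary probability is the participant's propensity;
* i.i.d. per-sample dropout at a participant rate, plus occasional
  high-loss "bad" trials;
* a constant per-participant-day calibration offset added to emitted
  coordinates;
* logistic-shaped pupil constrictions with a planted analytic
  minimum-acceleration time;
* clinical scores coupled to the face latent through a Gaussian copula so
  population Spearman correlations hit configured targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .calibrate import (
    GroupCalibration,
    calibrate,
    chain_lambda,
    task_unique_trait_fraction,
)
from .config import (
    ASD,
    FACE_TASKS,
    GROUPS,
    TD,
    SimulationConfig,
    Task,
)
from .rois import BatterySpec, TrialROI, build_battery_spec, core_rect

#: logit-curve coordinate of the minimum of the second time-derivative of a
#: falling logistic: solving S'''(u) = 0 gives S(u) = (3 - sqrt(3))/6
LOGISTIC_ACCEL_ARGMIN = math.log((3 - math.sqrt(3)) / (3 + math.sqrt(3)))

GAZE_COLUMNS = [
    "participant_id",
    "group",
    "timepoint",
    "day",
    "task",
    "trial",
    "t_ms",
    "x_px",
    "y_px",
    "pupil_au",
    "tracked_flag",
]

_BACKGROUND_PAD_DEG = 2.0
_EDGE_PAD_DEG = 2.5


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------

@dataclass
class Latents:
    """Per-participant generative state, aligned by row index."""

    participant_id: np.ndarray
    group: np.ndarray
    site: np.ndarray
    age_years: np.ndarray
    dropout_rate: np.ndarray
    bad_trial_rate: np.ndarray
    cal_offset_deg: np.ndarray  # (P, n_timepoints, 2 days, 2) in degrees
    p_face: np.ndarray          # (P, len(FACE_TASKS), n_timepoints)
    p_bio: np.ndarray           # (P, n_timepoints)
    latent_composite: np.ndarray  # standardized within group
    plr_latency_ms: np.ndarray
    plr_constriction: np.ndarray
    plr_baseline_au: np.ndarray

    @property
    def n(self) -> int:
        return len(self.participant_id)


def _participant_ids(config: SimulationConfig) -> Tuple[np.ndarray, np.ndarray]:
    ids = [f"{ASD}{i + 1:04d}" for i in range(config.n_asd)] + [
        f"{TD}{i + 1:04d}" for i in range(config.n_td)
    ]
    groups = [ASD] * config.n_asd + [TD] * config.n_td
    return np.array(ids, dtype=object), np.array(groups, dtype=object)


def draw_latents(
    config: SimulationConfig,
    calib: Dict[str, GroupCalibration],
    rng: np.random.Generator,
) -> Latents:
    ids, groups = _participant_ids(config)
    n_total = len(ids)
    n_tp = len(config.timepoints)

    site = np.array(
        [f"Site{i + 1}" for i in rng.integers(0, config.n_sites, n_total)],
        dtype=object,
    )
    age = rng.uniform(*config.age_range_years, n_total)

    p_face = np.empty((n_total, len(FACE_TASKS), n_tp))
    p_bio = np.empty((n_total, n_tp))
    latent_composite = np.empty(n_total)
    dropout = np.empty(n_total)
    bad_rate = np.empty(n_total)
    cal = np.empty((n_total, n_tp, 2, 2))
    plr_lat = np.empty(n_total)
    plr_con = np.empty(n_total)
    plr_base = np.empty(n_total)

    start = 0
    for g, n_g in ((ASD, config.n_asd), (TD, config.n_td)):
        sl = slice(start, start + n_g)
        start += n_g
        gp = config.groups[g]
        gc = calib[g]
        c = gc.cross_task_corr

        f_shared = config.trait_variance_fraction
        u = rng.standard_normal(n_g)                       # shared trait
        e = rng.standard_normal((n_g, n_tp))               # shared state
        v = rng.standard_normal((n_g, len(FACE_TASKS)))    # task trait
        w = rng.standard_normal((n_g, len(FACE_TASKS), n_tp))  # task state

        # one shared component (target trait/state split), identical across
        # tasks, plus a task-unique component absorbing the inflation needed
        # so the realized per-task ICC matches the configured fraction
        shared = math.sqrt(f_shared) * u[:, None] + math.sqrt(1 - f_shared) * e
        z = np.empty((n_g, len(FACE_TASKS), n_tp))
        for ki, task in enumerate(FACE_TASKS):
            tc = gc.face[task]
            f_uni = task_unique_trait_fraction(tc.f_z, c, f_shared)
            unique = (
                math.sqrt(f_uni) * v[:, ki, None]
                + math.sqrt(1 - f_uni) * w[:, ki, :]
            )
            z[:, ki, :] = math.sqrt(c) * shared + math.sqrt(1 - c) * unique
            p_face[sl, ki, :] = expit(tc.mu + tc.sigma * z[:, ki, :])

        # linearized composite latent at the first timepoint, standardized
        sds = np.array([gc.face[t].latent_sd for t in FACE_TASKS])
        comp = (z[:, :, 0] * sds).sum(axis=1) / 3.0
        var = float(np.sum(sds**2))
        for i in range(len(sds)):
            for j in range(i + 1, len(sds)):
                var += 2 * sds[i] * sds[j] * c
        latent_composite[sl] = comp / math.sqrt(var / 9.0)

        ub = rng.standard_normal(n_g)
        eb = rng.standard_normal((n_g, n_tp))
        tb = gc.bio
        zb = math.sqrt(tb.f_z) * ub[:, None] + math.sqrt(1 - tb.f_z) * eb
        p_bio[sl, :] = expit(tb.mu + tb.sigma * zb)

        dropout[sl] = np.clip(
            rng.normal(gp.dropout_rate_mean, gp.dropout_rate_sd, n_g), 0.0, 0.95
        )
        bad_rate[sl] = gp.bad_trial_rate
        # per-axis normal offsets => Rayleigh magnitude, mean = s*sqrt(pi/2)
        s_cal = gp.cal_error_mean_deg / math.sqrt(math.pi / 2)
        cal[sl] = rng.normal(0.0, s_cal, (n_g, n_tp, 2, 2)) if s_cal > 0 else 0.0

        plr_lat[sl] = rng.normal(gp.plr_latency_mean_ms, gp.plr_latency_sd_ms, n_g)
        plr_con[sl] = np.clip(
            rng.normal(gp.plr_constriction_mean, gp.plr_constriction_sd, n_g),
            0.05,
            0.95,
        )
        plr_base[sl] = np.clip(
            rng.normal(config.plr.baseline_au, config.plr.baseline_sd_au, n_g),
            config.plr.baseline_au * 0.3,
            None,
        )

    return Latents(
        participant_id=ids,
        group=groups,
        site=site,
        age_years=age,
        dropout_rate=dropout,
        bad_trial_rate=bad_rate,
        cal_offset_deg=cal,
        p_face=p_face,
        p_bio=p_bio,
        latent_composite=latent_composite,
        plr_latency_ms=plr_lat,
        plr_constriction=plr_con,
        plr_baseline_au=plr_base,
    )


# ---------------------------------------------------------------------------
# gaze machinery
# ---------------------------------------------------------------------------

def simulate_dwell_chain(
    p: np.ndarray, lam: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary two-state chains with stationary probability ``p``.

    ``p`` has shape (M,); the result is boolean (M, n_steps).  The chain's
    per-step memory is ``lam`` (eigenvalue of the transition kernel), so the
    autocorrelation of the indicator is ``lam**k`` at lag ``k``.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = p.shape[0]
    u = rng.random((m, n_steps))
    states = np.empty((m, n_steps), dtype=bool)
    q_in = (1 - lam) * p
    q_out = (1 - lam) * (1 - p)
    s = u[:, 0] < p
    states[:, 0] = s
    for t in range(1, n_steps):
        s = np.where(s, u[:, t] >= q_out, u[:, t] < q_in)
        states[:, t] = s
    return states


def _fill_rect(
    x: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    rect: Sequence[float],
    rng: np.random.Generator,
) -> None:
    k = int(mask.sum())
    if k:
        x[mask] = rng.uniform(rect[0], rect[2], k)
        y[mask] = rng.uniform(rect[1], rect[3], k)


def _sample_background(
    n: int,
    screen,
    exclude_rects: List[Sequence[float]],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform points on-screen, away from edges and padded regions."""
    edge = _EDGE_PAD_DEG * screen.px_per_degree
    pad = _BACKGROUND_PAD_DEG * screen.px_per_degree
    padded = [
        (r[0] - pad, r[1] - pad, r[2] + pad, r[3] + pad) for r in exclude_rects
    ]
    xs = np.empty(n)
    ys = np.empty(n)
    need = np.arange(n)
    while need.size:
        x = rng.uniform(edge, screen.width_px - edge, need.size)
        y = rng.uniform(edge, screen.height_px - edge, need.size)
        bad = np.zeros(need.size, dtype=bool)
        for x0, y0, x1, y1 in padded:
            bad |= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        ok = ~bad
        xs[need[ok]] = x[ok]
        ys[need[ok]] = y[ok]
        need = need[bad]
    return xs, ys


def _region_rects(trial_roi: TrialROI) -> Dict[str, Tuple[float, ...]]:
    return {r.label: r.coords for r in trial_roi.regions if r.shape == "rect"}


def simulate_gaze_trial(
    stationary_p: float,
    trial_roi: TrialROI,
    config: SimulationConfig,
    rng: np.random.Generator,
    dropout_rate: float = 0.0,
    offset_px: Tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Reference single-trial generator (same law as the block engine).

    For social-viewing tasks ``stationary_p`` is the in-face probability; for
    the side-by-side preference task it is the on-bio-side probability.
    """
    if trial_roi.duration_ms <= 0:
        raise ValueError("trial duration must be positive")
    n_steps = max(1, round(trial_roi.duration_ms / 1000.0 * config.sample_rate_hz))
    lam = chain_lambda(config.sample_rate_hz, config.dwell_ms)
    states = simulate_dwell_chain(
        np.array([stationary_p]), lam, n_steps, rng
    )[0]
    dt = 1000.0 / config.sample_rate_hz
    t_ms = np.arange(n_steps) * dt
    x = np.empty(n_steps)
    y = np.empty(n_steps)
    rects = _region_rects(trial_roi)

    if trial_roi.task == Task.BM:
        _fill_rect(x, y, states, core_rect(rects["bio"]), rng)
        _fill_rect(x, y, ~states, core_rect(rects["control"]), rng)
    else:
        _fill_rect(x, y, states, core_rect(rects["face"]), rng)
        out = ~states
        n_out = int(out.sum())
        if n_out:
            sub = rng.random(n_out)
            a = config.out_of_face_split.get("activity", 0.0)
            b = config.out_of_face_split.get("body", 0.0)
            idx = np.flatnonzero(out)
            act = idx[sub < a]
            body = idx[(sub >= a) & (sub < a + b)]
            bg = idx[sub >= a + b]
            if "activity" in rects:
                _fill_rect_at(x, y, act, core_rect(rects["activity"]), rng)
            if "body" in rects:
                _fill_rect_at(x, y, body, core_rect(rects["body"]), rng)
            bx, by = _sample_background(
                bg.size, config.screen, list(rects.values()), rng
            )
            x[bg], y[bg] = bx, by

    tracked = rng.random(n_steps) >= dropout_rate
    x = x + offset_px[0]
    y = y + offset_px[1]
    x[~tracked] = np.nan
    y[~tracked] = np.nan
    return pd.DataFrame(
        {
            "t_ms": t_ms,
            "x_px": x,
            "y_px": y,
            "tracked_flag": tracked.astype(np.int8),
            "in_roi_state": states.astype(np.int8),
        }
    )


def _fill_rect_at(x, y, idx, rect, rng) -> None:
    if idx.size:
        x[idx] = rng.uniform(rect[0], rect[2], idx.size)
        y[idx] = rng.uniform(rect[1], rect[3], idx.size)


def simulate_plr_trial(
    latency_ms: float,
    constriction: float,
    baseline_au: float,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    noise_frac: Optional[float] = None,
) -> pd.DataFrame:
    """One pupil-flash trace with the planted analytic latency.

    The diameter is ``baseline - amplitude * S((t - flash - L0)/tau)`` with a
    logistic ``S``; the analytic time of minimum second derivative is
    ``flash + latency_ms`` because ``L0 = latency - tau * u*`` with ``u*`` the
    argmin of the logistic acceleration.
    """
    shape = config.plr
    rate = config.plr_sample_rate_hz
    n_steps = max(2, round(shape.trial_duration_ms / 1000.0 * rate))
    dt = 1000.0 / rate
    t_ms = np.arange(n_steps) * dt
    l0 = latency_ms - LOGISTIC_ACCEL_ARGMIN * shape.tau_ms
    u = (t_ms - shape.flash_ms - l0) / shape.tau_ms
    diam = baseline_au - constriction * baseline_au * expit(u)
    nf = shape.noise_frac if noise_frac is None else noise_frac
    if nf > 0:
        if rng is None:
            raise ValueError("rng required when noise_frac > 0")
        diam = diam + rng.normal(0.0, nf * baseline_au, n_steps)
    return pd.DataFrame({"t_ms": t_ms, "pupil_au": diam})


# ---------------------------------------------------------------------------
# clinical scores
# ---------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal relation between Spearman and Pearson correlation."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_clinical_scores(
    latents: Latents,
    config: SimulationConfig,
    calib: Dict[str, GroupCalibration],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical/demographic table with scores coupled to the face latent.

    Each score is a weighted standardized face latent plus independent noise;
    the weight follows the Gaussian-copula relation, divided by the analytic
    attenuation between the pure latent composite and the realized composite,
    so the population Spearman correlation with the realized composite hits
    the configured target.  Integer-like scores are rounded last.
    """
    n_total = latents.n
    out = pd.DataFrame(
        {
            "participant_id": latents.participant_id,
            "group": latents.group,
            "age_years": np.round(latents.age_years, 3),
            "site": latents.site,
        }
    )
    for spec in config.scores:
        vals = np.empty(n_total)
        noise = rng.standard_normal(n_total)
        for g in GROUPS:
            mask = latents.group == g
            atten = calib[g].omi_attenuation
            rho_p = spearman_to_pearson(spec.rho_target) / atten
            rho_p = float(np.clip(rho_p, -0.999, 0.999))
            zscore = (
                rho_p * latents.latent_composite[mask]
                + math.sqrt(1 - rho_p**2) * noise[mask]
            )
            vals[mask] = spec.mean[g] + spec.sd[g] * zscore
        if spec.bounds is not None:
            vals = np.clip(vals, *spec.bounds)
        if spec.integer:
            vals = np.round(vals)
        out[spec.name] = vals
    if "iq" not in out.columns:
        raise ValueError("score specs must include an 'iq' column")
    return out


def ground_truth_table(
    latents: Latents, config: SimulationConfig
) -> pd.DataFrame:
    """Ground-truth ledger keyed by participant id (one row each)."""
    d: Dict[str, np.ndarray] = {
        "participant_id": latents.participant_id,
        "group": latents.group,
        "site": latents.site,
        "age_years": latents.age_years,
        "dropout_rate": latents.dropout_rate,
        "bad_trial_rate": latents.bad_trial_rate,
        "latent_composite": latents.latent_composite,
        "plr_latency_ms": latents.plr_latency_ms,
        "plr_constriction": latents.plr_constriction,
        "plr_baseline_au": latents.plr_baseline_au,
    }
    for ti, tp in enumerate(config.timepoints):
        for ki, task in enumerate(FACE_TASKS):
            d[f"p_face_{task.value.lower()}_t{tp}"] = latents.p_face[:, ki, ti]
        d[f"p_bio_t{tp}"] = latents.p_bio[:, ti]
        for day in (1, 2):
            d[f"cal_dx_deg_t{tp}_d{day}"] = latents.cal_offset_deg[:, ti, day - 1, 0]
            d[f"cal_dy_deg_t{tp}_d{day}"] = latents.cal_offset_deg[:, ti, day - 1, 1]
    return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# block engine
# ---------------------------------------------------------------------------

def _trial_dropout(
    base: np.ndarray,
    bad_rate: np.ndarray,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-(participant, trial) dropout: participant base rate, with
    occasional high-loss trials."""
    m = base.size
    d = np.tile(base[:, None], (1, n_trials))
    bad = rng.random((m, n_trials)) < bad_rate[:, None]
    d[bad] = rng.uniform(0.55, 0.98, int(bad.sum()))
    return d


def _emit_block(
    config: SimulationConfig,
    battery: BatterySpec,
    task: Task,
    day: int,
    trial_numbers: np.ndarray,
    duration_s: float,
    p_stat: np.ndarray,
    dropout: np.ndarray,
    bad_rate: np.ndarray,
    offsets_px: np.ndarray,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Generate one homogeneous trial block for every participant at once."""
    n_part = p_stat.shape[0]
    n_trials = trial_numbers.size
    n_steps = max(1, round(duration_s * config.sample_rate_hz))
    dt = 1000.0 / config.sample_rate_hz
    m = n_part * n_trials

    p_rows = np.repeat(p_stat, n_trials)
    if config.trial_noise_sd > 0:
        theta = np.log(p_rows / (1 - p_rows))
        theta = theta + rng.normal(0.0, config.trial_noise_sd, m)
        p_rows = expit(theta)
    lam = chain_lambda(config.sample_rate_hz, config.dwell_ms)
    states = simulate_dwell_chain(p_rows, lam, n_steps, rng)

    x = np.empty((m, n_steps))
    y = np.empty((m, n_steps))
    first = battery.lookup(task.value, day, int(trial_numbers[0]))
    rects = _region_rects(first)

    if task == Task.BM:
        bio_left = np.array(
            [
                _region_rects(battery.lookup(task.value, day, int(tn)))["bio"][0]
                < config.screen.width_px / 2
                for tn in trial_numbers
            ]
        )
        left_rect = min((r.coords for r in first.regions), key=lambda c: c[0])
        right_rect = max((r.coords for r in first.regions), key=lambda c: c[0])
        # states True = gaze on the bio side; map to panels via the trial's side
        on_left = states == np.tile(bio_left, n_part)[:, None]
        _fill_rect(x, y, on_left, core_rect(left_rect), rng)
        _fill_rect(x, y, ~on_left, core_rect(right_rect), rng)
    else:
        _fill_rect(x, y, states, core_rect(rects["face"]), rng)
        out = ~states
        n_out = int(out.sum())
        if n_out:
            sub = rng.random(n_out)
            a = config.out_of_face_split.get("activity", 0.0)
            b = config.out_of_face_split.get("body", 0.0)
            flat_idx = np.flatnonzero(out.ravel())
            act = flat_idx[sub < a]
            body = flat_idx[(sub >= a) & (sub < a + b)]
            bg = flat_idx[sub >= a + b]
            xf, yf = x.ravel(), y.ravel()
            if "activity" in rects:
                _fill_rect_at(xf, yf, act, core_rect(rects["activity"]), rng)
            if "body" in rects:
                _fill_rect_at(xf, yf, body, core_rect(rects["body"]), rng)
            bx, by = _sample_background(bg.size, config.screen, list(rects.values()), rng)
            xf[bg], yf[bg] = bx, by
            x = xf.reshape(m, n_steps)
            y = yf.reshape(m, n_steps)

    d_trial = _trial_dropout(dropout, bad_rate, n_trials, rng).reshape(m)
    tracked = rng.random((m, n_steps)) >= d_trial[:, None]

    x = x + np.repeat(offsets_px[:, 0], n_trials)[:, None]
    y = y + np.repeat(offsets_px[:, 1], n_trials)[:, None]
    x[~tracked] = np.nan
    y[~tracked] = np.nan

    part_idx = np.repeat(np.arange(n_part, dtype=np.int32), n_trials * n_steps)
    trial_col = np.tile(np.repeat(trial_numbers.astype(np.int16), n_steps), n_part)
    t_col = np.tile((np.arange(n_steps) * dt).astype(np.float32), m)

    return {
        "participant_idx": part_idx,
        "trial": trial_col,
        "t_ms": t_col,
        "x_px": x.ravel().astype(np.float32),
        "y_px": y.ravel().astype(np.float32),
        "tracked_flag": tracked.ravel().astype(np.int8),
    }


def _emit_validation(
    config: SimulationConfig,
    battery: BatterySpec,
    day: int,
    dropout: np.ndarray,
    offsets_px: np.ndarray,
    rng: np.random.Generator,
) -> List[Dict[str, np.ndarray]]:
    out = []
    n_part = dropout.size
    jitter_px = config.validation_jitter_deg * config.screen.px_per_degree
    n_steps = max(1, round(config.validation_duration_s * config.sample_rate_hz))
    dt = 1000.0 / config.sample_rate_hz
    for i in range(config.validation_trials_per_day):
        trial_roi = battery.lookup(Task.VAL.value, day, i + 1)
        tx, ty = trial_roi.target_px
        x = tx + offsets_px[:, 0:1] + rng.normal(0, jitter_px, (n_part, n_steps))
        y = ty + offsets_px[:, 1:2] + rng.normal(0, jitter_px, (n_part, n_steps))
        tracked = rng.random((n_part, n_steps)) >= dropout[:, None]
        x[~tracked] = np.nan
        y[~tracked] = np.nan
        out.append(
            {
                "participant_idx": np.repeat(
                    np.arange(n_part, dtype=np.int32), n_steps
                ),
                "trial": np.full(n_part * n_steps, i + 1, dtype=np.int16),
                "t_ms": np.tile((np.arange(n_steps) * dt).astype(np.float32), n_part),
                "x_px": x.ravel().astype(np.float32),
                "y_px": y.ravel().astype(np.float32),
                "tracked_flag": tracked.ravel().astype(np.int8),
            }
        )
    return out


def _emit_plr_block(
    config: SimulationConfig,
    trial_numbers: np.ndarray,
    latents: Latents,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    shape = config.plr
    rate = config.plr_sample_rate_hz
    n_part = latents.n
    n_trials = trial_numbers.size
    n_steps = max(2, round(shape.trial_duration_ms / 1000.0 * rate))
    dt = 1000.0 / rate
    m = n_part * n_trials

    lat = np.repeat(latents.plr_latency_ms, n_trials)
    if shape.trial_jitter_sd_ms > 0:
        lat = lat + rng.normal(0.0, shape.trial_jitter_sd_ms, m)
    base = np.repeat(latents.plr_baseline_au, n_trials)
    con = np.repeat(latents.plr_constriction, n_trials)
    l0 = lat - LOGISTIC_ACCEL_ARGMIN * shape.tau_ms

    t = np.arange(n_steps) * dt
    u = (t[None, :] - shape.flash_ms - l0[:, None]) / shape.tau_ms
    diam = base[:, None] * (1.0 - con[:, None] * expit(u))
    if shape.noise_frac > 0:
        diam = diam + rng.normal(0.0, 1.0, (m, n_steps)) * (
            shape.noise_frac * base[:, None]
        )

    # blinks: contiguous gaps
    blink = rng.random(m) < shape.blink_rate
    n_gap = max(1, round(shape.blink_duration_ms / dt))
    starts = rng.integers(0, max(1, n_steps - n_gap), m)
    cols = np.arange(n_steps)[None, :]
    gap = blink[:, None] & (cols >= starts[:, None]) & (cols < (starts + n_gap)[:, None])
    # per-sample dropout at the participant rate
    drop = rng.random((m, n_steps)) < np.repeat(latents.dropout_rate, n_trials)[:, None]
    diam[gap | drop] = np.nan

    part_idx = np.repeat(np.arange(n_part, dtype=np.int32), n_trials * n_steps)
    trial_col = np.tile(np.repeat(trial_numbers.astype(np.int16), n_steps), n_part)
    t_col = np.tile(t.astype(np.float32), m)
    return {
        "participant_idx": part_idx,
        "trial": trial_col,
        "t_ms": t_col,
        "pupil_au": diam.ravel().astype(np.float32),
    }


def _chunk_to_frames(
    config: SimulationConfig,
    latents: Latents,
    tp: int,
    day: int,
    gaze_parts: List[Tuple[Task, Dict[str, np.ndarray]]],
    pupil_parts: List[Dict[str, np.ndarray]],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    id_cat = pd.CategoricalDtype(categories=list(latents.participant_id))
    group_cat = pd.CategoricalDtype(categories=list(GROUPS))
    task_cat = pd.CategoricalDtype(categories=[t.value for t in Task])

    def assemble(parts, with_xy: bool) -> pd.DataFrame:
        frames = []
        for task, cols in parts:
            pid = latents.participant_id[cols["participant_idx"]]
            grp = latents.group[cols["participant_idx"]]
            df = pd.DataFrame(
                {
                    "participant_id": pd.Categorical(pid, dtype=id_cat),
                    "group": pd.Categorical(grp, dtype=group_cat),
                    "timepoint": np.int8(tp),
                    "day": np.int8(day),
                    "task": pd.Categorical(
                        np.full(len(pid), task.value, dtype=object), dtype=task_cat
                    ),
                    "trial": cols["trial"],
                    "t_ms": cols["t_ms"],
                }
            )
            if with_xy:
                df["x_px"] = cols["x_px"]
                df["y_px"] = cols["y_px"]
                df["pupil_au"] = np.float32(np.nan)
                df["tracked_flag"] = cols["tracked_flag"]
            else:
                df["pupil_au"] = cols["pupil_au"]
            frames.append(df)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)

    gaze = assemble(gaze_parts, with_xy=True)
    pupil = assemble([(Task.PLR, c) for c in pupil_parts], with_xy=False)
    return gaze, pupil


def iter_session_chunks(
    config: SimulationConfig,
    calib: Dict[str, GroupCalibration],
    latents: Latents,
    battery: BatterySpec,
    chunk_seeds: Sequence[np.random.SeedSequence],
) -> Iterator[Tuple[int, int, pd.DataFrame, pd.DataFrame]]:
    """Yield (timepoint, day, gaze_df, pupil_df) one session at a time."""
    ppd = config.screen.px_per_degree
    si = 0
    for ti, tp in enumerate(config.timepoints):
        for day in (1, 2):
            rng = np.random.default_rng(chunk_seeds[si])
            si += 1
            offsets_px = latents.cal_offset_deg[:, ti, day - 1, :] * ppd
            gaze_parts: List[Tuple[Task, Dict[str, np.ndarray]]] = []
            pupil_parts: List[Dict[str, np.ndarray]] = []

            for task in (Task.AM, Task.SI, Task.SS, Task.BM, Task.PLR):
                blocks = config.blocks_for(task, day)
                trial_no = 0
                for block in blocks:
                    trial_numbers = np.arange(
                        trial_no + 1, trial_no + block.n_trials + 1
                    )
                    trial_no += block.n_trials
                    if task == Task.PLR:
                        pupil_parts.append(
                            _emit_plr_block(config, trial_numbers, latents, rng)
                        )
                        continue
                    if task == Task.BM:
                        p_stat = latents.p_bio[:, ti]
                    else:
                        ki = FACE_TASKS.index(task)
                        p_stat = latents.p_face[:, ki, ti]
                    gaze_parts.append(
                        (
                            task,
                            _emit_block(
                                config,
                                battery,
                                task,
                                day,
                                trial_numbers,
                                block.duration_s,
                                p_stat,
                                latents.dropout_rate,
                                latents.bad_trial_rate,
                                offsets_px,
                                rng,
                            ),
                        )
                    )

            for cols in _emit_validation(
                config, battery, day, latents.dropout_rate, offsets_px, rng
            ):
                gaze_parts.append((Task.VAL, cols))

            gaze, pupil = _chunk_to_frames(
                config, latents, tp, day, gaze_parts, pupil_parts
            )
            yield tp, day, gaze, pupil


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortTables:
    gaze: pd.DataFrame
    pupil: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    battery: BatterySpec
    latents: Latents
    calibration: Dict[str, GroupCalibration]
    config: SimulationConfig


def prepare_simulation(
    config: SimulationConfig,
) -> Tuple[Dict[str, GroupCalibration], Latents, BatterySpec, List[np.random.SeedSequence]]:
    """Deterministic set-up shared by the eager and streaming paths."""
    root = np.random.SeedSequence(config.seed)
    n_chunks = len(config.timepoints) * 2
    children = root.spawn(3 + n_chunks)
    calib = calibrate(config)
    battery = build_battery_spec(config, np.random.default_rng(children[0]))
    latents = draw_latents(config, calib, np.random.default_rng(children[1]))
    return calib, latents, battery, children


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Generate a full synthetic cohort in memory.

    For cohorts at full study scale prefer the streaming interface
    (:func:`prepare_simulation` + :func:`iter_session_chunks`) which keeps
    only one session of samples in memory.
    """
    calib, latents, battery, children = prepare_simulation(config)
    clinical = simulate_clinical_scores(
        latents, config, calib, np.random.default_rng(children[2])
    )
    gaze_chunks = []
    pupil_chunks = []
    for _tp, _day, gaze, pupil in iter_session_chunks(
        config, calib, latents, battery, children[3:]
    ):
        gaze_chunks.append(gaze)
        pupil_chunks.append(pupil)
    gaze = pd.concat(gaze_chunks, ignore_index=True)
    pupil = pd.concat(pupil_chunks, ignore_index=True)
    return CohortTables(
        gaze=gaze,
        pupil=pupil,
        clinical=clinical,
        ground_truth=ground_truth_table(latents, config),
        battery=battery,
        latents=latents,
        calibration=calib,
        config=config,
    )
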