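"""Moment calibration of the gaze simulator.

The simulator controls three layers of variation in the per-participant task
means: a logit-normal between-participant latent, a two-state Markov dwell
process within trials, and per-sample dropout.  Targets are specified as the
realized mean and SD of per-participant task means (percent scale).  This
module solves for the logit-scale parameters that achieve them:

* ``match_logit_normal`` inverts the first two moments of ``expit(mu + s*Z)``
  by Gauss-Hermite quadrature and a Newton root find;
* ``chain_mean_variance`` gives the exact variance of the time-average of a
  stationary two-state chain, so the trial-sampling ("measurement") variance
  implied by the trial plan can be subtracted from the target variance;
* the trait/state split is inflated so that the configured trait fraction is
  recovered as the intraclass correlation of the *realized* task means, not
  of the noise-free latent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .config import FACE_TASKS, GROUPS, SimulationConfig, Task, TrialBlock

_GH_POINTS = 96
_gh_x, _gh_w = np.polynomial.hermite_e.hermegauss(_GH_POINTS)
_gh_w = _gh_w / _gh_w.sum()


def logit_normal_moments(mu: float, sigma: float) -> Tuple[float, float]:
    """Mean and SD of expit(mu + sigma*Z), Z standard normal (quadrature)."""
    vals = expit(mu + sigma * _gh_x)
    m = float(_gh_w @ vals)
    v = float(_gh_w @ (vals - m) ** 2)
    return m, math.sqrt(max(v, 0.0))


def match_logit_normal(mean: float, sd: float) -> Tuple[float, float]:
    """Solve for (mu, sigma) with expit-transformed moments (mean, sd).

    ``mean`` and ``sd`` are on the fraction scale (0-1).
    """
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    max_sd = math.sqrt(mean * (1 - mean))  # Bernoulli bound
    if not 0 < sd < max_sd:
        raise ValueError(f"sd must lie in (0, {max_sd:.4f}) for mean {mean}")

    def equations(p: np.ndarray) -> List[float]:
        m, s = logit_normal_moments(p[0], math.exp(p[1]))
        return [m - mean, s - sd]

    x0 = np.array([logit(mean), math.log(sd / (mean * (1 - mean)))])
    sol = optimize.root(equations, x0, method="hybr", tol=1e-12)
    resid = np.abs(equations(sol.x)).max()
    if not sol.success or resid > 1e-8:
        raise RuntimeError(f"logit-normal calibration failed for ({mean}, {sd})")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def chain_lambda(sample_rate_hz: float, dwell_ms: float) -> float:
    """Per-step memory of the two-state chain (eigenvalue of its kernel)."""
    dt_ms = 1000.0 / sample_rate_hz
    return math.exp(-dt_ms / dwell_ms)


def chain_mean_variance(p: float, lam: float, n_steps: int) -> float:
    """Exact variance of the time-average of a stationary two-state chain.

    Var(mean of N samples) with Corr(X_i, X_j) = lam**|i-j| and
    Var(X) = p(1-p).
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    n = n_steps
    if lam == 0.0:
        return p * (1 - p) / n
    s = n * (1 + lam) / (1 - lam) - 2 * lam * (1 - lam**n) / (1 - lam) ** 2
    return p * (1 - p) * s / n**2


def task_measurement_variance(
    p: float,
    blocks: List[TrialBlock],
    sample_rate_hz: float,
    dwell_ms: float,
) -> float:
    """Variance (fraction^2) of the unweighted mean of per-trial time-averages
    over every trial the plan administers for one task (all days pooled)."""
    lam = chain_lambda(sample_rate_hz, dwell_ms)
    per_trial = []
    for b in blocks:
        n_steps = max(1, round(b.duration_s * sample_rate_hz))
        per_trial += [chain_mean_variance(p, lam, n_steps)] * b.n_trials
    n = len(per_trial)
    if n == 0:
        raise ValueError("no trials planned for task")
    return float(sum(per_trial)) / n**2


@dataclass(frozen=True)
class TaskCalibration:
    """Solved generative parameters for one group x task."""

    mu: float            # logit-scale location
    sigma: float         # logit-scale between-participant SD
    f_z: float           # trait fraction on the latent scale (inflated)
    target_mean: float   # fraction scale
    target_sd: float     # fraction scale (realized, incl. trial sampling)
    latent_sd: float     # fraction scale SD attributable to the latent
    v_meas: float        # trial-sampling variance of the task mean


@dataclass(frozen=True)
class GroupCalibration:
    face: Dict[Task, TaskCalibration]
    bio: TaskCalibration
    cross_task_corr: float
    #: corr between the linearized composite latent and the realized composite
    omi_attenuation: float
    omi_latent_sds: Dict[Task, float] = field(default_factory=dict)


def _calibrate_task(
    mean_pct: float,
    sd_pct: float,
    v_meas: float,
    trait_fraction: float,
) -> TaskCalibration:
    m = mean_pct / 100.0
    s_tot = sd_pct / 100.0
    s2_lat = s_tot**2 - v_meas
    if s2_lat < 0.2 * s_tot**2:
        warnings.warn(
            "trial-sampling variance dominates the target SD; "
            "latent variance floored at 20% of target",
            stacklevel=2,
        )
        s2_lat = 0.2 * s_tot**2
    s_lat = math.sqrt(s2_lat)
    mu, sigma = match_logit_normal(m, s_lat)
    f_z = trait_fraction * s_tot**2 / s2_lat
    if f_z > 1.0:
        warnings.warn(
            "requested trait fraction unattainable at this trial plan; "
            "clamping latent trait fraction to 1",
            stacklevel=2,
        )
        f_z = 1.0
    return TaskCalibration(
        mu=mu,
        sigma=sigma,
        f_z=f_z,
        target_mean=m,
        target_sd=s_tot,
        latent_sd=s_lat,
        v_meas=v_meas,
    )


def _solve_cross_task_corr(
    tasks: Dict[Task, TaskCalibration], omi_sd_target: float
) -> float:
    """Choose the cross-task correlation of the face latents so the
    linearized composite variance matches the target composite SD.

    The shared component is identical across tasks (same trait/state split as
    the target), so the same-timepoint cross-task covariance of the latents
    is exactly ``c * sd_k * sd_k'``.
    """
    ks = list(tasks)
    v_target = (omi_sd_target / 100.0) ** 2
    own = sum(t.latent_sd**2 + t.v_meas for t in tasks.values())
    cross = 0.0
    for i, ki in enumerate(ks):
        for kj in ks[i + 1 :]:
            cross += 2 * tasks[ki].latent_sd * tasks[kj].latent_sd
    if cross <= 0:
        return 1.0
    c = (9.0 * v_target - own) / cross
    return float(min(max(c, 0.0), 1.0))


def task_unique_trait_fraction(f_z: float, c: float, trait_fraction: float) -> float:
    """Trait fraction of the task-unique latent component.

    The shared (cross-task) component carries the *target* trait fraction so
    cross-task covariance terms keep the target stability ratio; the
    task-unique component absorbs the inflation needed for the per-task
    realized ICC: c*f + (1-c)*f_unique = f_z.
    """
    if c >= 1.0:
        return trait_fraction
    f_unique = (f_z - c * trait_fraction) / (1.0 - c)
    if not 0.0 <= f_unique <= 1.0:
        warnings.warn(
            "task-unique trait fraction clamped to [0, 1]; per-task ICC will "
            "deviate slightly from the configured trait fraction",
            stacklevel=2,
        )
        f_unique = min(max(f_unique, 0.0), 1.0)
    return f_unique


def calibrate(config: SimulationConfig) -> Dict[str, GroupCalibration]:
    """Solve generative parameters for every group from the configured targets."""
    out: Dict[str, GroupCalibration] = {}
    for g in GROUPS:
        gp = config.groups[g]
        face: Dict[Task, TaskCalibration] = {}
        for task in FACE_TASKS:
            mean_pct, sd_pct = gp.face_pct_targets[task]
            v = task_measurement_variance(
                mean_pct / 100.0,
                config.blocks_for(task),
                config.sample_rate_hz,
                config.dwell_ms,
            )
            face[task] = _calibrate_task(
                mean_pct, sd_pct, v, config.trait_variance_fraction
            )
        bm_mean, bm_sd = gp.bio_pct_target
        v_bio = task_measurement_variance(
            bm_mean / 100.0,
            config.blocks_for(Task.BM),
            config.sample_rate_hz,
            config.dwell_ms,
        )
        bio = _calibrate_task(bm_mean, bm_sd, v_bio, config.trait_variance_fraction)

        if config.cross_task_corr is not None:
            c = config.cross_task_corr
        else:
            c = _solve_cross_task_corr(face, gp.omi_sd_target)

        # composite = mean of the three task values; attenuation of its
        # correlation with the pure latent composite due to trial sampling
        v_meas_omi = sum(t.v_meas for t in face.values()) / 9.0
        v_lat_omi = (gp.omi_sd_target / 100.0) ** 2 - v_meas_omi
        if v_lat_omi <= 0:
            atten = 0.5
        else:
            atten = math.sqrt(v_lat_omi / (v_lat_omi + v_meas_omi))

        out[g] = GroupCalibration(
            face=face,
            bio=bio,
            cross_task_corr=c,
            omi_attenuation=atten,
            omi_latent_sds={k: t.latent_sd for k, t in face.items()},
        )
    return out
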