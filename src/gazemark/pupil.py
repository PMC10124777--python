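"""Pupil-flash response metrics: preprocessing, latency, relative constriction.

Latency is the time from flash onset to the minimum of the discrete second
derivative ("acceleration") of the smoothed diameter series; constriction is
the relative drop from the pre-flash baseline mean to the post-flash minimum.
Trial-level validity combines coverage, latency-range, and constriction-range
rules (the four-part rule is this package's definition; see the docs).

All operations are implemented on trace matrices (n_traces, n_samples) so the
derivation stage can process thousands of trials at once; the public
single-trace functions are one-row wrappers over the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter


@dataclass(frozen=True)
class PupilParams:
    """Tunable preprocessing/estimation parameters.

    The acceleration series for the latency estimate comes from a
    Savitzky-Golay second-derivative filter rather than plain central
    differences: the curvature extremum of the reflex is shallow, and a
    one-sample second difference at high sampling rates is swamped by even
    sub-percent measurement noise.
    """

    smooth_ms: float = 20.0
    sg_window_ms: float = 201.0
    sg_poly: int = 4
    constriction_smooth_ms: float = 150.0
    search_window_ms: float = 1000.0
    min_coverage: float = 0.5
    artifact_jump_frac: float = 0.10  # |step| > frac * median diameter => artifact


@dataclass
class PupilTrace:
    """A preprocessed, uniformly sampled pupil-diameter series."""

    t_ms: np.ndarray
    diameter: np.ndarray
    flash_ms: float
    baseline_window: Tuple[float, float]
    valid: bool = True
    n_interpolated: int = 0
    coverage_baseline: float = 1.0
    coverage_response: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_window[1] > self.flash_ms:
            raise ValueError("baseline window must precede the flash")
        dt = np.diff(self.t_ms)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace must be uniformly sampled")


# ---------------------------------------------------------------------------
# batch implementations
# ---------------------------------------------------------------------------

def _smooth_kernel_size(smooth_ms: float, dt_ms: float) -> int:
    k = max(1, round(smooth_ms / dt_ms))
    return k if k % 2 else k + 1


def preprocess_matrix(
    diam: np.ndarray,
    t_ms: np.ndarray,
    flash_ms: float,
    params: PupilParams = PupilParams(),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clean, interpolate, and smooth trace rows.

    Returns ``(smoothed, valid, n_interp, cov_base, cov_resp)``.  A row is
    valid when at least ``min_coverage`` of both the baseline window and the
    post-flash response window carry usable samples.
    """
    diam = np.array(diam, dtype=float)
    if diam.ndim == 1:
        diam = diam[None, :]
    dt = float(t_ms[1] - t_ms[0])

    missing = ~np.isfinite(diam) | (diam <= 0)
    diam[missing] = np.nan

    # physiologically implausible per-sample jumps: kill both endpoints
    med = np.nanmedian(diam, axis=1, keepdims=True)
    med = np.where(np.isfinite(med) & (med > 0), med, 1.0)
    step = np.abs(np.diff(diam, axis=1))
    jump = step > params.artifact_jump_frac * med
    artifact = np.zeros_like(diam, dtype=bool)
    artifact[:, :-1] |= jump
    artifact[:, 1:] |= jump
    diam[artifact] = np.nan
    missing = ~np.isfinite(diam)

    base_mask = t_ms < flash_ms
    resp_mask = (t_ms > flash_ms) & (t_ms <= flash_ms + params.search_window_ms)
    cov_base = 1.0 - missing[:, base_mask].mean(axis=1)
    cov_resp = 1.0 - missing[:, resp_mask].mean(axis=1)
    valid = (cov_base >= params.min_coverage) & (cov_resp >= params.min_coverage)
    n_interp = missing.sum(axis=1)

    filled = (
        pd.DataFrame(diam)
        .interpolate(axis=1, limit_direction="both")
        .to_numpy()
    )
    filled = np.nan_to_num(filled, nan=0.0)

    k = _smooth_kernel_size(params.smooth_ms, dt)
    smoothed = uniform_filter1d(filled, size=k, axis=1, mode="nearest")
    return smoothed, valid, n_interp, cov_base, cov_resp


def latency_matrix(
    smoothed: np.ndarray,
    t_ms: np.ndarray,
    flash_ms: float,
    params: PupilParams = PupilParams(),
) -> np.ndarray:
    """Per-row latency (ms from flash) of the acceleration minimum.

    Savitzky-Golay second derivative, discrete argmin inside the post-flash
    search window, then parabolic sub-sample refinement.  Rows whose minimum
    sits on the window boundary (no interior acceleration minimum) get NaN.
    """
    dt = float(t_ms[1] - t_ms[0])
    k = max(params.sg_poly + 2, round(params.sg_window_ms / dt))
    k += 1 - k % 2
    k = min(k, smoothed.shape[1] - (1 - smoothed.shape[1] % 2))
    if k <= params.sg_poly:
        return np.full(smoothed.shape[0], np.nan)
    d2 = savgol_filter(
        smoothed, k, params.sg_poly, deriv=2, delta=dt, axis=1, mode="nearest"
    )
    in_window = (t_ms > flash_ms) & (t_ms <= flash_ms + params.search_window_ms)
    idx = np.flatnonzero(in_window)
    idx = idx[(idx >= 1) & (idx <= len(t_ms) - 2)]
    if idx.size < 3:
        return np.full(smoothed.shape[0], np.nan)
    seg = d2[:, idx]
    arg = np.argmin(seg, axis=1)
    lat = t_ms[idx[arg]] - flash_ms
    # parabolic refinement around the discrete minimum
    rows = np.arange(seg.shape[0])
    interior = (arg > 0) & (arg < seg.shape[1] - 1)
    ai = np.clip(arg, 1, seg.shape[1] - 2)
    left = seg[rows, ai - 1]
    mid = seg[rows, ai]
    right = seg[rows, ai + 1]
    denom = left - 2 * mid + right
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 0, 0.5 * (left - right) / denom, 0.0)
    delta = np.clip(np.nan_to_num(delta), -1.0, 1.0)
    lat = np.where(interior, lat + delta * dt, np.nan)
    return lat


def constriction_matrix(
    smoothed: np.ndarray,
    t_ms: np.ndarray,
    flash_ms: float,
    baseline_window: Tuple[float, float],
    params: PupilParams = PupilParams(),
) -> np.ndarray:
    """Per-row relative constriction (baseline - post-flash min) / baseline.

    The post-flash minimum is taken on an extra-smoothed copy of the trace so
    that the pointwise minimum of residual noise does not inflate the
    estimate; the result is invariant to rescaling the diameter.
    """
    dt = float(t_ms[1] - t_ms[0])
    base_mask = (t_ms >= baseline_window[0]) & (t_ms < baseline_window[1])
    post_mask = t_ms > flash_ms  # full post-flash segment (reflex plateau)
    k = max(1, round(params.constriction_smooth_ms / dt))
    k += 1 - k % 2
    extra = uniform_filter1d(smoothed, size=k, axis=1, mode="nearest")
    base = extra[:, base_mask].mean(axis=1)
    low = extra[:, post_mask].min(axis=1)
    out = (base - low) / base
    out[base <= 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# single-trace API
# ---------------------------------------------------------------------------

def preprocess_trace(
    t_ms: np.ndarray,
    diameter: np.ndarray,
    flash_ms: float,
    baseline_window: Optional[Tuple[float, float]] = None,
    params: PupilParams = PupilParams(),
) -> PupilTrace:
    """Clean one raw trace: artifacts removed, gaps interpolated, smoothed."""
    t_ms = np.asarray(t_ms, dtype=float)
    if baseline_window is None:
        baseline_window = (float(t_ms[0]), float(flash_ms))
    smoothed, valid, n_interp, cov_b, cov_r = preprocess_matrix(
        np.asarray(diameter, dtype=float), t_ms, flash_ms, params
    )
    return PupilTrace(
        t_ms=t_ms,
        diameter=smoothed[0],
        flash_ms=float(flash_ms),
        baseline_window=baseline_window,
        valid=bool(valid[0]),
        n_interpolated=int(n_interp[0]),
        coverage_baseline=float(cov_b[0]),
        coverage_response=float(cov_r[0]),
    )


def plr_latency(trace: PupilTrace, params: PupilParams = PupilParams()) -> float:
    """Latency (ms) from flash to the minimum of the diameter acceleration."""
    return float(
        latency_matrix(trace.diameter[None, :], trace.t_ms, trace.flash_ms, params)[0]
    )


def plr_constriction(trace: PupilTrace, params: PupilParams = PupilParams()) -> float:
    """Relative constriction of the diameter from baseline. Scale-invariant."""
    return float(
        constriction_matrix(
            trace.diameter[None, :],
            trace.t_ms,
            trace.flash_ms,
            trace.baseline_window,
            params,
        )[0]
    )


def plr_trial_valid(
    trace: PupilTrace,
    latency_ms: Optional[float] = None,
    constriction: Optional[float] = None,
    params: PupilParams = PupilParams(),
) -> bool:
    """Four-part validity: coverage in both windows, latency in the search
    window, constriction strictly inside (0, 1)."""
    if latency_ms is None:
        latency_ms = plr_latency(trace, params)
    if constriction is None:
        constriction = plr_constriction(trace, params)
    return bool(
        trace.coverage_baseline >= params.min_coverage
        and trace.coverage_response >= params.min_coverage
        and np.isfinite(latency_ms)
        and 0 < latency_ms <= params.search_window_ms
        and np.isfinite(constriction)
        and 0 < constriction < 1
    )
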