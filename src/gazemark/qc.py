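"""Quality-control gating, participant-level aggregation, the face-gaze
composite (OMI), and acquisition reporting.

Gating rules (all thresholds configurable, boundaries inclusive):

* a trial is valid when tracked-on-screen time >= 50% of stimulus time AND
  calibration error <= 2.5 degrees (pupil trials must additionally pass the
  pupil shape-validity rule);
* flagged sessions (counterbalancing error, malfunction, non-standardized
  cueing) lose all their trials before aggregation;
* a participant's task at a timepoint is valid when >= 25% of administered
  trials are valid; derived means use valid trials only;
* the composite is valid only when all three constituent tasks are valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import FACE_TASKS, GROUPS, Task, Thresholds

logger = logging.getLogger(__name__)

OMI_LABEL = "OMI"
SUMMARY_KEYS = ["participant_id", "group", "timepoint", "task"]


def apply_session_invalidations(
    trials: pd.DataFrame, session_flags: Optional[pd.DataFrame]
) -> pd.Series:
    """Boolean mask (aligned with ``trials``): True = session invalidated.

    ``session_flags`` has columns participant_id, timepoint, day and
    optionally reason; missing/None means no invalidations.
    """
    if session_flags is None or len(session_flags) == 0:
        return pd.Series(False, index=trials.index)
    flags = session_flags[["participant_id", "timepoint", "day"]].drop_duplicates()
    flags = flags.assign(_flagged=True)
    merged = trials[["participant_id", "timepoint", "day"]].merge(
        flags, on=["participant_id", "timepoint", "day"], how="left"
    )
    mask = merged["_flagged"].notna().to_numpy()
    n = int(mask.sum())
    if n:
        logger.info("session invalidation: %d trials removed (reason=flagged)", n)
    return pd.Series(mask, index=trials.index)


def trial_valid(
    trials: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    session_flags: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Vectorized trial gate. Missing calibration error counts as invalid
    (the derivation stage already applied the session-level fallback)."""
    pvd = trials["pct_valid_data"].to_numpy(dtype=float)
    cal = trials["cal_error_deg"].to_numpy(dtype=float)
    ok = (pvd >= thresholds.valid_data_pct) & (cal <= thresholds.cal_error_deg)
    is_plr = (trials["task"] == Task.PLR.value).to_numpy()
    if is_plr.any():
        shape_ok = trials["plr_shape_valid"].to_numpy(dtype=float) == 1.0
        lat = trials["latency_ms"].to_numpy(dtype=float)
        window_ok = np.isfinite(lat) & (lat > 0) & (
            lat <= thresholds.plr_latency_window_ms
        )
        ok = np.where(is_plr, ok & shape_ok & window_ok, ok)
    invalidated = apply_session_invalidations(trials, session_flags).to_numpy()
    ok = ok & ~invalidated
    for reason, mask in (
        ("low_valid_data", pvd < thresholds.valid_data_pct),
        ("high_cal_error", ~(cal <= thresholds.cal_error_deg)),
        ("session_flag", invalidated),
    ):
        n = int(mask.sum())
        if n:
            logger.info("gating: %d trials fail (%s)", n, reason)
    return pd.Series(ok, index=trials.index, name="trial_valid")


def gate_trials(
    trials: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    session_flags: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    out = trials.copy()
    out["trial_valid"] = trial_valid(trials, thresholds, session_flags)
    return out


def summarize_task(
    gated_trials: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Participant x timepoint x task summaries over gated trials.

    Derived means are over valid trials only; the undefined preference
    percentage (no bio/control gaze) is excluded from its mean; acquisition
    metrics (%Valid Data, Cal Error) average over all administered trials.
    """
    if "trial_valid" not in gated_trials.columns:
        raise ValueError("trials must be gated first (missing trial_valid column)")
    t = gated_trials
    valid = t["trial_valid"].to_numpy(dtype=bool)

    def masked(col: str, mask: np.ndarray) -> pd.Series:
        return pd.Series(
            np.where(mask, t[col].to_numpy(dtype=float), np.nan), index=t.index
        )

    work = pd.DataFrame({k: t[k] for k in SUMMARY_KEYS})
    work["n_total_trials"] = 1
    work["n_valid_trials"] = valid.astype(int)
    work["any_data"] = (t["pct_valid_data"].to_numpy(dtype=float) > 0).astype(int)
    work["pct_valid_data"] = t["pct_valid_data"].astype(float)
    work["cal_error_deg"] = t["cal_error_deg"].astype(float)
    for col in (
        "pct_face",
        "pct_activity",
        "pct_body",
        "pct_social",
        "pct_bio",
        "latency_ms",
        "constriction",
    ):
        work[col] = masked(col, valid)
    affective = t["affective_flag"].to_numpy(dtype=float) == 1.0
    work["pct_bio_affect"] = masked("pct_bio", valid & affective)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        summary = (
            work.groupby(SUMMARY_KEYS, observed=True, sort=True)
            .agg(
                n_total_trials=("n_total_trials", "sum"),
                n_valid_trials=("n_valid_trials", "sum"),
                any_data=("any_data", "max"),
                mean_pct_valid_data=("pct_valid_data", "mean"),
                mean_cal_error_deg=("cal_error_deg", "mean"),
                pct_face=("pct_face", "mean"),
                pct_activity=("pct_activity", "mean"),
                pct_body=("pct_body", "mean"),
                pct_social=("pct_social", "mean"),
                pct_bio=("pct_bio", "mean"),
                pct_bio_affect=("pct_bio_affect", "mean"),
                latency_ms=("latency_ms", "mean"),
                constriction=("constriction", "mean"),
            )
            .reset_index()
        )
    summary["pct_valid_trials"] = (
        100.0 * summary["n_valid_trials"] / summary["n_total_trials"]
    )
    summary["task_valid"] = (
        (summary["n_total_trials"] > 0)
        & (summary["pct_valid_trials"] >= thresholds.valid_trials_pct)
    )
    return summary


def battery_valid_data(gated_trials: pd.DataFrame) -> pd.DataFrame:
    """Battery-wide %Valid Data per participant-timepoint (covariate)."""
    return (
        gated_trials.groupby(
            ["participant_id", "group", "timepoint"], observed=True
        )["pct_valid_data"]
        .mean()
        .rename("pct_valid_data")
        .reset_index()
    )


def compute_omi(summaries: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight composite of the three face tasks' %Face.

    Valid only when every constituent task is valid; the value is absent
    (NaN) otherwise.
    """
    face = summaries[summaries["task"].isin([t.value for t in FACE_TASKS])]
    piv_face = face.pivot_table(
        index=["participant_id", "group", "timepoint"],
        columns="task",
        values="pct_face",
        observed=True,
    )
    piv_valid = face.pivot_table(
        index=["participant_id", "group", "timepoint"],
        columns="task",
        values="task_valid",
        aggfunc="first",
        observed=True,
    )
    tasks = [t.value for t in FACE_TASKS]
    for t in tasks:
        if t not in piv_face.columns:
            piv_face[t] = np.nan
        if t not in piv_valid.columns:
            piv_valid[t] = False
    omi_valid = piv_valid[tasks].fillna(False).astype(bool).all(axis=1)
    omi = piv_face[tasks].mean(axis=1)
    omi[~omi_valid] = np.nan
    out = pd.DataFrame(
        {"omi": omi, "omi_valid": omi_valid}
    ).reset_index()
    return out


def omi_value(am_pct_face: float, si_pct_face: float, ss_pct_face: float) -> float:
    """Unweighted mean of exactly three task-level %Face values."""
    return float(np.mean([am_pct_face, si_pct_face, ss_pct_face]))


def build_biomarker_table(
    summaries: pd.DataFrame,
    omi: pd.DataFrame,
    clinical: pd.DataFrame,
    gated_trials: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Wide participant x timepoint table feeding the psychometric battery."""
    value_map = {
        Task.AM.value: [("pct_face", "am_pct_face"), ("pct_activity", "am_pct_activity")],
        Task.SI.value: [("pct_face", "si_pct_face"), ("pct_social", "si_pct_social")],
        Task.SS.value: [("pct_face", "ss_pct_face"), ("pct_social", "ss_pct_social")],
        Task.BM.value: [("pct_bio", "bm_pct_bio"), ("pct_bio_affect", "bm_pct_bio_affect")],
        Task.PLR.value: [("latency_ms", "plr_latency_ms"), ("constriction", "plr_constriction")],
    }
    idx = ["participant_id", "group", "timepoint"]
    wide = omi.set_index(idx)
    for task, pairs in value_map.items():
        sub = summaries[summaries["task"] == task].set_index(idx)
        if sub.empty:
            continue
        for src, dst in pairs:
            vals = sub[src].copy()
            vals[~sub["task_valid"]] = np.nan
            wide[dst] = vals
        wide[f"{task.lower()}_valid"] = sub["task_valid"]
    if gated_trials is not None:
        bw = battery_valid_data(gated_trials).set_index(idx)
        wide["pct_valid_data"] = bw["pct_valid_data"]
    wide = wide.reset_index()
    clin_cols = [c for c in clinical.columns if c != "group"]
    wide = wide.merge(clinical[clin_cols], on="participant_id", how="left")
    return wide


# ---------------------------------------------------------------------------
# acquisition reporting
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionReport:
    table: pd.DataFrame
    group_tests: pd.DataFrame
    site_tests: pd.DataFrame


def _chi2_2xk(counts: np.ndarray) -> Dict[str, float]:
    """Plain chi-square on a contingency table, with a small-expected-count
    warning instead of a Monte-Carlo fallback."""
    counts = np.asarray(counts, dtype=float)
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
        return {"chi2": np.nan, "p": np.nan, "df": np.nan}
    res = stats.chi2_contingency(counts, correction=False)
    expected = res.expected_freq
    if (expected < 5).any():
        warnings.warn("chi-square cells with expected count < 5", stacklevel=2)
    return {"chi2": float(res.statistic), "p": float(res.pvalue), "df": float(res.dof)}


def chi_square_validity(valid: Iterable[bool], category: Iterable) -> Dict[str, float]:
    """Chi-square test of validity rates across the levels of a category."""
    valid = np.asarray(list(valid), dtype=bool)
    category = np.asarray(list(category))
    levels = np.unique(category)
    counts = np.array(
        [
            [np.sum(valid & (category == lv)) for lv in levels],
            [np.sum(~valid & (category == lv)) for lv in levels],
        ]
    )
    return _chi2_2xk(counts)


def acquisition_report(
    summaries: pd.DataFrame,
    omi: pd.DataFrame,
    clinical: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    timepoint: int = 1,
) -> AcquisitionReport:
    """Acquisition and validity rates per group x task, with chi-square tests
    for group and site differences and the suitability benchmark flag."""
    s = summaries[summaries["timepoint"] == timepoint]
    o = omi[omi["timepoint"] == timepoint]
    clin = clinical.set_index("participant_id")
    tasks = [t.value for t in Task if t != Task.VAL] + [OMI_LABEL]

    rows: List[dict] = []
    group_tests: List[dict] = []
    site_tests: List[dict] = []
    for task in tasks:
        if task == OMI_LABEL:
            per_part = o.rename(columns={"omi_valid": "signal_valid"})[
                ["participant_id", "group", "signal_valid"]
            ].copy()
            face = s[s["task"].isin([t.value for t in FACE_TASKS])]
            acq = face.groupby("participant_id", observed=True)["any_data"].min()
            per_part["acquisition_valid"] = (
                per_part["participant_id"].map(acq).fillna(0).astype(bool)
            )
            extra: Dict[str, float] = {}
        else:
            sub = s[s["task"] == task]
            if sub.empty:
                warnings.warn(f"no data for task {task}; omitted from report")
                continue
            per_part = pd.DataFrame(
                {
                    "participant_id": sub["participant_id"],
                    "group": sub["group"],
                    "signal_valid": sub["task_valid"].to_numpy(dtype=bool),
                    "acquisition_valid": sub["any_data"].to_numpy(dtype=bool),
                }
            )
            extra = {
                "mean_pct_valid_trials": float(sub["pct_valid_trials"].mean()),
                "mean_pct_valid_data": float(sub["mean_pct_valid_data"].mean()),
                "mean_cal_error_deg": float(sub["mean_cal_error_deg"].mean()),
            }
        per_part["site"] = per_part["participant_id"].map(clin["site"])

        for g in GROUPS:
            gp = per_part[per_part["group"] == g]
            n = len(gp)
            if n == 0:
                warnings.warn(f"empty group {g} for task {task}; omitted")
                continue
            sig_pct = 100.0 * gp["signal_valid"].mean()
            rows.append(
                {
                    "group": g,
                    "task": task,
                    "n": n,
                    "acquisition_valid_n": int(gp["acquisition_valid"].sum()),
                    "acquisition_valid_pct": 100.0 * gp["acquisition_valid"].mean(),
                    "signal_valid_n": int(gp["signal_valid"].sum()),
                    "signal_valid_pct": sig_pct,
                    "benchmark_pass": bool(sig_pct > thresholds.benchmark_pct),
                    **extra,
                }
            )
            site_tests.append(
                {
                    "group": g,
                    "task": task,
                    **chi_square_validity(gp["signal_valid"], gp["site"]),
                }
            )
        group_tests.append(
            {
                "task": task,
                **chi_square_validity(per_part["signal_valid"], per_part["group"]),
            }
        )

    return AcquisitionReport(
        table=pd.DataFrame(rows),
        group_tests=pd.DataFrame(group_tests),
        site_tests=pd.DataFrame(site_tests),
    )
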