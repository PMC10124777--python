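import numpy as np
import pandas as pd
import pytest

from gazemark.config import Thresholds
from gazemark.qc import (
    acquisition_report,
    apply_session_invalidations,
    chi_square_validity,
    compute_omi,
    gate_trials,
    omi_value,
    summarize_task,
    trial_valid,
)


def _trial_rows(rows):
    defaults = {
        "participant_id": "ASD0001",
        "group": "ASD",
        "timepoint": 1,
        "day": 1,
        "task": "AM",
        "trial": 1,
        "pct_valid_data": 100.0,
        "cal_error_deg": 0.5,
        "pct_face": 20.0,
        "pct_activity": 10.0,
        "pct_body": 5.0,
        "pct_social": 35.0,
        "pct_bio": np.nan,
        "bio_ms": 0.0,
        "control_ms": 0.0,
        "affective_flag": 0.0,
        "latency_ms": np.nan,
        "constriction": np.nan,
        "plr_shape_valid": np.nan,
    }
    out = []
    for i, r in enumerate(rows):
        row = dict(defaults)
        row["trial"] = i + 1
        row.update(r)
        out.append(row)
    return pd.DataFrame(out)


class TestTrialGate:
    def test_boundary_inclusive(self):
        t = _trial_rows([{"pct_valid_data": 50.0, "cal_error_deg": 2.5}])
        assert trial_valid(t).iloc[0]

    def test_low_valid_data_invalid(self):
        t = _trial_rows([{"pct_valid_data": 49.9, "cal_error_deg": 0.1}])
        assert not trial_valid(t).iloc[0]

    def test_high_cal_error_invalid(self):
        t = _trial_rows([{"pct_valid_data": 100.0, "cal_error_deg": 2.6}])
        assert not trial_valid(t).iloc[0]

    def test_missing_cal_error_invalid(self):
        t = _trial_rows([{"cal_error_deg": np.nan}])
        assert not trial_valid(t).iloc[0]

    def test_plr_needs_shape_validity(self):
        rows = [
            {"task": "PLR", "plr_shape_valid": 1.0, "latency_ms": 300.0,
             "constriction": 0.5},
            {"task": "PLR", "plr_shape_valid": 0.0, "latency_ms": 300.0,
             "constriction": 0.5},
        ]
        v = trial_valid(_trial_rows(rows))
        assert v.iloc[0] and not v.iloc[1]

    def test_gating_monotone_in_thresholds(self):
        t = _trial_rows(
            [
                {"pct_valid_data": pv, "cal_error_deg": ce}
                for pv in (30, 50, 70, 90)
                for ce in (0.5, 2.0, 3.0)
            ]
        )
        strict = trial_valid(t, Thresholds(valid_data_pct=60, cal_error_deg=1.0)).sum()
        relaxed = trial_valid(t, Thresholds(valid_data_pct=50, cal_error_deg=2.5)).sum()
        assert relaxed >= strict

    def test_idempotent(self):
        t = _trial_rows([{"pct_valid_data": 80.0}, {"pct_valid_data": 20.0}])
        g1 = gate_trials(t)
        g2 = gate_trials(g1.drop(columns=["trial_valid"]))
        assert g1["trial_valid"].equals(g2["trial_valid"])


class TestSessionInvalidation:
    def test_flagged_day_excluded_other_kept(self):
        rows = [{"day": 1}, {"day": 1}, {"day": 2}, {"day": 2}]
        t = _trial_rows(rows)
        flags = pd.DataFrame(
            [{"participant_id": "ASD0001", "timepoint": 1, "day": 1}]
        )
        v = trial_valid(t, session_flags=flags)
        assert list(v) == [False, False, True, True]

    def test_no_flags_identity(self):
        t = _trial_rows([{}, {}])
        assert apply_session_invalidations(t, None).sum() == 0
        assert apply_session_invalidations(t, pd.DataFrame()).sum() == 0

    def test_both_days_flagged_task_invalid(self):
        rows = [{"day": 1}, {"day": 2}]
        t = _trial_rows(rows)
        flags = pd.DataFrame(
            [
                {"participant_id": "ASD0001", "timepoint": 1, "day": 1},
                {"participant_id": "ASD0001", "timepoint": 1, "day": 2},
            ]
        )
        gated = gate_trials(t, session_flags=flags)
        summary = summarize_task(gated)
        assert not summary["task_valid"].iloc[0]
        assert summary["n_valid_trials"].iloc[0] == 0


class TestSummaries:
    def test_25_percent_rule_threshold_arithmetic(self):
        # 54 trials: 13 valid (24.1%) -> invalid; 14 valid (25.9%) -> valid
        for n_valid, expect in ((13, False), (14, True)):
            rows = [
                {"pct_valid_data": 100.0 if i < n_valid else 0.0}
                for i in range(54)
            ]
            summary = summarize_task(gate_trials(_trial_rows(rows)))
            assert bool(summary["task_valid"].iloc[0]) is expect

    def test_exact_boundary_inclusive(self):
        rows = [{"pct_valid_data": 100.0 if i < 1 else 0.0} for i in range(4)]
        summary = summarize_task(gate_trials(_trial_rows(rows)))
        assert summary["pct_valid_trials"].iloc[0] == 25.0
        assert bool(summary["task_valid"].iloc[0])

    def test_mean_over_valid_trials_only(self):
        rows = [
            {"pct_face": 20.0},
            {"pct_face": 30.0},
            {"pct_face": 90.0, "pct_valid_data": 10.0},  # invalid trial
        ]
        summary = summarize_task(gate_trials(_trial_rows(rows)))
        assert summary["pct_face"].iloc[0] == pytest.approx(25.0)

    def test_undefined_bio_excluded_from_mean(self):
        rows = [
            {"task": "BM", "pct_bio": 60.0},
            {"task": "BM", "pct_bio": np.nan},  # no bio/control gaze
            {"task": "BM", "pct_bio": 40.0},
        ]
        summary = summarize_task(gate_trials(_trial_rows(rows)))
        assert summary["pct_bio"].iloc[0] == pytest.approx(50.0)

    def test_cal_error_averaged_over_all_trials(self):
        rows = [
            {"cal_error_deg": 1.0},
            {"cal_error_deg": 3.0, "pct_valid_data": 10.0},  # invalid trial
        ]
        summary = summarize_task(gate_trials(_trial_rows(rows)))
        assert summary["mean_cal_error_deg"].iloc[0] == pytest.approx(2.0)

    def test_bio_affect_restricted_to_affective_trials(self):
        rows = [
            {"task": "BM", "pct_bio": 80.0, "affective_flag": 1.0},
            {"task": "BM", "pct_bio": 20.0, "affective_flag": 0.0},
        ]
        summary = summarize_task(gate_trials(_trial_rows(rows)))
        assert summary["pct_bio_affect"].iloc[0] == pytest.approx(80.0)
        assert summary["pct_bio"].iloc[0] == pytest.approx(50.0)


def _summary_rows(spec):
    rows = []
    for task, pct_face, valid in spec:
        rows.append(
            {
                "participant_id": "ASD0001",
                "group": "ASD",
                "timepoint": 1,
                "task": task,
                "n_total_trials": 10,
                "n_valid_trials": 8 if valid else 1,
                "any_data": 1,
                "mean_pct_valid_data": 90.0,
                "mean_cal_error_deg": 0.5,
                "pct_face": pct_face,
                "pct_activity": np.nan,
                "pct_body": np.nan,
                "pct_social": np.nan,
                "pct_bio": np.nan,
                "pct_bio_affect": np.nan,
                "latency_ms": np.nan,
                "constriction": np.nan,
                "pct_valid_trials": 80.0 if valid else 10.0,
                "task_valid": valid,
            }
        )
    return pd.DataFrame(rows)


class TestOmi:
    def test_simple_mean(self):
        assert omi_value(20.0, 25.0, 30.0) == 25.0

    def test_compute_omi_all_valid(self):
        s = _summary_rows([("AM", 20.0, True), ("SI", 25.0, True), ("SS", 30.0, True)])
        omi = compute_omi(s)
        assert omi["omi"].iloc[0] == pytest.approx(25.0)
        assert omi["omi_valid"].iloc[0]

    def test_td_table_worked_example(self):
        # reference task means 27.6 / 30.4 / 34.9 average to the reference
        # composite mean up to rounding
        s = _summary_rows([("AM", 27.6, True), ("SI", 30.4, True), ("SS", 34.9, True)])
        omi = compute_omi(s)
        assert omi["omi"].iloc[0] == pytest.approx(30.9667, abs=1e-4)
        assert round(omi["omi"].iloc[0], 1) == pytest.approx(31.0)

    def test_one_invalid_task_invalidates_composite(self):
        s = _summary_rows([("AM", 20.0, True), ("SI", 25.0, True), ("SS", 30.0, False)])
        omi = compute_omi(s)
        assert not omi["omi_valid"].iloc[0]
        assert np.isnan(omi["omi"].iloc[0])

    def test_missing_task_invalidates_composite(self):
        s = _summary_rows([("AM", 20.0, True), ("SI", 25.0, True)])
        omi = compute_omi(s)
        assert not omi["omi_valid"].iloc[0]

    def test_bounds_and_day_partition_invariance(self, micro_bundle):
        omi = micro_bundle.omi
        vals = omi["omi"].dropna()
        assert ((vals >= 0) & (vals <= 100)).all()
        # recompute from shuffled trials: order must not matter
        trials = micro_bundle.trials.sample(frac=1.0, random_state=0)
        summary = summarize_task(trials)
        omi2 = compute_omi(summary).sort_values(
            ["participant_id", "timepoint"]
        ).reset_index(drop=True)
        omi1 = omi.sort_values(["participant_id", "timepoint"]).reset_index(drop=True)
        pd.testing.assert_series_equal(omi1["omi"], omi2["omi"], check_exact=False)


class TestAcquisitionReport:
    def test_chi_square_hand_value(self):
        # 2x2 validity table (30,10 / 36,4): plain chi-square = 3.117
        valid = [True] * 30 + [False] * 10 + [True] * 36 + [False] * 4
        site = ["A"] * 40 + ["B"] * 40
        res = chi_square_validity(valid, site)
        assert res["chi2"] == pytest.approx(3.117, abs=0.001)
        assert res["df"] == 1

    def test_chi_square_degenerate_returns_nan(self):
        res = chi_square_validity([True] * 10, ["A"] * 5 + ["B"] * 5)
        assert np.isnan(res["chi2"])

    def test_all_valid_benchmark_pass(self, micro_bundle):
        rep = micro_bundle.acquisition
        assert (rep.table["signal_valid_pct"] <= 100).all()
        omi_rows = rep.table[rep.table["task"] == "OMI"]
        assert len(omi_rows) == 2

    def test_low_validity_group_fails_benchmark(self):
        spec = []
        for i in range(10):
            valid = i < 5  # 50% validity
            spec.append(("AM", 20.0, valid))
        s = _summary_rows([("AM", 20.0, True)])
        s = pd.concat(
            [
                s.assign(participant_id=f"ASD{i:04d}", task_valid=(i < 5))
                for i in range(10)
            ]
        )
        omi = pd.DataFrame(
            {
                "participant_id": [f"ASD{i:04d}" for i in range(10)],
                "group": "ASD",
                "timepoint": 1,
                "omi": 20.0,
                "omi_valid": [i < 5 for i in range(10)],
            }
        )
        clinical = pd.DataFrame(
            {
                "participant_id": [f"ASD{i:04d}" for i in range(10)],
                "group": "ASD",
                "age_years": 8.0,
                "iq": 100.0,
                "site": "Site1",
            }
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = acquisition_report(s, omi, clinical)
        am = rep.table[(rep.table["task"] == "AM") & (rep.table["group"] == "ASD")]
        assert not am["benchmark_pass"].iloc[0]
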