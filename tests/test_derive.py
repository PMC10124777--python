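import numpy as np
import pandas as pd
import pytest

from gazemark.config import Screen, Task
from gazemark.derive import (
    assign_sample_to_roi,
    compute_trial_metrics,
    derive_trials,
    estimate_cal_error,
)
from gazemark.rois import Region, TrialROI, mirror_rect


@pytest.fixture()
def simple_roi():
    return TrialROI(
        task=Task.AM,
        day=1,
        trial=1,
        duration_ms=1000.0,
        regions=(
            Region(label="face", shape="rect", coords=(100, 100, 300, 300)),
            Region(label="activity", shape="rect", coords=(400, 400, 800, 700)),
        ),
    )


def _samples(points, tracked=None, dt=50.0):
    n = len(points)
    tracked = [1] * n if tracked is None else tracked
    return pd.DataFrame(
        {
            "t_ms": np.arange(n) * dt,
            "x_px": [p[0] for p in points],
            "y_px": [p[1] for p in points],
            "tracked_flag": tracked,
        }
    )


class TestAssign:
    def test_face_centroid(self, simple_roi, screen):
        assert assign_sample_to_roi(200, 200, 10, simple_roi, screen) == "face"

    def test_point_outside_screen(self, simple_roi, screen):
        assert assign_sample_to_roi(-5, 200, 10, simple_roi, screen) is None
        assert assign_sample_to_roi(screen.width_px, 10, 10, simple_roi, screen) is None

    def test_point_in_no_region(self, simple_roi, screen):
        assert assign_sample_to_roi(50, 50, 10, simple_roi, screen) is None

    def test_untracked_sample(self, simple_roi, screen):
        assert (
            assign_sample_to_roi(200, 200, 10, simple_roi, screen, tracked=False)
            is None
        )

    def test_overlap_precedence_face_over_body(self, screen):
        troi = TrialROI(
            task=Task.SS,
            day=1,
            trial=1,
            duration_ms=1000.0,
            regions=(
                Region(label="body", shape="rect", coords=(100, 100, 500, 600)),
                Region(label="face", shape="poly",
                       coords=(150, 150, 400, 150, 400, 400, 150, 400)),
            ),
        )
        # inside both polygons: face wins
        assert assign_sample_to_roi(200, 200, 10, troi, screen) == "face"
        # inside body only
        assert assign_sample_to_roi(450, 500, 10, troi, screen) == "body"

    def test_time_window_respected(self, screen):
        troi = TrialROI(
            task=Task.AM,
            day=1,
            trial=1,
            duration_ms=1000.0,
            regions=(
                Region(
                    label="face",
                    shape="rect",
                    coords=(100, 100, 300, 300),
                    t_start_ms=500.0,
                ),
            ),
        )
        assert assign_sample_to_roi(200, 200, 100, troi, screen) is None
        assert assign_sample_to_roi(200, 200, 700, troi, screen) == "face"


class TestTrialMetrics:
    def test_all_tracked_in_face(self, simple_roi, screen):
        pts = [(200, 200)] * 20
        m = compute_trial_metrics(_samples(pts), simple_roi, screen, 20.0)
        assert m["pct_valid_data"] == 100.0
        assert m["pct_face"] == 100.0

    def test_hand_built_twenty_sample_trial(self, simple_roi, screen):
        # 10 tracked of 20: 5 face, 3 activity, 2 background
        pts = (
            [(200, 200)] * 5
            + [(500, 500)] * 3
            + [(900, 900)] * 2
            + [(0, 0)] * 10
        )
        tracked = [1] * 10 + [0] * 10
        m = compute_trial_metrics(
            _samples(pts, tracked), simple_roi, screen, 20.0
        )
        assert m["pct_valid_data"] == pytest.approx(50.0)
        assert m["pct_face"] == pytest.approx(50.0)
        assert m["pct_activity"] == pytest.approx(30.0)
        assert m["pct_social"] == pytest.approx(80.0)

    def test_zero_valid_time_flags_nan(self, simple_roi, screen):
        pts = [(200, 200)] * 10
        m = compute_trial_metrics(
            _samples(pts, tracked=[0] * 10), simple_roi, screen, 20.0
        )
        assert m["pct_valid_data"] == 0.0
        assert np.isnan(m["pct_face"])

    def test_off_screen_not_valid(self, simple_roi, screen):
        pts = [(200, 200)] * 5 + [(-100, 200)] * 5
        m = compute_trial_metrics(_samples(pts, dt=100.0), simple_roi, screen, 10.0)
        assert m["pct_valid_data"] == pytest.approx(50.0)
        assert m["pct_face"] == pytest.approx(100.0)  # of valid time

    def test_uniform_gaze_matches_area_fraction(self, screen, rng):
        # face occupies 3.2% of the screen; uniform gaze dwells there 3.2%
        area = 0.032 * screen.width_px * screen.height_px
        w = h = np.sqrt(area)
        x0, y0 = 500.0, 400.0
        troi = TrialROI(
            task=Task.AM,
            day=1,
            trial=1,
            duration_ms=200_000.0,
            regions=(
                Region(label="face", shape="rect", coords=(x0, y0, x0 + w, y0 + h)),
            ),
        )
        n = 200_000
        df = pd.DataFrame(
            {
                "t_ms": np.arange(n) * 1.0,
                "x_px": rng.uniform(0, screen.width_px, n),
                "y_px": rng.uniform(0, screen.height_px, n),
                "tracked_flag": 1,
            }
        )
        m = compute_trial_metrics(df, troi, screen, 1000.0)
        assert m["pct_face"] == pytest.approx(3.2, abs=0.15)

    def test_bio_preference_ratio(self, screen):
        troi = TrialROI(
            task=Task.BM,
            day=1,
            trial=1,
            duration_ms=1000.0,
            regions=(
                Region(label="bio", shape="rect", coords=(0, 0, 900, 1200)),
                Region(label="control", shape="rect", coords=(1000, 0, 1900, 1200)),
            ),
        )
        pts = [(100, 100)] * 6 + [(1500, 100)] * 2 + [(950, 100)] * 2
        m = compute_trial_metrics(_samples(pts), troi, screen, 20.0)
        assert m["pct_bio"] == pytest.approx(75.0)
        assert m["bio_ms"] == pytest.approx(6 * 50.0)
        assert m["control_ms"] == pytest.approx(2 * 50.0)

    def test_bio_undefined_without_panel_gaze(self, screen):
        troi = TrialROI(
            task=Task.BM,
            day=1,
            trial=1,
            duration_ms=1000.0,
            regions=(
                Region(label="bio", shape="rect", coords=(0, 0, 900, 1200)),
                Region(label="control", shape="rect", coords=(1000, 0, 1900, 1200)),
            ),
        )
        pts = [(950, 1150)] * 10  # between the panels
        m = compute_trial_metrics(_samples(pts), troi, screen, 20.0)
        assert np.isnan(m["pct_bio"])


class TestMirrorInvariance:
    def test_horizontal_flip_preserves_metrics(self, simple_roi, screen, rng):
        n = 500
        pts = list(
            zip(
                rng.uniform(0.5, screen.width_px - 0.5, n),
                rng.uniform(0.5, screen.height_px - 0.5, n),
            )
        )
        df = _samples(pts, dt=2.0)
        m1 = compute_trial_metrics(df, simple_roi, screen, 500.0)
        flipped = df.copy()
        flipped["x_px"] = screen.width_px - flipped["x_px"]
        troi2 = TrialROI(
            task=simple_roi.task,
            day=2,
            trial=1,
            duration_ms=simple_roi.duration_ms,
            regions=tuple(
                Region(
                    label=r.label,
                    shape="rect",
                    coords=mirror_rect(r.coords, screen.width_px),
                )
                for r in simple_roi.regions
            ),
        )
        m2 = compute_trial_metrics(flipped, troi2, screen, 500.0)
        for key in ("pct_valid_data", "pct_face", "pct_activity", "pct_social"):
            assert m1[key] == pytest.approx(m2[key], abs=1e-9)


class TestCalError:
    def test_gaze_on_target_zero(self, screen):
        s = _samples([(500, 500)] * 5)
        assert estimate_cal_error([(s, (500, 500))], 42.0) == 0.0

    def test_constant_offset_42px_is_one_degree(self, screen):
        s = _samples([(542, 500)] * 5)
        assert estimate_cal_error([(s, (500, 500))], 42.0) == pytest.approx(1.0)

    def test_pythagorean_offset(self, screen):
        # (3 deg, 4 deg) offset -> 5 deg
        s = _samples([(500 + 3 * 42, 500 + 4 * 42)] * 5)
        assert estimate_cal_error([(s, (500, 500))], 42.0) == pytest.approx(5.0)

    def test_no_tracked_samples_gives_nan(self, screen):
        s = _samples([(500, 500)] * 5, tracked=[0] * 5)
        assert np.isnan(estimate_cal_error([(s, (500, 500))], 42.0))

    def test_median_over_events(self, screen):
        events = [
            (_samples([(542, 500)] * 3), (500, 500)),
            (_samples([(584, 500)] * 3), (500, 500)),
            (_samples([(500, 542)] * 3), (500, 500)),
        ]
        assert estimate_cal_error(events, 42.0) == pytest.approx(1.0)


class TestVectorizedAgainstReference:
    def test_table_deriver_matches_per_trial_reference(self, micro_bundle, micro_config):
        gaze = micro_bundle.gaze
        battery = micro_bundle.battery
        trials = micro_bundle.trials
        sub = gaze[
            (gaze["task"] == "AM")
            & (gaze["timepoint"] == 1)
            & (gaze["day"] == 1)
        ]
        pid = sub["participant_id"].iloc[0]
        for trial in (1, 9):
            samples = sub[(sub["participant_id"] == pid) & (sub["trial"] == trial)]
            ref = compute_trial_metrics(
                samples,
                battery.lookup("AM", 1, trial),
                micro_config.screen,
                micro_config.sample_rate_hz,
            )
            row = trials[
                (trials["participant_id"] == pid)
                & (trials["timepoint"] == 1)
                & (trials["day"] == 1)
                & (trials["task"] == "AM")
                & (trials["trial"] == trial)
            ].iloc[0]
            for key in ("pct_valid_data", "pct_face", "pct_activity", "pct_social"):
                assert row[key] == pytest.approx(ref[key], abs=1e-9)

    def test_conservation_of_percentages(self, micro_bundle):
        t = micro_bundle.trials
        gaze_tasks = t[t["task"].isin(["AM", "SI", "SS"])].dropna(subset=["pct_face"])
        total = gaze_tasks[["pct_face", "pct_body", "pct_activity"]].sum(axis=1)
        assert (total <= 100.0 + 1e-9).all()

    def test_session_cal_error_attached_to_all_trials(self, micro_bundle):
        t = micro_bundle.trials
        assert t["cal_error_deg"].notna().all()

    def test_recovered_offset_magnitude(self, micro_bundle, micro_config):
        # the derived session error should track the planted offset magnitude
        gt = micro_bundle.ground_truth.set_index("participant_id")
        t = micro_bundle.trials
        sess = t[(t["timepoint"] == 1) & (t["day"] == 1)].groupby(
            "participant_id", observed=True
        )["cal_error_deg"].first()
        planted = np.hypot(gt["cal_dx_deg_t1_d1"], gt["cal_dy_deg_t1_d1"])
        err = (sess - planted.reindex(sess.index)).abs()
        assert err.median() < 0.25  # validation jitter limits precision
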