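import math

import numpy as np
import pandas as pd
import pytest

from mindwander import simulate
from mindwander.gaze_pipeline import (
    EYE_FEATURE_NAMES,
    Fixation,
    compute_saccades,
    detect_fixations_idt,
    detect_fixations_reference,
    extract_eye_features,
    filter_reading_area,
    pupil_zscore,
    screen_paragraph_quality,
)


def _stream(t, x, y, pupil=None, valid=None):
    n = len(t)
    return pd.DataFrame(
        {
            "t": np.asarray(t, dtype=float),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "pupil": np.ones(n) if pupil is None else np.asarray(pupil, dtype=float),
            "valid": np.ones(n, dtype=bool) if valid is None else valid,
        }
    )


def random_walk_stream(rng, n):
    """Random-walk gaze with occasional jumps and variable sampling gaps."""
    t = np.cumsum(rng.integers(8, 16, n)).astype(float)
    steps = rng.normal(0, rng.uniform(2, 25), (n, 2))
    jumps = (rng.random(n) < 0.05)[:, None] * rng.normal(0, 300, (n, 2))
    xy = np.cumsum(steps + jumps, axis=0) + 500
    return _stream(t, xy[:, 0], xy[:, 1])


class TestIdt:
    def test_stationary_samples_form_one_fixation(self):
        t = np.linspace(0, 322, 30)
        s = _stream(t, np.full(30, 100.0), np.full(30, 100.0))
        fixations = detect_fixations_idt(s, 40, 100)
        assert len(fixations) == 1
        f = fixations[0]
        assert (f.x, f.y) == (100.0, 100.0)
        assert f.duration == pytest.approx(322.0)

    def test_two_separated_clusters(self):
        t = np.arange(40) * 11.0
        x = np.where(np.arange(40) < 20, 100.0, 600.0)
        s = _stream(t, x, np.full(40, 100.0))
        fixations = detect_fixations_idt(s, 40, 100)
        assert len(fixations) == 2
        assert fixations[0].x == pytest.approx(100.0)
        assert fixations[1].x == pytest.approx(600.0)

    def test_fewer_than_two_samples(self):
        assert detect_fixations_idt(_stream([0.0], [1.0], [1.0]), 40, 100) == []

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_reference(self, seed):
        """Incremental I-DT equals the exhaustive window-enumeration reference."""
        rng = np.random.default_rng(seed)
        s = random_walk_stream(rng, int(rng.integers(2, 200)))
        disp = float(rng.uniform(10, 80))
        fast = detect_fixations_idt(s, disp, 100)
        slow = detect_fixations_reference(s, disp, 100)
        assert fast == slow

    def test_gap_splits_window(self):
        # identical position, but a 500 ms hole: two fixations, not one
        t = np.concatenate([np.arange(0, 150, 11.0), np.arange(650, 800, 11.0)])
        s = _stream(t, np.full(len(t), 50.0), np.full(len(t), 50.0))
        fixations = detect_fixations_idt(s, 40, 100, max_gap_ms=75)
        assert len(fixations) == 2

    def test_fixation_intervals_disjoint_and_bounded(self):
        rng = np.random.default_rng(99)
        s = random_walk_stream(rng, 400)
        fixations = detect_fixations_idt(s, 40, 100)
        for a, b in zip(fixations, fixations[1:]):
            assert a.offset <= b.onset
        total = sum(f.duration for f in fixations)
        assert total <= s["t"].iloc[-1] - s["t"].iloc[0]


class TestReadingArea:
    def test_all_inside_is_identity(self):
        fx = [Fixation(0, 100, 10, 10, 0), Fixation(100, 200, 90, 90, 0)]
        assert filter_reading_area(fx, (0, 0, 100, 100)) == fx

    def test_half_open_edges(self):
        fx = [Fixation(0, 100, 100.0, 50.0, 0), Fixation(0, 100, 0.0, 0.0, 0)]
        kept = filter_reading_area(fx, (0, 0, 100, 100))
        assert kept == [fx[1]]  # right edge excluded, top-left corner included

    def test_matches_point_in_rect_oracle(self, rng):
        fx = [
            Fixation(0, 1, float(x), float(y), 0)
            for x, y in rng.uniform(-50, 150, (200, 2))
        ]
        rect = (0.0, 10.0, 120.0, 110.0)
        kept = filter_reading_area(fx, rect)
        oracle = [
            f for f in fx if rect[0] <= f.x < rect[2] and rect[1] <= f.y < rect[3]
        ]
        assert kept == oracle

    def test_degenerate_rect_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            filter_reading_area([], (10, 0, 10, 100))


class TestQualityScreen:
    def _fix(self, n):
        return [Fixation(i * 100, i * 100 + 80, 0, 0, 0) for i in range(n)]

    def test_clean_paragraph_kept(self):
        s = _stream(np.arange(100.0), np.zeros(100), np.zeros(100))
        assert screen_paragraph_quality(s, self._fix(20)).keep

    def test_low_validity_excluded(self):
        valid = np.zeros(100, dtype=bool)
        valid[:50] = True
        s = _stream(np.arange(100.0), np.zeros(100), np.zeros(100), valid=valid)
        decision = screen_paragraph_quality(s, self._fix(20))
        assert not decision.keep and decision.reason == "low-validity"

    def test_too_few_fixations_excluded(self):
        s = _stream(np.arange(100.0), np.zeros(100), np.zeros(100))
        decision = screen_paragraph_quality(s, self._fix(3))
        assert not decision.keep and decision.reason == "few-fixations"

    def test_exclusion_monotone_in_dropout(self):
        """Injecting more tracking loss can only flip paragraphs toward exclusion."""
        rng = np.random.default_rng(4)
        base = random_walk_stream(rng, 300)
        order = rng.permutation(300)
        excluded = []
        for rate in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            valid = np.ones(300, dtype=bool)
            valid[order[: int(rate * 300)]] = False
            s = base.assign(valid=valid)
            fixations = detect_fixations_idt(s[s["valid"]], 40, 100)
            excluded.append(not screen_paragraph_quality(s, fixations).keep)
        assert excluded == sorted(excluded)


class TestSaccades:
    def test_three_four_five(self):
        fx = [Fixation(0, 60, 0, 0, 0), Fixation(100, 200, 3, 4, 0)]
        (s,) = compute_saccades(fx)
        assert s.length == pytest.approx(5.0)
        assert s.transit_ms == pytest.approx(40.0)
        assert s.angle == pytest.approx(math.atan2(4, 3))
        assert not s.is_regression

    def test_pure_leftward_is_regression(self):
        fx = [Fixation(0, 60, 100, 0, 0), Fixation(100, 200, 50, 0, 0)]
        (s,) = compute_saccades(fx)
        assert s.is_regression and s.regression_length == pytest.approx(50.0)

    def test_line_return_not_regression(self):
        fx = [Fixation(0, 60, 1500, 400, 0), Fixation(100, 200, 360, 436, 0)]
        (s,) = compute_saccades(fx, line_height_px=36)
        assert not s.is_regression

    def test_count_relation(self, rng):
        fx = [
            Fixation(i * 100.0, i * 100.0 + 80, x, y, 0)
            for i, (x, y) in enumerate(rng.uniform(0, 1000, (30, 2)))
        ]
        saccades = compute_saccades(fx)
        assert len(saccades) == len(fx) - 1
        assert sum(s.is_regression for s in saccades) <= len(saccades)

    def test_regression_count_matches_simulated_schedule(self):
        """Saccades over the generator's true fixation schedule reproduce its
        scheduled regression count exactly."""
        params = simulate.GazeParams()
        ev = simulate.ParagraphEvent("P", "S1", "p", 0.0, 20_000.0, "Random", "NoMusic")
        _, schedule, n_scheduled = simulate.simulate_gaze(
            ev, None, params, np.random.default_rng(17)
        )
        fx = [
            Fixation(r.onset, r.offset, r.x, r.y, 0.0)
            for r in schedule.itertuples()
        ]
        saccades = compute_saccades(fx, line_height_px=params.line_height_px)
        assert sum(s.is_regression for s in saccades) == n_scheduled


class TestPupilZscore:
    def test_mean_zero_sd_one(self, small_study):
        pupil_zscore(small_study)
        for pid in small_study.participants:
            vals = np.concatenate(
                [
                    df.loc[df["valid"], "pupil"].to_numpy()
                    for key, df in small_study.gaze.items()
                    if key[0] == pid
                ]
            )
            assert np.mean(vals) == pytest.approx(0.0, abs=1e-9)
            assert np.std(vals) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self):
        study_a = simulate.simulate_study(simulate.small_config(n_participants=2, seed=31))
        study_b = simulate.simulate_study(simulate.small_config(n_participants=2, seed=31))
        for key, df in study_b.gaze.items():
            study_b.gaze[key] = df.assign(pupil=3.5 * df["pupil"] - 40.0)
        pupil_zscore(study_a)
        pupil_zscore(study_b)
        for key in study_a.gaze:
            np.testing.assert_allclose(
                study_a.gaze[key]["pupil"].to_numpy(),
                study_b.gaze[key]["pupil"].to_numpy(),
                atol=1e-9,
                equal_nan=True,
            )

    def test_zero_variance_rejected(self):
        study = simulate.simulate_study(simulate.small_config(n_participants=2, seed=1))
        for key, df in study.gaze.items():
            study.gaze[key] = df.assign(pupil=5.0)
        with pytest.raises(ValueError, match="zero pupil variance"):
            pupil_zscore(study)


class TestEyeFeatures:
    def test_registry_has_19_entries(self, rng):
        fx = [
            Fixation(i * 100.0, i * 100.0 + 80, x, y, p)
            for i, (x, y, p) in enumerate(rng.uniform(0, 500, (10, 3)))
        ]
        feats = extract_eye_features(fx, compute_saccades(fx))
        assert list(feats) == EYE_FEATURE_NAMES
        assert len(feats) == 19
        assert all(np.isfinite(v) for v in feats.values())

    def test_identical_fixations_collapse_extrema(self):
        fx = [Fixation(0, 80, 10, 10, 1.0), Fixation(120, 200, 10, 10, 1.0)]
        feats = extract_eye_features(fx, compute_saccades(fx))
        assert feats["fix_duration_min"] == feats["fix_duration_max"] == feats["fix_duration_mean"]

    def test_hand_built_paragraph_matches_manual_computation(self):
        """Four fixations worked out by hand (spreadsheet-style)."""
        fx = [
            Fixation(0, 100, 0, 0, -1.0),
            Fixation(140, 300, 100, 0, 0.0),
            Fixation(340, 420, 40, 0, 0.5),
            Fixation(460, 700, 40, 100, 2.5),
        ]
        saccades = compute_saccades(fx, line_height_px=36)
        feats = extract_eye_features(fx, saccades)
        # durations 100, 160, 80, 240
        assert feats["fix_duration_mean"] == pytest.approx(145.0)
        assert feats["fix_duration_min"] == 80.0
        assert feats["fix_duration_max"] == 240.0
        # pupil -1, 0, 0.5, 2.5
        assert feats["pupil_mean"] == pytest.approx(0.5)
        assert feats["pupil_min"] == -1.0 and feats["pupil_max"] == 2.5
        # saccade lengths 100, 60, 100; transits 40, 40, 40
        assert feats["saccade_length_mean"] == pytest.approx((100 + 60 + 100) / 3)
        assert feats["saccade_length_min"] == 60.0
        assert feats["saccade_velocity_mean"] == pytest.approx(40.0)
        # angles: atan2(0,100)=0, atan2(0,-60)=pi, atan2(100,0)=pi/2
        assert feats["saccade_angle_mean"] == pytest.approx((0 + math.pi + math.pi / 2) / 3)
        # single regression (second saccade, dx=-60, dy=0)
        assert feats["n_regressions"] == 1.0
        assert feats["regression_length_mean"] == 60.0
        assert feats["regression_length_min"] == feats["regression_length_max"] == 60.0
        assert feats["n_fixations"] == 4.0 and feats["n_saccades"] == 3.0

    def test_time_shift_invariance(self, rng):
        fx = [
            Fixation(i * 110.0, i * 110.0 + 90, x, y, p)
            for i, (x, y, p) in enumerate(rng.uniform(0, 500, (8, 3)))
        ]
        shifted = [
            Fixation(f.onset + 5_000.0, f.offset + 5_000.0, f.x, f.y, f.pupil) for f in fx
        ]
        a = extract_eye_features(fx, compute_saccades(fx))
        b = extract_eye_features(shifted, compute_saccades(shifted))
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_empty_fixations_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            extract_eye_features([], [])
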