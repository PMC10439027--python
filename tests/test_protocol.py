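"""Trial assembly: placement, cueing, balance, overlays, config checks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from pinkstim.dynamics import frame_statistics
from pinkstim.protocol import (
    ConfigError,
    SessionConfig,
    TrialSpec,
    apply_overlay,
    build_frames_overlay,
    build_trial,
    generate_session,
    place_signal,
)

from conftest import small_exp1a_config


class TestPlaceSignal:
    def test_zero_eccentricity_is_fixation(self, exp1a_small):
        trial = TrialSpec("cued", sigma=50.0, tilt=40.0, seed=1, eccentricity=0.0)
        window = place_signal(trial, exp1a_small)
        assert (window.center_x, window.center_y) == (0.0, 0.0)

    def test_position_mode_offsets_along_midline(self):
        config = small_exp1a_config(
            field_shape="rectangular",
            field_radius_deg=None,
            field_height_deg=2.5,
            field_width_deg=20.0,
            eccentricities=None,
            positions=(-8.0, 0.0, 8.0),
            window_r_deg=1.0,
        )
        trial = TrialSpec("uncued", sigma=30.0, tilt=-40.0, seed=2, position=4.0)
        window = place_signal(trial, config)
        assert window.center_x == 4.0 and window.center_y == 0.0
        # +4 deg at p px/deg is a 4p-pixel offset from the field centre
        assert window.center_x * config.ppd == pytest.approx(4 * config.ppd)

    def test_radial_distance_and_angle_uniformity(self, exp1a_small):
        angles = []
        for seed in range(1000):
            trial = TrialSpec("cued", sigma=50.0, tilt=40.0, seed=seed, eccentricity=7.0)
            window = place_signal(trial, exp1a_small)
            radius = np.hypot(window.center_x, window.center_y)
            assert radius == pytest.approx(7.0, abs=1e-9)
            angles.append(np.arctan2(window.center_y, window.center_x))
        counts, _ = np.histogram(angles, bins=8, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_placement_outside_field_rejected(self, exp1a_small):
        trial = TrialSpec("cued", sigma=50.0, tilt=40.0, seed=1, eccentricity=13.0)
        with pytest.raises(ValueError):
            place_signal(trial, exp1a_small)


class TestBuildTrial:
    def test_cued_uncued_share_frames_differ_in_events(self, exp1a_small):
        cued = TrialSpec("cued", sigma=50.0, tilt=40.0, seed=77, eccentricity=3.5)
        uncued = dataclasses.replace(cued, condition="uncued")
        seq_c, _ = build_trial(cued, exp1a_small)
        seq_u, _ = build_trial(uncued, exp1a_small)
        # the colour cue lives in the export layer: grayscale frames match
        assert np.array_equal(seq_c.frames, seq_u.frames)
        assert "cue_on" in seq_c.events and "cue_on" not in seq_u.events
        assert seq_c.meta["cue_window"] is not None
        assert seq_u.meta["cue_window"] is None

    def test_ground_truth_round_trips(self, exp1a_small):
        trial = TrialSpec("cued", sigma=45.0, tilt=-40.0, seed=5, eccentricity=7.0)
        seq, record = build_trial(trial, exp1a_small)
        assert record["tilt"] == -40.0
        assert record["sigma"] == 45.0
        assert record["eccentricity"] == 7.0
        assert record["signal_on_frame"] == seq.events["signal_on"]
        assert np.hypot(record["center_x_deg"], record["center_y_deg"]) == pytest.approx(7.0)

    def test_timeline_layout(self, exp1a_small):
        trial = TrialSpec("cued", sigma=50.0, tilt=40.0, seed=3, eccentricity=0.0)
        seq, record = build_trial(trial, exp1a_small)
        fix_frames = round(record["fixation_ms"] / 1000 * 60)
        assert seq.events["cue_on"] == fix_frames
        assert seq.events["cue_off"] == fix_frames + 4
        assert seq.events["signal_on"] == fix_frames + 4 + 6  # 100 ms delay
        assert seq.events["signal_off"] - seq.events["signal_on"] == 3
        assert seq.meta["repeat_factor"] == 2


class TestSession:
    def test_factors_balanced_over_session(self, exp1a_small):
        config = dataclasses.replace(exp1a_small, trials_per_cell=2)
        trials = generate_session(config)
        assert len(trials) == 2 * 4 * 5 * 2 * 2  # cond x ecc x sigma x tilt x reps
        conditions = [t.condition for t in trials]
        assert conditions.count("cued") == conditions.count("uncued")
        for sigma in config.sigmas:
            assert sum(t.sigma == sigma for t in trials) == len(trials) // 5
        for ecc in config.eccentricities:
            assert sum(t.eccentricity == ecc for t in trials) == len(trials) // 4

    def test_session_reproducible_from_master_seed(self, exp1a_small):
        assert generate_session(exp1a_small) == generate_session(exp1a_small)
        other = dataclasses.replace(exp1a_small, master_seed=999)
        assert generate_session(other) != generate_session(exp1a_small)

    def test_full_block_builds_within_invariants(self):
        # a whole block at coarse pixel scale; every frame must hold the
        # target statistics
        config = small_exp1a_config(ppd=2.0, sigmas=(30.0, 50.0, 70.0), master_seed=7)
        trials = generate_session(config)[:30]
        for trial in trials:
            seq, _ = build_trial(trial, config)
            means, contrasts = frame_statistics(seq)
            assert np.abs(means - 0.5).max() < 1e-6
            assert np.abs(contrasts - 0.2).max() < 1e-6
            assert seq.events["signal_on"] < seq.events["signal_off"] <= seq.n_frames


class TestFramesOverlay:
    def test_ring_geometry(self):
        shape = (68, 536)
        ppd = 26.8
        mask = build_frames_overlay([-8.0, -4.0, 0.0, 4.0, 8.0], 1.0, ppd, shape)
        # ~2*pi*R pixels per one-pixel ring stroke
        expected = 5 * 2 * np.pi * 1.0 * ppd
        assert abs(mask.sum() - expected) / expected < 0.25
        # ring centred at +4 deg: stroke present near (cy, cx + R)
        cx = (536 - 1) / 2 + 4.0 * ppd
        cy = (68 - 1) / 2
        near = mask[int(cy) - 1 : int(cy) + 2, int(cx + ppd) - 2 : int(cx + ppd) + 3]
        assert near.any()

    def test_overlay_touches_only_stroke_pixels(self, rng):
        shape = (68, 536)
        mask = build_frames_overlay([0.0, 4.0], 1.0, 26.8, shape)
        pixels = rng.random(shape)
        painted = apply_overlay(pixels, mask, luminance=0.0)
        assert np.array_equal(painted[~mask], pixels[~mask])
        assert np.all(painted[mask] == 0.0)

    def test_ring_must_fit(self):
        with pytest.raises(ValueError):
            build_frames_overlay([9.9], 1.0, 26.8, (68, 536))


class TestConfigValidation:
    def test_misaligned_cue_duration_reports_nearest(self):
        data = dict(
            schema_version=1,
            ppd=10.0,
            field_shape="circular",
            field_radius_deg=14.32,
            window_r_deg=1.75,
            window_w_deg=0.875,
            sigmas=[30.0, 50.0, 70.0],
            trials_per_cell=1,
            master_seed=1,
            eccentricities=[0.0, 7.0],
            cue_ms=75.0,  # 4.5 frames at 60 Hz
        )
        with pytest.raises(ConfigError) as err:
            SessionConfig.from_dict(data)
        assert "66.67" in str(err.value) and "83.33" in str(err.value)

    def test_all_problems_reported_at_once(self):
        data = dict(
            schema_version=1,
            ppd=-1.0,
            field_shape="hexagonal",
            window_r_deg=1.0,
            window_w_deg=0.5,
            sigmas=[30.0, 50.0],
            trials_per_cell=0,
            master_seed=1,
            eccentricities=[0.0],
            positions=[0.0],
            bogus_key=1,
        )
        with pytest.raises(ConfigError) as err:
            SessionConfig.from_dict(data)
        message = str(err.value)
        for fragment in ("ppd", "field_shape", "trials_per_cell",
                         "exactly one of", "unknown field: bogus_key"):
            assert fragment in message
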