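"""Normalization, regional sums, event detection, phase labelling, the
circular sine-cosine encoding, COP, windowing and stride interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitphase as gp
from gaitphase import phase_features as pf
from gaitphase.signal_io import CHANNEL_NAMES, RIGHT_HEEL
from gaitphase.synthetic_gait import SensorLayout


class TestMinMaxNormalization:
    def test_simple_value(self):
        rng = np.random.default_rng(0)
        forces = rng.uniform(0, 4, size=(50, 10))
        forces[0] = 0.0
        forces[1] = 4.0
        rec = gp.FsrRecording("s", "sc", 1, np.arange(50) / 100, forces,
                              np.zeros(50, np.int8))
        stats = pf.fit_norm_stats([rec])
        forces2 = forces.copy()
        forces2[2, 0] = 1.0
        out = pf.apply_minmax(rec.with_forces(forces2, False), stats)
        assert out.forces[2, 0] == pytest.approx(0.25)

    def test_heldout_values_clipped(self, tiny_split, tiny_stats):
        rec = tiny_split.test_recordings[0]
        boosted = rec.with_forces(rec.forces * 10.0, False)
        out = pf.apply_minmax(boosted, tiny_stats)
        assert out.forces.max() <= 1.0 and out.forces.min() >= 0.0

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(1)
        forces = rng.uniform(0, 3, size=(200, 10))
        rec = gp.FsrRecording("s", "sc", 1, np.arange(200) / 100, forces,
                              np.zeros(200, np.int8))
        stats = pf.fit_norm_stats([rec])
        out = pf.apply_minmax(rec, stats).forces
        for j in range(10):
            col = forces[:, j]
            expect = (col - col.min()) / (col.max() - col.min())
            np.testing.assert_allclose(out[:, j], expect, atol=1e-12)

    def test_constant_channel_raises_with_name(self):
        forces = np.random.default_rng(2).uniform(0, 1, size=(30, 10))
        forces[:, 4] = 0.7
        rec = gp.FsrRecording("s", "sc", 1, np.arange(30) / 100, forces,
                              np.zeros(30, np.int8))
        with pytest.raises(pf.DegenerateChannelError, match=CHANNEL_NAMES[4]):
            pf.fit_norm_stats([rec])


class TestRegionSums:
    def test_direct_sum(self, tiny_stats):
        sample = np.zeros(10)
        # right-foot toe/meta1/meta5 are channels 5, 6, 7
        sample[5], sample[6], sample[7] = 0.2, 0.3, 0.1
        out = pf.region_sums(sample, tiny_stats)
        assert out[2] == pytest.approx(0.6 / tiny_stats.fore_max["R"])
        assert out[3] == 0.0

    def test_all_zero_sample(self, tiny_stats):
        assert np.all(pf.region_sums(np.zeros(10), tiny_stats) == 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_summation_oracle(self, tiny_stats, seed):
        x = np.random.default_rng(seed).uniform(0, 1, size=(7, 10))
        out = pf.region_sums(x, tiny_stats)
        for i in range(7):
            fore_l = sum(x[i, CHANNEL_NAMES.index(f"L_{s}")] for s in ("toe", "meta1", "meta5"))
            back_r = sum(x[i, CHANNEL_NAMES.index(f"R_{s}")] for s in ("cuboid", "heel"))
            assert out[i, 0] == pytest.approx(fore_l / tiny_stats.fore_max["L"])
            assert out[i, 3] == pytest.approx(back_r / tiny_stats.back_max["R"])


class TestHeelStrikeDetection:
    def test_detects_synthetic_pulse_onsets(self):
        s = np.zeros(1000)
        onsets = np.arange(10) * 100 + 7
        for o in onsets:
            s[o : o + 40] = np.sin(np.linspace(0, np.pi, 40)) ** 2
        ev = pf.detect_heel_strikes(s)
        assert len(ev) == len(onsets)
        # onset refinement lands on the ramp start (the first sample may be
        # exactly zero, one sample before the first nonzero value)
        assert np.max(np.abs(ev - onsets)) <= 1

    def test_all_zero_series_empty(self):
        assert len(pf.detect_heel_strikes(np.zeros(500))) == 0

    def test_refractory_suppresses_double_trigger(self):
        s = np.zeros(200)
        s[50:55] = 1.0  # crossing 1
        s[60:65] = 1.0  # crossing 2, 100 ms later
        ev = pf.detect_heel_strikes(s, refractory_s=0.3)
        assert len(ev) == 1


class TestPhaseLabelling:
    def test_linear_midpoint(self):
        gps = pf.label_gait_phase(150, [0, 100])
        assert gps.values[50] == pytest.approx(50.0)
        assert gps.values[0] == 0.0
        assert not gps.valid[120]  # beyond last event

    def test_event_samples_are_zero(self):
        gps = pf.label_gait_phase(300, [10, 110, 260])
        assert gps.values[10] == 0.0 and gps.values[110] == 0.0
        assert not gps.valid[5]

    def test_too_few_events_raise(self):
        with pytest.raises(pf.InsufficientEventsError):
            pf.label_gait_phase(100, [50])

    def test_recovers_generator_phase_on_noiseless_trial(self, noiseless_trial, tiny_stats):
        rec = noiseless_trial
        stats = pf.fit_norm_stats([rec])
        rn = pf.apply_minmax(rec, stats)
        ev = pf.detect_heel_strikes(rn.forces[:, RIGHT_HEEL])
        gps = pf.label_gait_phase(rec, ev)
        err = ((gps.values - rec.phase + 50) % 100) - 50
        assert np.nanmax(np.abs(err[gps.valid])) < 1.0


class TestCsfEncoding:
    @pytest.mark.parametrize(
        "phase,expected",
        [(0.0, (1.0, 0.0)), (25.0, (0.0, 1.0)), (50.0, (-1.0, 0.0)), (75.0, (0.0, -1.0))],
    )
    def test_cardinal_points(self, phase, expected):
        np.testing.assert_allclose(pf.encode_phase(phase), expected, atol=1e-12)
        assert pf.decode_phase(np.asarray(expected, float)) == pytest.approx(phase)

    def test_unit_norm(self):
        grid = np.arange(0, 100, 0.25)
        csf = pf.encode_phase(grid)
        np.testing.assert_allclose(np.linalg.norm(csf, axis=1), 1.0, atol=1e-12)

    @given(st.floats(0, 99.999))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_property(self, phase):
        assert pf.decode_phase(pf.encode_phase(phase)) == pytest.approx(phase, abs=1e-9)

    def test_decode_invariant_to_radial_scale(self):
        grid = np.arange(0, 100, 0.5)
        csf = pf.encode_phase(grid)
        for scale in (0.01, 0.5, 7.3):
            np.testing.assert_allclose(
                pf.decode_phase(scale * csf), pf.decode_phase(csf), atol=1e-9
            )

    def test_zero_vector_rejected(self):
        with pytest.raises(pf.UndefinedPhaseError):
            pf.decode_phase(np.zeros(2))


class TestCenterOfPressure:
    def test_heel_only_gives_heel_coordinate(self):
        sample = np.zeros(10)
        sample[CHANNEL_NAMES.index("R_heel")] = 0.8
        cop = pf.compute_cop(sample)
        assert cop[1] == pytest.approx(0.0)

    def test_heel_toe_symmetry(self):
        sample = np.zeros(10)
        sample[CHANNEL_NAMES.index("L_heel")] = 0.5
        sample[CHANNEL_NAMES.index("L_toe")] = 0.5
        assert pf.compute_cop(sample)[0] == pytest.approx(0.5)

    def test_matches_weighted_mean_oracle(self):
        layout = SensorLayout()
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=(20, 10))
        cop = pf.compute_cop(x, layout)
        coords = layout.site_coords()
        for i in range(20):
            right = x[i, 5:10]
            assert cop[i, 1] == pytest.approx(right @ coords / right.sum())

    def test_swing_holds_previous_value(self):
        x = np.zeros((5, 10))
        x[0, CHANNEL_NAMES.index("R_toe")] = 1.0  # COP at 1.0
        cop = pf.compute_cop(x)
        np.testing.assert_allclose(cop[:, 1], 1.0)
        assert np.all(cop[:, 0] == 0.0)  # left never loaded: default heel


class TestWindowing:
    def test_count_formula(self):
        x = np.zeros((100, 3))
        w, _, ends = pf.build_windows(x, None, seq_len=25, hop=1)
        assert w.shape == (76, 25, 3)
        assert ends[0] == 24 and ends[-1] == 99

    def test_short_series_empty(self):
        w, labels, ends = pf.build_windows(np.zeros((24, 3)), np.zeros(24), 25)
        assert len(w) == 0 and len(ends) == 0

    def test_labels_taken_at_end_samples(self):
        x = np.arange(50)[:, None].astype(float)
        labels = np.arange(50) * 10
        w, lab, ends = pf.build_windows(x, labels, seq_len=10, hop=3)
        np.testing.assert_array_equal(lab, ends * 10)
        # window content is the trailing seq_len samples
        np.testing.assert_array_equal(w[2, :, 0], np.arange(6, 16))


class TestFeatureVariants:
    @pytest.mark.parametrize("variant,width", [(1, 19), (2, 14), (3, 15), (4, 9), (5, 21)])
    def test_variant_widths(self, variant, width, tiny_split, tiny_stats):
        assert pf.variant_width(variant) == width
        rec = pf.apply_minmax(tiny_split.train_recordings[0], tiny_stats)
        fm = pf.build_features(rec, tiny_stats, variant=variant)
        assert fm.width == width

    def test_unnormalized_recording_rejected(self, tiny_split, tiny_stats):
        with pytest.raises(ValueError, match="normalized"):
            pf.build_features(tiny_split.train_recordings[0], tiny_stats, variant=1)

    def test_wc_onehot_rows(self):
        oh = pf.wc_onehot(np.array([0, 4, -1]))
        np.testing.assert_array_equal(oh.sum(axis=1), [1, 1, 0])
        assert oh[1, 4] == 1.0


class TestStrideNormalize:
    def test_grid_size(self, noiseless_trial):
        curves = pf.stride_normalize(noiseless_trial, noiseless_trial.heel_strikes)
        arr = next(iter(curves.values()))
        assert arr.shape[1] == 101 and arr.shape[2] == 10

    def test_constant_channel_stays_constant(self):
        forces = np.ones((200, 10))
        rec = gp.FsrRecording("s", "sc", 1, np.arange(200) / 100, forces,
                              np.zeros(200, np.int8))
        curves = pf.stride_normalize(rec, [0, 100, 200])
        np.testing.assert_allclose(next(iter(curves.values())), 1.0)

    def test_matches_interp_oracle(self, noiseless_trial):
        rec = noiseless_trial
        ev = rec.heel_strikes[:3]
        curves = pf.stride_normalize(rec, ev, grid_points=51)
        a, b = ev[0], ev[1]
        xp = np.arange(b - a) * (100.0 / (b - a))
        grid = np.linspace(0, 100, 51)
        for j in (0, 4, 9):
            expect = np.interp(grid, xp, rec.forces[a:b, j])
            np.testing.assert_allclose(curves[list(curves)[0]][0][:, j], expect)

    def test_groups_by_condition(self, noiseless_trial):
        curves = pf.stride_normalize(noiseless_trial, noiseless_trial.heel_strikes)
        assert set(curves) == {"LW", "SA", "SD"}
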