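"""Optics-to-hemoglobin conversion, FIR filtering and artifact masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as _sig

from nfloop import (
    ChannelMontage,
    FilterSpec,
    HemoTimeSeries,
    MbllConstants,
    concentrations_to_od,
    detect_motion_artifacts,
    intensities_to_od,
    lowpass_filter,
    od_to_concentrations,
    rebase_to_baseline,
)
from nfloop.errors import ChannelUnusableError, ConfigError, SignalError, TooShortToFilterError
from nfloop.signal_core import design_lowpass


def make_series(hbo, fs=2.0, mask=None):
    hbo = np.atleast_2d(np.asarray(hbo, float))
    if hbo.shape[0] == 1:
        hbo = hbo.T
    t = np.arange(hbo.shape[0]) / fs
    return HemoTimeSeries(t, hbo, np.zeros_like(hbo),
                          mask if mask is not None else np.zeros(hbo.shape, bool),
                          fs)


class TestMontage:
    def test_default_groups_are_valid(self):
        m = ChannelMontage()
        assert m.n_channels == 16
        assert len(m.left_group) == len(m.right_group) == 4
        assert not set(m.left_group) & set(m.right_group)

    @pytest.mark.parametrize("kwargs", [
        dict(left_group=(), right_group=(1,)),
        dict(left_group=(1,), right_group=(1,)),
        dict(left_group=(0,), right_group=(2,)),
        dict(left_group=(17,), right_group=(2,)),
    ])
    def test_invalid_montages_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ChannelMontage(**kwargs)


class TestOpticalDensity:
    def test_reference_intensity_gives_zero_od(self):
        I = np.full((10, 3), 2000.0)
        assert np.allclose(intensities_to_od(I, I[0]), 0.0)

    def test_tenfold_drop_is_one_od_unit(self):
        I = np.full(5, 100.0)
        I[2] = 10.0
        od = intensities_to_od(I, 100.0)
        assert od[2] == pytest.approx(1.0)

    def test_matches_per_sample_log_ratio(self, rng):
        """Brute-force per-sample -log10(I/Iref) oracle."""
        I = rng.uniform(10, 5000, size=(50, 4))
        ref = rng.uniform(10, 5000, size=4)
        expected = np.array([[-np.log10(I[i, c] / ref[c])
                              for c in range(4)] for i in range(50)])
        assert np.allclose(intensities_to_od(I, ref), expected)

    def test_non_positive_intensity_rejected_with_location(self):
        I = np.ones((4, 2))
        I[2, 1] = 0.0
        with pytest.raises(SignalError, match=r"\[2, 1\]"):
            intensities_to_od(I, 1.0)


class TestMbll:
    def test_zero_od_gives_zero_concentrations(self):
        hbo, hbr = od_to_concentrations(np.zeros((2, 7)))
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_forward_backward_round_trip(self):
        od = concentrations_to_od(np.array([1.0]), np.array([-0.2]))
        hbo, hbr = od_to_concentrations(od)
        assert hbo[0] == pytest.approx(1.0, abs=1e-9)
        assert hbr[0] == pytest.approx(-0.2, abs=1e-9)

    def test_linearity_doubling_od_doubles_concentrations(self):
        od = concentrations_to_od(np.array([0.7]), np.array([0.3]))
        h1, r1 = od_to_concentrations(od)
        h2, r2 = od_to_concentrations(2 * od)
        assert h2[0] == pytest.approx(2 * h1[0])
        assert r2[0] == pytest.approx(2 * r1[0])

    @settings(deadline=None, max_examples=50)
    @given(
        hbo=st.floats(-50, 50), hbr=st.floats(-50, 50),
        dpf=st.floats(3, 8), L=st.floats(1, 4),
    )
    def test_round_trip_property(self, hbo, hbr, dpf, L):
        """MBLL inversion recovers any concentration pair to 1e-9."""
        c = MbllConstants(pathlength=L, dpf=(dpf, dpf))
        od = concentrations_to_od(np.array([hbo]), np.array([hbr]), c)
        h, r = od_to_concentrations(od, c)
        assert abs(h[0] - hbo) < 1e-9
        assert abs(r[0] - hbr) < 1e-9

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigError):
            MbllConstants(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestLowpassFilter:
    def test_tap_count_is_order_plus_one(self):
        assert design_lowpass(FilterSpec(order=20)).size == 21

    def test_dc_gain_unity_on_constant_series(self):
        s = make_series(np.full(200, 3.7))
        out = lowpass_filter(s)
        assert np.allclose(out.hbo, 3.7, atol=0.01 * 3.7)

    def test_half_hertz_attenuated_by_20_db(self):
        """The designed response at 0.5 Hz is the independent oracle."""
        taps = design_lowpass(FilterSpec())
        w, h = _sig.freqz(taps, worN=[0.5], fs=2.0)
        assert 20 * np.log10(abs(h[0])) <= -20
        t = np.arange(600) / 2.0
        s = make_series(np.sin(2 * np.pi * 0.5 * t))
        out = lowpass_filter(s)
        interior = out.hbo[50:-50, 0]
        rms_ratio = np.sqrt((interior ** 2).mean()) / np.sqrt(0.5)
        assert 20 * np.log10(rms_ratio) <= -20

    def test_linear_and_shift_invariant(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        a, b = 2.5, -1.3
        fx = lowpass_filter(make_series(x)).hbo[:, 0]
        fy = lowpass_filter(make_series(y)).hbo[:, 0]
        fab = lowpass_filter(make_series(a * x + b * y)).hbo[:, 0]
        assert np.allclose(fab[30:-30], (a * fx + b * fy)[30:-30], atol=1e-9)

    def test_too_short_series_raises(self):
        with pytest.raises(TooShortToFilterError):
            lowpass_filter(make_series(np.zeros(10)))


class TestMotionArtifacts:
    def test_constant_signal_empty_mask(self):
        mask, usable = detect_motion_artifacts(np.zeros((100, 2)), fs=2.0)
        assert not mask.any() and usable.all()

    def test_infinite_threshold_empty_mask(self, rng):
        x = rng.normal(size=(200, 3))
        mask, _ = detect_motion_artifacts(x, 2.0, z_thresh=np.inf)
        assert not mask.any()

    def test_injected_step_is_flagged_and_covered(self, rng):
        x = rng.normal(0, 0.1, size=400)
        x[200:] += 10 * 0.1 * 10  # step of 10x the rolling SD scale
        mask, usable = detect_motion_artifacts(x, fs=2.0, window_s=10)
        # windows overlapping the step are flagged...
        assert mask[195:205].all()
        # ...but samples far from it are not
        assert not mask[:150].any()
        assert not mask[300:].any()
        assert usable[0]

    def test_mask_monotone_in_threshold(self, rng):
        x = rng.normal(size=500)
        x[100:110] += 5
        loose, _ = detect_motion_artifacts(x, 2.0, z_thresh=4.0)
        tight, _ = detect_motion_artifacts(x, 2.0, z_thresh=2.0)
        # lowering the threshold never unflags a sample
        assert np.all(tight[loose])

    def test_mostly_contaminated_channel_marked_unusable(self, rng):
        # sparse huge spikes whose flagged windows cover > half the samples
        x = rng.normal(0, 0.05, size=200)
        x[[30, 90, 150]] += 50.0
        _, usable = detect_motion_artifacts(x, 2.0, max_reject=0.5)
        assert not usable[0]


class TestRebase:
    def test_constant_series_becomes_zero(self):
        s = make_series(np.full((100, 2), 4.2))
        out = rebase_to_baseline(s, (10.0, 20.0))
        assert np.allclose(out.hbo, 0.0)

    def test_window_mean_is_zero_after_rebase(self, rng):
        s = make_series(rng.normal(3, 1, size=(200, 4)))
        out = rebase_to_baseline(s, (20.0, 30.0))
        sel = (out.time >= 20) & (out.time < 30)
        assert np.allclose(out.hbo[sel].mean(axis=0), 0.0, atol=1e-9)

    def test_rebasing_is_idempotent(self, rng):
        s = make_series(rng.normal(size=(150, 3)))
        once = rebase_to_baseline(s, (5.0, 15.0))
        twice = rebase_to_baseline(once, (5.0, 15.0))
        assert np.allclose(once.hbo, twice.hbo, atol=1e-12)

    def test_masked_samples_excluded_from_baseline_mean(self):
        hbo = np.zeros((40, 1))
        hbo[4:8] = 100.0  # artifact inside the baseline window
        mask = np.zeros((40, 1), bool)
        mask[4:8] = True
        s = make_series(hbo[:, 0], mask=mask)
        out = rebase_to_baseline(s, (0.0, 10.0))
        assert np.allclose(out.hbo[~mask[:, 0].astype(bool), 0][:2], 0.0)

    def test_fully_masked_baseline_rejected(self):
        mask = np.zeros((40, 1), bool)
        mask[:20] = True
        s = make_series(np.ones(40), mask=mask)
        with pytest.raises(ChannelUnusableError):
            rebase_to_baseline(s, (0.0, 10.0))
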