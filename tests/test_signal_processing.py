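import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from synemg.signal_processing import (DpCycle, RawChannelSeries, filter_emg,
                                      filter_kinematics, normalize_emg,
                                      segment_cycles, time_normalize)

RATE = 2000.0


def _sine(freq, rate=RATE, duration=2.0, amp=1.0):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilterEmg:
    def test_zero_in_zero_out(self):
        out = filter_emg(RawChannelSeries(np.zeros(4000), RATE))
        assert np.all(out.samples == 0)

    def test_below_band_attenuated(self):
        # 10 Hz lies well under the 50 Hz band edge
        x = _sine(10.0)
        out = filter_emg(RawChannelSeries(x, RATE)).samples
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_in_band_envelope_is_rectified_mean(self):
        # mean of |A sin| is 2A/pi; 150 Hz passes the band essentially unity
        amp = 2.0
        x = _sine(150.0, duration=4.0, amp=amp)
        out = filter_emg(RawChannelSeries(x, RATE)).samples
        core = out[2000:-2000]  # keep away from filter edges
        assert np.mean(core) == pytest.approx(2 * amp / np.pi, rel=0.05)

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            filter_emg(RawChannelSeries(np.zeros(100), 500.0))

    @settings(deadline=None, max_examples=25)
    @given(npst.arrays(np.float64, 1200, elements=st.floats(-10, 10)))
    def test_envelope_nonnegative(self, values):
        out = filter_emg(RawChannelSeries(values, RATE))
        assert np.all(out.samples >= 0)


class TestFilterKinematics:
    def test_dc_gain_unity(self):
        out = filter_kinematics(RawChannelSeries(np.full(400, 3.7), 200.0))
        assert np.allclose(out.samples, 3.7)

    @pytest.mark.parametrize("freq, passes", [(1.0, True), (50.0, False)])
    def test_frequency_response(self, freq, passes):
        x = _sine(freq, rate=200.0, duration=10.0)
        out = filter_kinematics(RawChannelSeries(x, 200.0)).samples
        amp = np.max(np.abs(out[400:-400]))
        if passes:
            assert amp == pytest.approx(1.0, rel=0.01)
        else:
            assert amp < 0.01

    def test_rate_check(self):
        with pytest.raises(ValueError):
            filter_kinematics(RawChannelSeries(np.zeros(50), 15.0))


class TestNormalizeEmg:
    def test_global_max_is_one_and_ratio_kept(self):
        t1 = np.array([0.0, 1.0, 2.0])
        t2 = np.array([0.0, 4.0])
        n1, n2 = normalize_emg([t1, t2])
        assert n2.max() == 1.0
        assert n1.max() == pytest.approx(0.5)

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        trials = [rng.random(50), rng.random(70)]
        once = normalize_emg(trials)
        scaled = normalize_emg([7.3 * t for t in trials])
        twice = normalize_emg(once)
        for a, b, c in zip(once, scaled, twice):
            assert np.allclose(a, b)
            assert np.allclose(a, c)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="normalization undefined"):
            normalize_emg([np.zeros(10), np.zeros(5)])


def _cosine_height(n_cycles, rate=200.0, T=1.2, lead=0.3):
    # peaks at t = lead, lead + T, ...: all interior to the record
    t = np.arange(int((n_cycles * T + 2 * lead) * rate) + 1) / rate
    return np.cos(2 * np.pi * (t - lead) / T)


class TestSegmentCycles:
    def test_cosine_poling_is_first_half_period(self):
        cycles = segment_cycles(RawChannelSeries(_cosine_height(6), 200.0))
        for c in cycles:
            half = (c.transition - c.start) / (c.end - c.start)
            assert half == pytest.approx(0.5, abs=0.02)

    def test_fourteen_cycles_detected(self):
        cycles = segment_cycles(RawChannelSeries(_cosine_height(14), 200.0))
        assert len(cycles) == 14

    def test_noisy_boundaries_match_clean_oracle(self):
        rate = 200.0
        clean = _cosine_height(8)
        rng = np.random.default_rng(3)
        noisy_raw = clean + 0.01 * rng.standard_normal(clean.shape)
        # height channels are low-pass filtered before segmentation
        noisy = filter_kinematics(RawChannelSeries(noisy_raw, rate)).samples
        ref = segment_cycles(RawChannelSeries(clean, rate))
        got = segment_cycles(RawChannelSeries(noisy, rate))
        assert len(got) == len(ref)
        for a, b in zip(ref, got):
            assert abs(a.start - b.start) <= 2
            assert abs(a.transition - b.transition) <= 2

    def test_flat_signal_rejected(self):
        with pytest.raises(ValueError):
            segment_cycles(RawChannelSeries(np.ones(1000), 200.0))


class TestTimeNormalize:
    def test_uniform_100_grid_is_identity(self):
        x = np.arange(101, dtype=float)  # cycle occupies samples 0..100
        cyc = DpCycle(0, 50, 100, rate=100.0)
        out = time_normalize(x, cyc)
        assert np.allclose(out, x[:100])

    def test_affine_signal_preserved(self):
        x = 3.0 - 0.25 * np.arange(173)
        cyc = DpCycle(0, 80, 172, rate=100.0)
        out = time_normalize(x, cyc)
        # reconstruct the affine law on the resampled grid
        targets = np.concatenate([0 + 80 * np.arange(50) / 50,
                                  80 + 92 * np.arange(50) / 50])
        assert np.allclose(out, 3.0 - 0.25 * targets)

    def test_quadratic_within_interpolation_bound(self):
        c2 = 0.004
        i = np.arange(173, dtype=float)
        x = 1.0 + 0.05 * i + c2 * i**2
        cyc = DpCycle(0, 86, 172, rate=100.0)
        out = time_normalize(x, cyc)
        targets = np.concatenate([0 + 86 * np.arange(50) / 50,
                                  86 + 86 * np.arange(50) / 50])
        exact = 1.0 + 0.05 * targets + c2 * targets**2
        # linear interpolation error bound: |f''| h^2 / 8 with h = 1 sample
        assert np.max(np.abs(out - exact)) <= 2 * c2 / 8 + 1e-12

    def test_phase_ordering_monotone(self):
        cyc = DpCycle(0, 40, 130, rate=100.0)
        out = time_normalize(np.arange(131, dtype=float), cyc)
        assert np.all(np.diff(out) > 0)

    def test_degenerate_phase_rejected(self):
        with pytest.raises(ValueError):
            DpCycle(0, 0, 100, rate=100.0)
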