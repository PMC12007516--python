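"""Clock alignment: transforms, edge detection, affine fit, resampling, ECG."""

import numpy as np
import pytest

from perceptmeg.alignment import (
    ClockMap,
    EdgeList,
    detect_stim_edges,
    ecg_xcorr_lag,
    fit_clock_map,
    jump_robust_transform,
    resample_to_meg_clock,
)
from perceptmeg.simulate import LfpStream, ecg_template_train, inject_clock_drift


def _toggled_signal(fs=1000.0, f_stim=145.0, cycles=((2, 6), (8, 12), (14, 18),
                                                     (20, 24), (26, 30)),
                    duration=32.0, noise=0.05, seed=0, jumps=False):
    rng = np.random.default_rng(seed)
    n = int(fs * duration)
    t = np.arange(n) / fs
    env = np.zeros(n)
    for a, b in cycles:
        env[int(a * fs):int(b * fs)] = 1.0
    x = env * np.sin(2 * np.pi * f_stim * t) + noise * rng.standard_normal(n)
    if jumps:
        for tj in (5.0, 13.0, 22.0):
            x[int(tj * fs):] += 200.0 * rng.choice([-1, 1])
    truth = np.array(sorted(np.array(cycles).ravel()), float)
    return x, truth


class TestJumpRobustTransform:
    def test_constant_input(self):
        y = jump_robust_transform(np.full(100, 3.3))
        assert len(y) == 99
        assert np.allclose(y, y[0])

    def test_single_step_single_spike(self):
        x = np.zeros(1000)
        x[500:] = 1.0
        x += 1e-6 * np.sin(np.arange(1000))
        y = jump_robust_transform(x)
        assert np.argmax(y) == 499
        assert y[499] > np.median(y) + 5

    def test_too_short(self):
        with pytest.raises(ValueError):
            jump_robust_transform(np.array([1.0]))

    def test_unit_invariance(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.standard_normal(5000))
        y1 = jump_robust_transform(x)
        y2 = jump_robust_transform(1e6 * x)
        # same shape up to the additive log-scale constant
        assert np.allclose(y2 - y1, np.log(1e6), atol=1e-6)


class TestDetectStimEdges:
    def test_stim_off_returns_empty(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20_000)
        with pytest.warns(UserWarning, match="no toggling"):
            edges = detect_stim_edges(x, 1000.0, 145.0)
        assert len(edges) == 0

    def test_five_cycles_ten_edges(self):
        x, truth = _toggled_signal()
        edges = detect_stim_edges(x, 1000.0, 145.0)
        assert len(edges) == 10
        assert np.all(np.abs(edges.times - truth) < 0.05)
        assert list(edges.polarity[:2]) == ["on", "off"]

    def test_polarity_flip_invariance(self):
        x, truth = _toggled_signal()
        e1 = detect_stim_edges(x, 1000.0, 145.0)
        e2 = detect_stim_edges(-x, 1000.0, 145.0)
        assert np.allclose(e1.times, e2.times, atol=1e-6)

    def test_robust_to_broadband_noise_20db_down(self):
        x, truth = _toggled_signal(noise=0.1)  # 20 dB below envelope
        edges = detect_stim_edges(x, 1000.0, 145.0)
        assert len(edges) == 10
        assert np.all(np.abs(edges.times - truth) < 0.05)

    def test_jumpy_channel_uses_robust_transform(self):
        x, truth = _toggled_signal(jumps=True, noise=0.02)
        edges = detect_stim_edges(x, 1000.0, 145.0, robust="auto")
        matched = sum(np.min(np.abs(edges.times - tt)) < 0.2 for tt in truth)
        assert matched >= 8

    def test_aliased_stim_frequency(self):
        # 145 Hz stim in a 250 Hz stream appears at its 105 Hz alias
        fs = 250.0
        x, truth = _toggled_signal(fs=fs, f_stim=105.0)
        edges = detect_stim_edges(x, fs, 145.0)
        assert len(edges) == 10
        assert np.all(np.abs(edges.times - truth) < 0.1)

    def test_all_three_system_rates(self):
        for fs in (19200.0, 5000.0, 6000.0):
            x, truth = _toggled_signal(fs=fs)
            edges = detect_stim_edges(x, fs, 145.0)
            assert len(edges) == 10, fs
            assert np.all(np.abs(edges.times - truth) < 0.05), fs

    def test_tap_transients_detected(self):
        """Mechanical taps >= 10x noise SD produce detectable transients."""
        fs = 1000.0
        rng = np.random.default_rng(3)
        n = int(30 * fs)
        x = rng.standard_normal(n)
        t = np.arange(n) / fs
        taps = (5.0, 12.0, 21.0)
        for tt in taps:
            seg = (t >= tt) & (t < tt + 1.0)
            x[seg] += 10.0 * np.sin(2 * np.pi * 20.0 * (t[seg] - tt))
        edges = detect_stim_edges(x, fs, 20.0, min_state=0.2)
        for tt in taps:
            assert np.min(np.abs(edges.times - tt)) < 0.4, tt


def _edge_list(times, start="on"):
    pol = ["on", "off"] * (len(times) // 2 + 1)
    if start == "off":
        pol = pol[1:]
    return EdgeList(np.asarray(times, float),
                    np.array(pol[:len(times)], dtype="<U3"),
                    np.ones(len(times)))


class TestClockMapFit:
    def test_identity(self):
        e = _edge_list([1.0, 5.0, 9.0, 13.0])
        m = fit_clock_map(e, e)
        assert m.offset == pytest.approx(0.0, abs=1e-12)
        assert m.rate == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(m.residuals, 0.0)

    def test_offset_and_drift_recovery(self):
        t_meg = np.array([5.0, 40.0, 90.0, 150.0, 230.0, 295.0])
        a, b = 1.25, 1.0 + 5e-5
        t_lfp = a + b * t_meg
        m = fit_clock_map(_edge_list(t_meg), _edge_list(t_lfp))
        assert abs(m.offset - a) < 1e-3
        assert abs(m.rate - b) < 1e-6

    def test_two_events_exact(self):
        m = fit_clock_map(_edge_list([2.0, 200.0]),
                          _edge_list([2.5, 200.51]))
        assert np.allclose(m.residuals, 0.0, atol=1e-9)

    def test_count_mismatch_lists_unpaired(self):
        with pytest.raises(ValueError, match="unpaired"):
            fit_clock_map(_edge_list([1.0, 2.0, 3.0, 4.0]),
                          _edge_list([1.0, 2.0]))

    def test_polarity_mismatch(self):
        with pytest.raises(ValueError, match="polarity"):
            fit_clock_map(_edge_list([1.0, 2.0]),
                          _edge_list([1.0, 2.0], start="off"))

    def test_composition_returns_identity(self):
        t_meg = np.array([3.0, 50.0, 120.0, 200.0])
        m = fit_clock_map(_edge_list(t_meg),
                          _edge_list(0.7 + (1 + 2e-5) * t_meg))
        corrected = m.lfp_to_meg(0.7 + (1 + 2e-5) * t_meg)
        m2 = fit_clock_map(_edge_list(t_meg), _edge_list(corrected))
        assert abs(m2.offset) < 1e-9
        assert abs(m2.rate - 1.0) < 1e-12

    def test_jitter_degrades_monotonically(self):
        rng = np.random.default_rng(7)
        t_meg = np.linspace(5, 295, 20)
        rms = []
        for jit in (0.0, 0.01, 0.05, 0.2):
            t_lfp = 0.5 + t_meg + rng.normal(0, jit, len(t_meg))
            m = fit_clock_map(_edge_list(t_meg), _edge_list(t_lfp))
            rms.append(np.sqrt(np.mean(m.residuals**2)))
        assert rms[0] <= rms[1] <= rms[2] <= rms[3]

    def test_rate_invariant_enforced(self):
        with pytest.raises(ValueError, match="rate"):
            ClockMap(offset=0.0, rate=1.01)


class TestResample:
    def _sine_lfp(self, duration=300.0, f=20.0):
        t = np.arange(int(250.0 * duration)) / 250.0
        x = np.sin(2 * np.pi * f * t)
        return LfpStream(data=np.stack([x, x]), fs=250.0)

    def test_identity_map_roundtrip(self):
        lfp = self._sine_lfp(duration=30.0)
        out = resample_to_meg_clock(lfp, ClockMap.identity(), target_fs=250.0)
        n = min(out.shape[1], lfp.n_samples)
        assert np.allclose(out[0][:n], lfp.data[0][:n], atol=1e-9)

    def test_drift_correction_roundtrip(self):
        """inject drift -> fit from truth events -> resample -> < 1 sample."""
        offset, rate = 1.25, 1.0 + 5e-5
        lfp = self._sine_lfp(duration=300.0)
        drifted = inject_clock_drift(lfp, offset, rate)
        t_meg = np.linspace(5, 290, 6)
        m = fit_clock_map(_edge_list(t_meg),
                          _edge_list(offset + rate * t_meg))
        out = resample_to_meg_clock(drifted, m, target_fs=250.0)
        # compare against the original on the overlapping interior
        i0, i1 = int(5 * 250), int(280 * 250)
        a = out[0][i0:i1]
        b = lfp.data[0][i0:i1]
        corr = np.correlate(a - a.mean(), b - b.mean(), mode="same")
        lag = np.argmax(corr) - len(a) // 2
        assert abs(lag) < 1  # residual misalignment under one LFP sample

    def test_sine_through_drift_and_correction_lag_zero(self):
        lfp = self._sine_lfp(duration=60.0)
        drifted = inject_clock_drift(lfp, 0.4, 1.0 + 2e-5)
        m = ClockMap(offset=0.4, rate=1.0 + 2e-5)
        out = resample_to_meg_clock(drifted, m, target_fs=250.0)
        n = min(out.shape[1], lfp.n_samples) - 500
        a, b = out[0][500:n], lfp.data[0][500:n]
        corr = np.correlate(a, b, mode="same")
        assert abs(np.argmax(corr) - len(a) // 2) == 0

    def test_extrapolation_guard(self):
        # negative offset: MEG time zero maps 5 s before the LFP support
        lfp = self._sine_lfp(duration=30.0)
        with pytest.raises(ValueError, match="extrapolate"):
            resample_to_meg_clock(lfp, ClockMap(offset=-5.0, rate=1.0))


class TestEcgXcorr:
    def _ecg(self, fs=250.0, duration=60.0, seed=0):
        rng = np.random.default_rng(seed)
        beats = np.cumsum(rng.uniform(0.8, 1.0, int(duration)))
        beats = beats[beats < duration - 1]
        return ecg_template_train(beats, fs, duration)

    def test_self_lag_zero(self):
        x = self._ecg()
        res = ecg_xcorr_lag(x, x, 250.0)
        assert res.lag == 0.0
        assert res.confidence > 1.2

    def test_known_shift_recovered(self):
        fs = 250.0
        ecg = self._ecg(fs=fs, duration=90.0)
        shift = int(3.2 * fs)
        lfp = np.roll(ecg, shift) + 0.05 * np.random.default_rng(1).standard_normal(len(ecg))
        res = ecg_xcorr_lag(lfp[shift:], ecg[shift:], fs)  # same support
        res_full = ecg_xcorr_lag(np.roll(ecg, shift), ecg, fs)
        assert abs(res_full.lag - 3.2) <= 1.0 / fs + 1e-9

    def test_no_ecg_low_confidence(self):
        rng = np.random.default_rng(3)
        lfp = rng.standard_normal(250 * 120)
        ecg = self._ecg(duration=120.0, seed=3)
        with pytest.warns(UserWarning, match="unreliable"):
            ecg_xcorr_lag(lfp, ecg, 250.0)

    def test_overlap_precondition(self):
        with pytest.raises(ValueError, match="10 s"):
            ecg_xcorr_lag(np.zeros(100), np.zeros(100), 250.0)
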