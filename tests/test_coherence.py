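"""Epoching, MSC, permutation statistics and DICS imaging on toy data."""

import numpy as np
import pytest

from perceptmeg.coherence import (
    Epochs,
    dics_band,
    epoch_pair,
    msc,
    permutation_test,
)
from perceptmeg.forward import sphere_leadfield
from perceptmeg.profiles import ChannelInfo
from perceptmeg.simulate import Recording
from perceptmeg.spectral import reject_bad_segments


def _channels(n):
    return tuple(
        ChannelInfo(
            name=f"C{i}", ctype="mag", units="fT",
            position=np.array([0.0, 0.0, 0.1]),
            orientation=np.array([0.0, 0.0, 1.0]),
        )
        for i in range(n)
    )


def _epochs_from(arr, fs=100.0):
    names = tuple(f"ch{i}" for i in range(arr.shape[1]))
    return Epochs(data=arr, fs=fs, channel_names=names,
                  epoch_length=arr.shape[-1] / fs)


def _narrowband(rng, n, fs, f0, bw=2.0):
    from scipy import signal

    x = rng.standard_normal(n)
    sos = signal.butter(4, [f0 - bw / 2, f0 + bw / 2], btype="bandpass",
                        fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / np.std(y)


class TestEpochPair:
    def _rec(self, duration, fs=100.0, n_ch=3, rng=None):
        rng = rng or np.random.default_rng(0)
        n = int(duration * fs)
        return Recording(data=rng.standard_normal((n_ch, n)), fs=fs,
                         channels=_channels(n_ch))

    def test_clean_recording_epoch_count(self):
        rec = self._rec(120.0)
        lfp = np.zeros(rec.n_samples) + np.random.default_rng(1).standard_normal(rec.n_samples)
        ep = epoch_pair(rec, lfp, length=1.0)
        assert ep.n_epochs == 120
        assert ep.channel_names[-1] == "LFP_REF"

    def test_samples_per_epoch(self):
        rec = self._rec(30.0, fs=5000.0, n_ch=1)
        ep = epoch_pair(rec, np.zeros(rec.n_samples) + 1e-3, length=1.0)
        assert ep.data.shape[-1] == 5000

    def test_rejected_segments_drop_epochs(self):
        rec = self._rec(120.0)
        mask = reject_bad_segments(rec, segment_length=3.0)
        mask.keep[0, [5, 15, 30]] = False  # three 3 s segments
        ep = epoch_pair(rec, np.ones(rec.n_samples), length=1.0, mask=mask)
        # segment-overlap oracle: each bad 3 s segment removes 3 epochs
        assert ep.n_epochs == 120 - 9

    def test_too_few_epochs(self):
        rec = self._rec(5.0)
        with pytest.raises(ValueError, match="too short"):
            epoch_pair(rec, np.ones(rec.n_samples), length=1.0)


class TestMsc:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal((30, 1, 100))
        arr = np.concatenate([x, x], axis=1)
        coh = msc(_epochs_from(arr), ref=-1)
        assert np.allclose(coh.values[1], 1.0)

    def test_independence_bias_one_over_l(self, rng):
        L = 60
        arr = rng.standard_normal((L, 2, 100))
        coh = msc(_epochs_from(arr), ref=-1)
        mean_c = np.mean(coh.values[0][1:-1])
        assert mean_c == pytest.approx(1.0 / L, rel=0.35)

    def test_constructed_coherence_level(self, rng):
        """Shared + independent mixture with known MSC = 0.5."""
        L, n, fs, level = 120, 100, 100.0, 0.5
        shared = np.stack([_narrowband(rng, n, fs, 20.0) for _ in range(L)])
        a = np.stack([_narrowband(rng, n, fs, 20.0) for _ in range(L)])
        b = np.stack([_narrowband(rng, n, fs, 20.0) for _ in range(L)])
        x = np.sqrt(level) * shared + np.sqrt(1 - level) * a
        y = np.sqrt(level) * shared + np.sqrt(1 - level) * b
        arr = np.stack([x, y], axis=1)
        coh = msc(_epochs_from(arr), ref=1)
        i20 = np.argmin(np.abs(coh.freqs - 20.0))
        # E[MSC] = level^2 for two noisy copies sharing `level` variance
        est = coh.values[0][i20]
        se = 3 * (1 - level**2) / np.sqrt(L)
        assert abs(est - level**2) < se

    def test_zero_variance_channel_missing(self, rng):
        arr = rng.standard_normal((20, 3, 64))
        arr[:, 1, :] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            coh = msc(_epochs_from(arr), ref=-1)
        assert np.all(np.isnan(coh.values[1]))

    def test_bounds_on_random_input(self, rng):
        arr = rng.standard_normal((25, 5, 80))
        coh = msc(_epochs_from(arr), ref=0)
        finite = coh.values[np.isfinite(coh.values)]
        assert finite.min() >= 0.0 and finite.max() <= 1.0


class TestPermutationTest:
    def test_degenerate_null_gives_zero_t(self, rng):
        # ref identical in every epoch: permutation changes nothing,
        # null equals observed and the t map collapses to zero
        L = 24
        arr = rng.standard_normal((L, 3, 64))
        arr[:, -1, :] = arr[0, -1, :]
        res = permutation_test(_epochs_from(arr), ref=-1, n_perm=5, seed=0)
        assert np.allclose(res.t_map, 0.0)

    def test_planted_coupling_detected(self, rng):
        L, n, fs = 60, 100, 100.0
        n_meg = 12
        shared = np.stack([_narrowband(rng, n, fs, 20.0) for _ in range(L)])
        arr = rng.standard_normal((L, n_meg + 1, n))
        for c in range(5):
            arr[:, c, :] = 2.0 * shared + 0.5 * rng.standard_normal((L, n))
        arr[:, -1, :] = shared + 0.3 * rng.standard_normal((L, n))
        res = permutation_test(_epochs_from(arr), ref=-1, n_perm=10,
                               extent=1, seed=1)
        i20 = np.argmin(np.abs(res.freqs - 20.0))
        hits = sum(bool(res.mask[c, i20 - 1:i20 + 2].any()) for c in range(5))
        assert hits >= 4
        assert not res.mask[5:, :].any()

    def test_type_one_error_controlled(self, rng):
        """Loose FWE check: null rejections in <= 10% of runs at alpha 5%."""
        n_sig = 0
        runs = 60
        for r in range(runs):
            arr = rng.standard_normal((30, 6, 60))
            res = permutation_test(_epochs_from(arr), ref=-1, n_perm=10,
                                   extent=1, seed=r)
            n_sig += bool(res.mask.any())
        assert n_sig / runs <= 0.10

    def test_maxstat_resolution_guard(self, rng):
        arr = rng.standard_normal((25, 3, 64))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(_epochs_from(arr), ref=-1, n_perm=10,
                             alpha=0.05, correction="maxstat")

    def test_extent_threshold_prunes_singletons(self, rng):
        arr = rng.standard_normal((30, 4, 64))
        res = permutation_test(_epochs_from(arr), ref=-1, n_perm=10,
                               alpha=0.9999, extent=10_000, seed=2,
                               correction="bonferroni")
        assert not res.mask.any()


def _toy_setup(rng, n_grid_half=0.04, spacing=0.01):
    """OPM-like magnetometer cap + regular grid in the upper hemisphere."""
    from perceptmeg.profiles import make_profile

    chans = make_profile("opm").channels[:40]
    ax = np.arange(-n_grid_half, n_grid_half + 1e-9, spacing)
    X, Y, Z = np.meshgrid(ax, ax, ax[ax >= 0.01], indexing="ij")
    grid = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    grid = grid[np.linalg.norm(grid, axis=1) < 0.075]
    lf = sphere_leadfield(grid, chans)
    return chans, grid, lf


def _coupled_epochs(rng, lf, grid, chans, src_idx, L=60, n=100, fs=100.0,
                    f0=20.0, noise=1.0, coupling=1.0):
    shared = np.stack([_narrowband(rng, n, fs, f0) for _ in range(L)])
    gains = lf.lf[src_idx] @ np.array([1.0, 0.5, 0.0])
    gains = gains / np.max(np.abs(gains))
    arr = noise * rng.standard_normal((L, len(chans) + 1, n))
    arr[:, :-1, :] += coupling * 10.0 * gains[None, :, None] * shared[:, None, :]
    arr[:, -1, :] = shared + 0.5 * rng.standard_normal((L, n))
    return _epochs_from(arr, fs=fs)


class TestDics:
    def test_planted_source_localized(self, rng):
        chans, grid, lf = _toy_setup(rng)
        src = len(grid) // 2
        ep = _coupled_epochs(rng, lf, grid, chans, src)
        img = dics_band(ep, ref=-1, band=(15.0, 35.0), lf=lf,
                        rank=len(chans))
        best = int(np.argmax(img.values))
        dist = np.linalg.norm(grid[best] - grid[src])
        assert dist <= 0.0101  # within one 10 mm grid step

    def test_no_coupling_lower_peak_z(self, rng):
        chans, grid, lf = _toy_setup(rng)
        src = len(grid) // 2
        ep_c = _coupled_epochs(rng, lf, grid, chans, src)
        rng2 = np.random.default_rng(99)
        ep_n = _coupled_epochs(rng2, lf, grid, chans, src, coupling=0.0)
        img_c = dics_band(ep_c, -1, (15.0, 35.0), lf, rank=len(chans))
        img_n = dics_band(ep_n, -1, (15.0, 35.0), lf, rank=len(chans))
        assert img_c.values.max() > img_n.values.max()

    def test_rank_truncation_identity_when_full(self, rng):
        chans, grid, lf = _toy_setup(rng)
        ep = _coupled_epochs(rng, lf, grid, chans, 0, L=80)
        full = dics_band(ep, -1, (15.0, 35.0), lf, rank=len(chans))
        with pytest.warns(UserWarning, match="clamped"):
            clamped = dics_band(ep, -1, (15.0, 35.0), lf, rank=10_000)
        assert np.allclose(full.values, clamped.values, atol=1e-9)

    def test_band_outside_support(self, rng):
        chans, grid, lf = _toy_setup(rng)
        ep = _coupled_epochs(rng, lf, grid, chans, 0)
        with pytest.raises(ValueError, match="band"):
            dics_band(ep, -1, (500.0, 600.0), lf)

    def test_values_bounded(self, rng):
        chans, grid, lf = _toy_setup(rng)
        ep = _coupled_epochs(rng, lf, grid, chans, 3)
        img = dics_band(ep, -1, (15.0, 35.0), lf, rank=30)
        assert np.all((img.values >= 0) & (img.values <= 1))
        assert img.z is not None

    def test_upper_quadrant_recovery(self, rng):
        """Structural stand-in for the sensorimotor-peak pattern: a source
        planted in the +x/+y quadrant localizes to that quadrant."""
        chans, grid, lf = _toy_setup(rng)
        quadrant = (grid[:, 0] > 0.005) & (grid[:, 1] > 0.005)
        src = int(np.flatnonzero(quadrant)[len(np.flatnonzero(quadrant)) // 2])
        ep = _coupled_epochs(rng, lf, grid, chans, src)
        img = dics_band(ep, -1, (15.0, 35.0), lf, rank=len(chans))
        best = int(np.argmax(img.values))
        assert grid[best, 0] > 0 and grid[best, 1] > 0
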