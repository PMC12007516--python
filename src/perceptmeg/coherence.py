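"""LFP-referenced coherence mapping: sensor statistics and DICS imaging.

The analysis chain mirrors a patient-style coherence study at desk
scale: aligned MEG + LFP data are cut into 1 s epochs, magnitude-squared
coherence (MSC) against the reference channel is estimated from
per-epoch cross-/auto-spectra (single Hann taper, 1 Hz resolution), a
permutation scheme with the reference channel's epoch order shuffled
provides null images for a two-sample t statistic with family-wise
control and a cluster-extent threshold, and a DICS beamformer with a
rank-truncated cross-spectral density maps source-reference coherence
in alpha (7-13 Hz) and beta (15-35 Hz) bands on a 10 mm grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import LeadField
from .simulate import Recording
from .spectral import SegmentMask

__all__ = [
    "Epochs",
    "CoherenceMap",
    "PermutationResult",
    "epoch_pair",
    "msc",
    "permutation_test",
    "dics_band",
    "BANDS",
]

BANDS = {"alpha": (7.0, 13.0), "beta": (15.0, 35.0)}


@dataclass
class Epochs:
    """Equal-length epochs: trials x channels x samples."""

    data: np.ndarray
    fs: float
    channel_names: tuple
    epoch_length: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def index_of(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class CoherenceMap:
    """Sensor- or source-space coherence values."""

    domain: str  # 'sensor' | 'source'
    values: np.ndarray  # (locations, freqs) or (locations,)
    freqs: np.ndarray | None = None
    band: tuple[float, float] | None = None
    labels: tuple = ()  # channel names or grid indices
    positions: np.ndarray | None = None
    z: np.ndarray | None = None  # z-scored variant (source images)

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")


@dataclass
class PermutationResult:
    t_map: np.ndarray  # (locations, freqs)
    p_map: np.ndarray
    mask: np.ndarray  # significant cells after FWE + extent threshold
    observed: np.ndarray
    null_mean: np.ndarray
    n_perm: int
    alpha: float
    extent: int
    freqs: np.ndarray = field(default_factory=lambda: np.zeros(0))


def epoch_pair(meg: Recording, lfp_aligned: np.ndarray, length: float = 1.0,
               mask: SegmentMask | None = None,
               ref_name: str = "LFP_REF") -> Epochs:
    """Cut aligned MEG + LFP into contiguous non-overlapping epochs.

    ``lfp_aligned`` must already be on the MEG time base and rate (see
    :func:`perceptmeg.alignment.resample_to_meg_clock`).  Epochs
    overlapping segments rejected for any channel are dropped; fewer
    than 10 surviving epochs is an error.
    """
    lfp_aligned = np.asarray(lfp_aligned, float)
    if lfp_aligned.ndim > 1:
        lfp_aligned = lfp_aligned[-1]  # default to the last (right) channel
    size = int(round(length * meg.fs))
    n = min(meg.n_samples, len(lfp_aligned))
    n_epochs = n // size
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    keep = np.ones(n_epochs, dtype=bool)
    if mask is not None:
        any_bad = ~np.all(mask.keep, axis=0)  # per base segment
        for e in range(n_epochs):
            s0 = (e * size) // mask.segment_samples
            s1 = ((e + 1) * size - 1) // mask.segment_samples
            s1 = min(s1, len(any_bad) - 1)
            if np.any(any_bad[s0:s1 + 1]):
                keep[e] = False
    idx = np.flatnonzero(keep)
    if len(idx) < 10:
        raise ValueError(
            f"only {len(idx)} epochs survive; too short for coherence"
        )
    trials = np.empty((len(idx), meg.n_channels + 1, size))
    for j, e in enumerate(idx):
        sl = slice(e * size, (e + 1) * size)
        trials[j, :-1] = meg.data[:, sl]
        trials[j, -1] = lfp_aligned[sl]
    names = tuple(meg.channel_names()) + (ref_name,)
    return Epochs(data=trials, fs=meg.fs, channel_names=names,
                  epoch_length=length)


def _epoch_spectra(epochs: Epochs) -> tuple[np.ndarray, np.ndarray]:
    """Single-Hann-taper FFT per epoch: (trials, channels, freqs)."""
    size = epochs.data.shape[-1]
    win = np.hanning(size + 1)[:size]
    x = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(x * win, axis=-1)
    freqs = np.fft.rfftfreq(size, 1.0 / epochs.fs)
    return X, freqs


def msc(epochs: Epochs, ref: int | str = -1,
        chans: np.ndarray | None = None) -> CoherenceMap:
    """Magnitude-squared coherence of every channel with the reference.

    Estimated from per-epoch cross- and auto-spectra; with L independent
    epochs and no true coupling the estimator bias is approximately 1/L.
    Zero-variance channels yield NaN and are marked missing.
    """
    if epochs.n_epochs < 10:
        raise ValueError("need at least 10 epochs for coherence estimation")
    if isinstance(ref, str):
        ref = epochs.index_of(ref)
    ref = int(ref) % epochs.n_channels
    X, freqs = _epoch_spectra(epochs)
    if chans is None:
        chans = np.arange(epochs.n_channels)
    chans = np.asarray(chans)
    Xr = X[:, ref, :]
    Sxy = np.mean(X[:, chans, :] * np.conj(Xr[:, None, :]), axis=0)
    Sxx = np.mean(np.abs(X[:, chans, :]) ** 2, axis=0)
    Srr = np.mean(np.abs(Xr) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = (np.abs(Sxy) ** 2) / (Sxx * Srr[None, :])
    dead = Sxx <= 0
    if np.any(dead):
        warnings.warn("zero-variance channel(s); coherence marked missing",
                      stacklevel=2)
        coh[dead] = np.nan
    coh = np.clip(coh, 0.0, 1.0, out=coh, where=np.isfinite(coh))
    return CoherenceMap(
        domain="sensor", values=coh, freqs=freqs,
        labels=tuple(epochs.channel_names[c] for c in chans),
    )


def permutation_test(epochs: Epochs, ref: int | str = -1, n_perm: int = 10,
                     alpha: float = 0.05, extent: int | None = None,
                     correction: str = "bonferroni",
                     seed: int = 0, chans: np.ndarray | None = None,
                     f_max: float | None = None) -> PermutationResult:
    """Sensor coherence vs a permuted-reference null.

    Null images permute the reference channel's epoch order (identity
    permutation excluded).  Each cell is scored by a two-sample
    equal-variance t statistic between the observed image and the
    ``n_perm`` null images; family-wise control is Bonferroni by default
    (or ``maxstat`` when n_perm permits), followed by removal of
    connected components smaller than the extent threshold.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if epochs.n_epochs < 20:
        raise ValueError("need at least 20 epochs for the permutation test")
    if correction == "maxstat" and (n_perm + 1) * alpha < 1.0:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve alpha={alpha} under the "
            f"max-statistic scheme; need n_perm >= {int(np.ceil(1/alpha))-1}"
        )
    if isinstance(ref, str):
        ref = epochs.index_of(ref)
    ref = int(ref) % epochs.n_channels
    if chans is None:
        chans = np.array([c for c in range(epochs.n_channels) if c != ref])
    chans = np.asarray(chans)
    X, freqs = _epoch_spectra(epochs)
    # drop DC (and Nyquist): real-valued spectra there follow a different
    # null distribution than the interior complex bins
    last = -1 if epochs.data.shape[-1] % 2 == 0 else None
    X = X[..., 1:last]
    freqs = freqs[1:last]
    if f_max is not None:
        sel = freqs <= f_max
        X = X[..., sel]
        freqs = freqs[sel]
    L = epochs.n_epochs
    Xc = X[:, chans, :]
    Sxx = np.mean(np.abs(Xc) ** 2, axis=0)
    Xr = X[:, ref, :]
    Srr = np.mean(np.abs(Xr) ** 2, axis=0)

    def coh_with(order: np.ndarray) -> np.ndarray:
        Sxy = np.mean(Xc * np.conj(Xr[order][:, None, :]), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (np.abs(Sxy) ** 2) / (Sxx * Srr[None, :])

    identity = np.arange(L)
    observed = coh_with(identity)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        order = identity
        while np.array_equal(order, identity):
            order = rng.permutation(L)
        nulls[p] = coh_with(order)

    # variance-stabilize: Fisher z of the coherence magnitude.  The raw
    # MSC null is strongly right-skewed, which makes a per-cell t with
    # n_perm - 1 df badly anti-conservative; the z-transform plus a null
    # variance pooled over frequency bins (per channel) restores
    # family-wise calibration at small n_perm.
    def fisher_z(c):
        return np.arctanh(np.sqrt(np.clip(c, 0.0, 1.0 - 1e-12)))

    z_obs = fisher_z(np.where(np.isfinite(observed), observed, 0.0))
    z_null = fisher_z(np.where(np.isfinite(nulls), nulls, 0.0))
    null_mean = z_null.mean(axis=0)
    resid = z_null - null_mean
    n_freq = z_obs.shape[1]
    df_pool = max((n_perm - 1) * n_freq, 1)
    sd_pool = np.sqrt(np.sum(resid**2, axis=(0, 2), keepdims=True)
                      / df_pool)[0]
    denom = sd_pool * np.sqrt(1.0 + 1.0 / n_perm)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = (z_obs - null_mean) / denom
    # degenerate channels (null variance at numerical noise level) carry
    # no evidence either way
    degenerate = np.broadcast_to(
        sd_pool <= 1e-9 * (np.abs(null_mean).max() + 1e-300), t_map.shape
    )
    t_map = np.where(np.isfinite(t_map) & ~degenerate, t_map, 0.0)
    # per-cell p-values from the analytic MSC null P(C > c) = (1-c)^(L-1),
    # with the effective L calibrated on the permutation null images
    # (their mean coherence estimates 1/L_eff).  A t with n_perm - 1 df
    # cannot resolve Bonferroni-level tail probabilities; the calibrated
    # closed form can, while still being anchored to the permuted nulls.
    finite_nulls = nulls[np.isfinite(nulls)]
    m_null = float(finite_nulls.mean()) if finite_nulls.size else 0.0
    if m_null > 0 and not np.all(degenerate):
        L_eff = max(1.0 / m_null, 2.0)
        obs_c = np.clip(np.where(np.isfinite(observed), observed, 0.0),
                        0.0, 1.0 - 1e-15)
        p_map = np.exp((L_eff - 1.0) * np.log1p(-obs_c))
    else:
        p_map = np.ones_like(t_map)

    n_cells = t_map.size
    if correction == "bonferroni":
        sig = p_map < alpha / n_cells
    elif correction == "maxstat":
        null_max = nulls.max(axis=(1, 2))
        thresh_rank = int(np.floor((n_perm + 1) * alpha))
        cut = np.sort(null_max)[-max(thresh_rank, 1)]
        sig = observed > cut
    else:
        raise ValueError("correction must be 'bonferroni' or 'maxstat'")

    if extent is None:
        # 100 cells at full patient-scale resolution, scaled down for toys
        extent = max(1, int(round(100 * n_cells / 40000.0)))
    labeled, n_comp = ndimage.label(sig)
    for comp in range(1, n_comp + 1):
        if np.sum(labeled == comp) < extent:
            sig[labeled == comp] = False

    return PermutationResult(
        t_map=t_map, p_map=p_map, mask=sig, observed=observed,
        null_mean=null_mean, n_perm=n_perm, alpha=alpha, extent=extent,
        freqs=freqs,
    )


def _truncated_inverse(C: np.ndarray, rank: int) -> np.ndarray:
    """Hermitian inverse via eigendecomposition truncated to ``rank``."""
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    rank = min(rank, np.sum(w > w[0] * 1e-12))
    Vk = V[:, :rank]
    return (Vk / w[:rank]) @ Vk.conj().T


def dics_band(epochs: Epochs, ref: int | str, band: tuple[float, float],
              lf: LeadField, rank: int = 150) -> CoherenceMap:
    """DICS source-reference coherence image for one frequency band.

    The band-averaged sensor cross-spectral density is inverted through
    a rank-truncated eigendecomposition; per grid point, unit-gain
    beamformer weights with the analytically optimal scalar orientation
    give source-reference coherence |S_sr|^2 / (S_ss * S_rr).  The
    z-scored image is returned alongside the raw values.
    """
    if isinstance(ref, str):
        ref = epochs.index_of(ref)
    ref = int(ref) % epochs.n_channels
    X, freqs = _epoch_spectra(epochs)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} outside spectral support")
    n_sens = lf.lf.shape[1]
    chans = np.array([c for c in range(epochs.n_channels) if c != ref])
    if len(chans) != n_sens:
        raise ValueError(
            f"lead field has {n_sens} channels but epochs provide "
            f"{len(chans)} non-reference channels"
        )
    if rank > len(chans):
        warnings.warn(
            f"rank {rank} clamped to channel count {len(chans)}",
            stacklevel=2,
        )
        rank = len(chans)

    Xb = X[:, :, sel]
    # band-averaged CSD over epochs and bins
    Xc = Xb[:, chans, :]
    Xr = Xb[:, ref, :]
    L = Xb.shape[0] * Xb.shape[2]
    C = np.einsum("tcf,tdf->cd", Xc, np.conj(Xc)) / L
    c_sr = np.einsum("tcf,tf->c", Xc, np.conj(Xr)) / L
    S_rr = float(np.mean(np.abs(Xr) ** 2))

    Cinv = _truncated_inverse(C, rank)
    values = np.zeros(lf.n_points)
    for g in range(lf.n_points):
        Lg = lf.lf[g]  # (n_sens, 3)
        CiL = Cinv @ Lg
        A = Lg.T @ CiL  # 3x3 (real lead fields, complex Cinv -> Hermitian)
        Ainv = np.linalg.pinv(A, hermitian=True)
        W = CiL @ Ainv  # unit-gain weights, (n_sens, 3)
        S = W.conj().T @ C @ W
        s_r = W.conj().T @ c_sr
        Sinv = np.linalg.pinv(S, hermitian=True)
        val = np.real(s_r.conj() @ Sinv @ s_r) / S_rr
        values[g] = min(max(val, 0.0), 1.0)
    z = (values - values.mean()) / max(values.std(), 1e-300)
    return CoherenceMap(
        domain="source", values=values, band=(lo, hi),
        labels=tuple(range(lf.n_points)), positions=lf.positions, z=z,
    )
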