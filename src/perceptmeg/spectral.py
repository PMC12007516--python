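"""Amplitude-spectral-density estimation with bad-segment rejection.

The estimator is Welch's method (Hann window, 50% overlap, constant
detrend, mean averaging) normalized so the one-sided white-noise closed
form holds in expectation: unit-variance white noise at rate ``fs`` has
ASD ``sqrt(2 / fs)``.

Before estimation, recordings from jump-prone systems can be cleaned by
rejecting segments that contain flat stretches or discontinuous level
shifts.  Level shifts are detected on short-window medians of the
signal, which keeps the detector blind to narrow biphasic stimulation
pulses while remaining sensitive to flux-lock step jumps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft, signal as sps

from .simulate import Recording

__all__ = [
    "SpectrumSet",
    "SegmentMask",
    "reject_bad_segments",
    "welch_asd",
    "median_spectrum",
]

_CHUNK_SAMPLES = 2.5e7  # per-chunk budget for channel blocks


@dataclass
class SpectrumSet:
    """Per-channel one-sided amplitude spectral densities."""

    freqs: np.ndarray  # (n_freqs,) Hz, step = 1 / segment_length
    asd: np.ndarray  # (n_channels, n_freqs), sensor units / sqrt(Hz)
    segment_length: float  # s
    n_segments_used: np.ndarray  # (n_channels,)
    channels: tuple  # ChannelInfo per row (or descriptive tuple)

    def __post_init__(self) -> None:
        if self.asd.shape != (len(self.channels), len(self.freqs)):
            raise ValueError("asd shape does not match channels x freqs")
        if len(self.freqs) > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    @property
    def df(self) -> float:
        return 1.0 / self.segment_length

    def channel_names(self) -> list[str]:
        return [getattr(ch, "name", str(ch)) for ch in self.channels]

    def band(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of frequency bins within [lo, hi]."""
        return (self.freqs >= lo) & (self.freqs <= hi)


@dataclass
class SegmentMask:
    """Keep/reject decision per channel and non-overlapping segment."""

    keep: np.ndarray  # (n_channels, n_segments) bool
    reason: np.ndarray  # (n_channels, n_segments) '<U4': '', 'flat', 'jump'
    segment_samples: int
    fs: float

    @property
    def n_segments(self) -> int:
        return self.keep.shape[1]

    def rejected_fraction(self, channel: int | None = None) -> float:
        keep = self.keep if channel is None else self.keep[channel]
        return float(1.0 - np.mean(keep))


def _flat_run_mask(x: np.ndarray, flat_len: int) -> np.ndarray:
    """Sample positions inside runs of >= flat_len identical values."""
    same = np.concatenate(([False], x[1:] == x[:-1]))
    # vectorized run length ending at each index: reset where not-same
    idx = np.flatnonzero(~same)
    counter = np.arange(len(x), dtype=np.int32)
    run = counter - np.repeat(counter[idx], np.diff(np.append(idx, len(x))))
    hits = run >= flat_len - 1
    out = hits.copy()
    # extend hit back over the whole run
    ends = np.flatnonzero(hits)
    for e in ends:
        out[e - flat_len + 1:e + 1] = True
    return out


def reject_bad_segments(rec: Recording, flat_len: int = 10,
                        jump_k: float = 20.0,
                        segment_length: float = 3.0) -> SegmentMask:
    """Flag segments containing flat stretches or step discontinuities.

    Parameters
    ----------
    rec
        Input recording.
    flat_len
        Minimum number of consecutive identical samples to call a
        segment flat (must be >= 2).
    jump_k
        Threshold multiplier on the robust scale (scaled MAD) of the
        channel's short-window-median first differences.
    segment_length
        Non-overlapping segmentation length in seconds, matching the
        Welch trial length.
    """
    if flat_len < 2:
        raise ValueError("flat_len must be >= 2")
    if rec.n_samples == 0:
        raise ValueError("recording is empty")
    seg = int(round(segment_length * rec.fs))
    n_seg = rec.n_samples // seg
    if n_seg < 1:
        raise ValueError("recording shorter than one segment")
    keep = np.ones((rec.n_channels, n_seg), dtype=bool)
    reason = np.full((rec.n_channels, n_seg), "", dtype="<U4")

    # jump detection runs on a 20 Hz low-passed, ~100 Hz-decimated copy:
    # step discontinuities survive the low-pass while stimulation pulses,
    # telemetry tones and their ringing (all >= ~100 Hz) are removed
    f_lp = min(20.0, 0.2 * rec.fs)
    sos = sps.butter(4, f_lp, btype="lowpass", fs=rec.fs, output="sos")
    dec = max(1, int(rec.fs // 100))
    pad = min(int(rec.fs), rec.n_samples - 1)  # warmup by odd reflection
    for c in range(rec.n_channels):
        x = np.asarray(rec.data[c], dtype=np.float64)

        flat_hits = _flat_run_mask(x, flat_len)
        if flat_hits.any():
            segs = np.unique(np.flatnonzero(flat_hits) // seg)
            segs = segs[segs < n_seg]
            keep[c, segs] = False
            reason[c, segs] = "flat"

        xe = np.concatenate([x[pad:0:-1], x]) if pad else x
        y = sps.sosfilt(sos, xe)[pad:]
        d = np.diff(y[::dec])
        if len(d) < 4:
            continue
        mad = np.median(np.abs(d - np.median(d))) * 1.4826
        scale = max(mad, 1e-12 * max(np.std(x), 1.0))
        bad = np.flatnonzero(np.abs(d) > jump_k * scale)
        if len(bad):
            samples = (bad + 1) * dec
            segs = np.unique(samples // seg)
            segs = segs[segs < n_seg]
            new = keep[c, segs]  # flats take precedence in 'reason'
            keep[c, segs] = False
            reason[c, segs[new]] = "jump"
    return SegmentMask(keep=keep, reason=reason, segment_samples=seg, fs=rec.fs)


def welch_asd(rec: Recording, segment_length: float = 3.0,
              mask: SegmentMask | None = None,
              window: str = "hann", overlap: float = 0.5) -> SpectrumSet:
    """Welch amplitude spectral density, optionally excluding bad segments.

    A 50%-overlapping analysis window is used only when every
    non-overlapping base segment it touches is kept for that channel.
    Channels with no surviving windows get an all-NaN spectrum and a
    logged warning.
    """
    fs = rec.fs
    seg = int(round(segment_length * fs))
    if rec.n_samples < 2 * seg:
        raise ValueError("recording must be at least twice the segment length")
    hop = max(1, int(round(seg * (1.0 - overlap))))
    starts = np.arange(0, rec.n_samples - seg + 1, hop)
    win = np.hanning(seg + 1)[:seg] if window == "hann" else np.ones(seg)
    wnorm = fs * np.sum(win**2)
    freqs = np.fft.rfftfreq(seg, 1.0 / fs)

    # which base segments does each window touch
    if mask is not None:
        base = mask.segment_samples
        first = starts // base
        last = (starts + seg - 1) // base
        n_base = mask.keep.shape[1]

    n_ch = rec.n_channels
    asd = np.full((n_ch, len(freqs)), np.nan)
    used = np.zeros(n_ch, dtype=int)
    chunk = max(1, int(_CHUNK_SAMPLES // (len(starts) * seg)))
    for c0 in range(0, n_ch, chunk):
        c1 = min(n_ch, c0 + chunk)
        arr = np.asarray(rec.data[c0:c1])
        dtype = np.float32 if arr.dtype == np.float32 else np.float64
        segs = np.empty((c1 - c0, len(starts), seg), dtype=dtype)
        for w, s in enumerate(starts):
            segs[:, w, :] = arr[:, s:s + seg]
        segs -= segs.mean(axis=-1, keepdims=True, dtype=np.float64).astype(dtype)
        segs *= win.astype(dtype)
        X = sfft.rfft(segs, axis=-1)
        del segs
        psd_all = (np.abs(X) ** 2).astype(np.float64) * (2.0 / wnorm)
        del X
        psd_all[..., 0] /= 2.0
        if seg % 2 == 0:
            psd_all[..., -1] /= 2.0
        for i, c in enumerate(range(c0, c1)):
            if mask is None:
                sel = np.ones(len(starts), dtype=bool)
            else:
                ch_keep = mask.keep[c]
                sel = np.array([
                    bool(np.all(ch_keep[f:min(l, n_base - 1) + 1]))
                    if f < n_base else False
                    for f, l in zip(first, last)
                ])
            used[c] = int(np.sum(sel))
            if used[c] == 0:
                warnings.warn(
                    f"all segments rejected for channel {c}; spectrum "
                    "marked missing", stacklevel=2,
                )
                continue
            asd[c] = np.sqrt(psd_all[i, sel].mean(axis=0))
    return SpectrumSet(
        freqs=freqs, asd=asd, segment_length=seg / fs,
        n_segments_used=used, channels=tuple(rec.channels),
    )


def median_spectrum(spec: SpectrumSet, channel_selector=None) -> SpectrumSet:
    """Per-frequency median over the selected channels.

    ``channel_selector`` may be None (all channels), an index array /
    boolean mask, or a predicate on the channel metadata.
    """
    if channel_selector is None:
        idx = np.arange(len(spec.channels))
    elif callable(channel_selector):
        idx = np.array([i for i, ch in enumerate(spec.channels)
                        if channel_selector(ch)], dtype=int)
    else:
        idx = np.asarray(channel_selector)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
    if idx.size == 0:
        raise ValueError("empty channel selection")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmedian(spec.asd[idx], axis=0)
    return SpectrumSet(
        freqs=spec.freqs,
        asd=curve[None, :],
        segment_length=spec.segment_length,
        n_segments_used=np.array([int(spec.n_segments_used[idx].max())]),
        channels=("median",),
    )
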