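"""MEG/LFP clock alignment from shared artefact events.

Three alignment routes are provided: stimulation on/off toggling
(envelope edge detection around the stimulation frequency, with a
jump-robust log-|derivative| transform for heavily contaminated
channels), mechanical-tap transients (reusing the same edge detector on
a broadband envelope), and ECG cross-correlation.  Matched event lists
feed a least-squares affine clock map t_lfp = offset + rate * t_meg,
which a band-limited resampler then applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter1d

from .simulate import LfpStream, alias_frequency

__all__ = [
    "ClockMap",
    "EdgeList",
    "jump_robust_transform",
    "detect_stim_edges",
    "fit_clock_map",
    "resample_to_meg_clock",
    "ecg_xcorr_lag",
    "XcorrLag",
]


@dataclass
class ClockMap:
    """Affine map between clocks: t_lfp = offset + rate * t_meg."""

    offset: float
    rate: float
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_events: int = 0

    def __post_init__(self) -> None:
        if abs(self.rate - 1.0) >= 1e-3:
            raise ValueError("clock rate must satisfy |rate - 1| < 1e-3")

    def meg_to_lfp(self, t_meg):
        return self.offset + self.rate * np.asarray(t_meg, float)

    def lfp_to_meg(self, t_lfp):
        return (np.asarray(t_lfp, float) - self.offset) / self.rate

    def to_dict(self) -> dict:
        return {"offset": float(self.offset), "rate": float(self.rate),
                "residuals": [float(r) for r in self.residuals],
                "n_events": int(self.n_events)}

    @classmethod
    def identity(cls) -> "ClockMap":
        return cls(offset=0.0, rate=1.0)


@dataclass
class EdgeList:
    """Detected stimulation on/off (or transient) event times."""

    times: np.ndarray  # s, strictly increasing
    polarity: np.ndarray  # 'on' | 'off'
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.polarity = np.asarray(self.polarity)
        self.confidence = np.asarray(self.confidence, float)
        if len(self.times) > 1:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly increasing")
            flips = self.polarity[1:] != self.polarity[:-1]
            if not np.all(flips):
                raise ValueError("event polarities must alternate")

    def __len__(self) -> int:
        return len(self.times)


def jump_robust_transform(x: np.ndarray) -> np.ndarray:
    """log(|first difference| + eps), eps tied to the robust signal scale.

    Compresses large flux jumps into the same range as ordinary samples
    so that envelope detection still sees the stimulation pattern; the
    scale-linked eps makes the transform unit-invariant up to an
    additive constant.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    d = np.abs(np.diff(x))
    mad = np.median(np.abs(x - np.median(x)))
    scale = 1.4826 * mad if mad > 0 else max(np.std(x), 1.0)
    eps = 1e-12 * max(scale, 1e-300)
    return np.log(d + eps)


def _hysteresis_state(e: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Binary state with hysteresis: on above hi, off below lo."""
    state = np.zeros(len(e), dtype=bool)
    cross_hi = e > hi
    cross_lo = e < lo
    cur = bool(e[0] > (lo + hi) / 2)
    # iterate only over candidate switch points
    switches = np.flatnonzero(cross_hi ^ cross_lo)
    prev = 0
    for i in switches:
        state[prev:i] = cur
        if cross_hi[i]:
            cur = True
        elif cross_lo[i]:
            cur = False
        prev = i
    state[prev:] = cur
    return state


def detect_stim_edges(x: np.ndarray, fs: float, f_stim: float,
                      robust: bool | str = "auto",
                      smooth: float = 0.1,
                      min_state: float = 0.25) -> EdgeList:
    """Detect stimulation on/off edges from the band envelope at f_stim.

    The envelope of a +/-5 Hz band around the (alias-folded)
    stimulation frequency is smoothed over ``smooth`` seconds; edges are
    crossings of the midpoint between the 10th and 90th envelope
    percentiles, with hysteresis and a ``min_state`` debounce.  When the
    envelope dynamic range stays under 6 dB, no toggling is declared and
    an empty list returned.
    """
    x = np.asarray(x, float)
    if robust == "auto":
        d = np.abs(np.diff(x))
        dmad = np.median(d)
        robust = bool(dmad > 0 and d.max() > 2e3 * dmad)
    if robust:
        x = jump_robust_transform(x)
        x = x - np.median(x)

    nyq = fs / 2.0
    f_eff = alias_frequency(f_stim, fs)
    lo = max(0.5, f_eff - 5.0)
    hi = min(0.98 * nyq, f_eff + 5.0)
    if lo >= hi:
        raise ValueError("stimulation band does not fit below Nyquist")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(band))
    env = uniform_filter1d(env, size=max(1, int(round(smooth * fs))))

    # slow decision envelope: a ~1 s median flattens the Rayleigh-like
    # fluctuation of a pure-noise envelope, so only genuine on/off
    # plateaus produce a wide percentile spread
    from scipy.ndimage import median_filter

    step = max(1, int(round(fs / 50.0)))
    env_slow = median_filter(env[::step], size=51, mode="nearest")
    p10, p90 = np.percentile(env_slow, [10, 90])
    if p10 <= 0 or 20 * np.log10(p90 / max(p10, 1e-300)) < 6.0:
        warnings.warn("no toggling detected (envelope dynamic range < 6 dB)",
                      stacklevel=2)
        empty = np.zeros(0)
        return EdgeList(empty, np.zeros(0, dtype="<U3"), empty)

    mid = 0.5 * (p10 + p90)
    span = p90 - p10
    state = _hysteresis_state(env, mid - 0.15 * span, mid + 0.15 * span)

    # debounce: drop states shorter than min_state seconds
    min_len = max(1, int(round(min_state * fs)))
    changes = np.flatnonzero(np.diff(state.astype(np.int8)))
    runs = np.concatenate(([0], changes + 1, [len(state)]))
    for i in range(1, len(runs) - 2):
        if runs[i + 1] - runs[i] < min_len:
            state[runs[i]:runs[i + 1]] = state[runs[i] - 1]
    changes = np.flatnonzero(np.diff(state.astype(np.int8)))

    times, pol, conf = [], [], []
    for i in changes:
        times.append((i + 0.5) / fs)
        pol.append("on" if state[i + 1] else "off")
        lo_i = max(0, i - int(fs))
        hi_i = min(len(env), i + int(fs))
        local = env[lo_i:hi_i]
        conf.append(float((local.max() - local.min()) / max(span, 1e-300)))
    return EdgeList(np.array(times), np.array(pol, dtype="<U3"),
                    np.array(conf))


def fit_clock_map(meg_events: EdgeList, lfp_events: EdgeList) -> ClockMap:
    """Least-squares affine fit pairing events by rank order and polarity."""
    if len(meg_events) != len(lfp_events):
        raise ValueError(
            f"event count mismatch: {len(meg_events)} MEG vs "
            f"{len(lfp_events)} LFP events; unpaired MEG times "
            f"{meg_events.times[len(lfp_events):].tolist()} / LFP times "
            f"{lfp_events.times[len(meg_events):].tolist()}"
        )
    if len(meg_events) < 2:
        raise ValueError("need at least two paired events to fit a clock map")
    if np.any(meg_events.polarity != lfp_events.polarity):
        bad = np.flatnonzero(meg_events.polarity != lfp_events.polarity)
        raise ValueError(f"event polarity mismatch at pair indices {bad.tolist()}")
    t_meg = meg_events.times
    t_lfp = lfp_events.times
    A = np.column_stack([np.ones_like(t_meg), t_meg])
    coef, *_ = np.linalg.lstsq(A, t_lfp, rcond=None)
    offset, rate = float(coef[0]), float(coef[1])
    residuals = t_lfp - (offset + rate * t_meg)
    return ClockMap(offset=offset, rate=rate, residuals=residuals,
                    n_events=len(t_meg))


def resample_to_meg_clock(lfp: LfpStream, cmap: ClockMap,
                          target_fs: float | None = None) -> np.ndarray:
    """Interpolate the LFP onto the MEG time grid defined by ``cmap``.

    Returns an array (channels x samples) sampled at ``target_fs``
    (default: the LFP rate) on MEG time starting at 0.  Raises if the
    map would extrapolate more than 1 s beyond the LFP support.
    """
    if target_fs is None:
        target_fs = lfp.fs
    t_native = lfp.times()
    t_meg_end = cmap.lfp_to_meg(t_native[-1])
    t_meg_start = cmap.lfp_to_meg(0.0)
    if t_meg_start > 1.0 or t_meg_end < -1.0:
        raise ValueError(
            "clock map extrapolates more than 1 s beyond the LFP support"
        )
    n_out = int(np.floor(t_meg_end * target_fs)) + 1
    if n_out < 1:
        raise ValueError("no overlap between MEG grid and LFP support")
    t_grid = np.arange(n_out) / target_fs
    t_lfp_needed = cmap.meg_to_lfp(t_grid)
    t_lfp_needed = np.clip(t_lfp_needed, 0.0, t_native[-1])

    data = np.asarray(lfp.data, float)
    if target_fs < lfp.fs:
        sos = signal.butter(8, 0.45 * target_fs, btype="lowpass",
                            fs=lfp.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    out = np.empty((data.shape[0], n_out))
    for c in range(data.shape[0]):
        out[c] = CubicSpline(t_native, data[c])(t_lfp_needed)
    return out


class XcorrLag(NamedTuple):
    lag: float  # s; shift of `ecg` relative to `lfp`
    confidence: float  # main peak over next-highest side peak


def ecg_xcorr_lag(lfp: np.ndarray, ecg: np.ndarray, fs: float) -> XcorrLag:
    """Lag maximizing the normalized cross-correlation of LFP and ECG.

    Both inputs must share the sampling rate and overlap by at least
    10 s.  Confidence is the ratio of the main correlation peak to the
    highest secondary peak outside a +/-0.25 s guard; below 1.2 a
    low-confidence warning is emitted (the method only works when the
    LFP actually carries cardiac contamination).
    """
    lfp = np.asarray(lfp, float).ravel()
    ecg = np.asarray(ecg, float).ravel()
    if min(len(lfp), len(ecg)) < 10 * fs:
        raise ValueError("need at least 10 s of overlap for ECG alignment")
    a = (lfp - lfp.mean()) / max(lfp.std(), 1e-300)
    b = (ecg - ecg.mean()) / max(ecg.std(), 1e-300)
    corr = signal.correlate(a, b, mode="full", method="fft")
    lags = signal.correlation_lags(len(a), len(b), mode="full")
    # normalize by effective overlap length to avoid edge bias
    overlap = np.minimum(np.minimum(len(a), len(b)),
                         np.minimum(len(a) - lags, len(b) + lags))
    valid = overlap >= int(5 * fs)
    score = np.where(valid, corr / np.maximum(overlap, 1), -np.inf)
    i_best = int(np.argmax(score))
    lag = lags[i_best] / fs
    guard = int(round(0.25 * fs))
    side = score.copy()
    side[max(0, i_best - guard):i_best + guard + 1] = -np.inf
    next_peak = np.max(side[np.isfinite(side)]) if np.any(np.isfinite(side)) else 0.0
    conf = float(score[i_best] / next_peak) if next_peak > 0 else np.inf
    if conf < 1.2:
        warnings.warn("ECG alignment unreliable (confidence < 1.2)",
                      stacklevel=2)
    return XcorrLag(lag=float(lag), confidence=conf)
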