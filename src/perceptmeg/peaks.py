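"""Narrowband peak extraction, comb estimation and condition fingerprints.

Peaks are local maxima of the (median) amplitude spectrum exceeding a
running-median baseline by a prominence threshold in dB — the detector
is therefore equivariant to rescaling the spectrum by any positive
constant.  Comb fundamentals are recovered by a grid search maximizing
the number of explained peaks, with ties broken toward the largest
explaining fundamental.  Intermodulation products of a stimulation
train with the sensor modulation tone are predicted as difference terms
|n*f_stim - m*f_mod| folded into the sampled band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .spectral import SpectrumSet

__all__ = [
    "PeakTable",
    "CombEstimate",
    "Signature",
    "SignatureLibrary",
    "detect_peaks",
    "estimate_comb",
    "predict_intermod",
    "classify_condition",
    "default_signature_library",
    "LINE_FREQS",
]

#: mains frequencies excluded before classification
LINE_FREQS = (50.0, 100.0, 150.0, 60.0, 120.0, 180.0)


@dataclass
class PeakTable:
    """Inventory of detected narrowband peaks."""

    frequency: np.ndarray  # Hz
    prominence_db: np.ndarray  # dB over local running-median baseline
    width: np.ndarray  # Hz at half prominence
    n_channels: np.ndarray  # channels supporting each peak
    df: float  # frequency resolution of the source spectrum

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, float)
        self.prominence_db = np.asarray(self.prominence_db, float)
        self.width = np.asarray(self.width, float)
        self.n_channels = np.asarray(self.n_channels, int)

    def __len__(self) -> int:
        return len(self.frequency)

    def in_band(self, lo: float, hi: float) -> "PeakTable":
        sel = (self.frequency >= lo) & (self.frequency <= hi)
        return PeakTable(self.frequency[sel], self.prominence_db[sel],
                         self.width[sel], self.n_channels[sel], self.df)

    def exclude(self, freqs, tol: float = 1.0) -> "PeakTable":
        """Drop peaks within ``tol`` Hz of any of the given frequencies."""
        if len(self) == 0 or len(tuple(freqs)) == 0:
            return self
        f = np.asarray(tuple(freqs), float)
        dist = np.min(np.abs(self.frequency[:, None] - f[None, :]), axis=1)
        sel = dist > tol
        return PeakTable(self.frequency[sel], self.prominence_db[sel],
                         self.width[sel], self.n_channels[sel], self.df)

    def strongest(self) -> float:
        """Frequency of the most prominent peak."""
        if len(self) == 0:
            raise ValueError("peak table is empty")
        return float(self.frequency[np.argmax(self.prominence_db)])


@dataclass
class CombEstimate:
    fundamental: float
    matched_harmonics: int
    coverage: float  # fraction of peaks explained

    def __post_init__(self) -> None:
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")


def _running_median_baseline(curve: np.ndarray, n_bins: int) -> np.ndarray:
    n_bins = max(3, n_bins | 1)  # odd
    return ndimage.median_filter(curve, size=n_bins, mode="nearest")


def detect_peaks(spec: SpectrumSet, baseline_window: float = 5.0,
                 min_prominence: float = 6.0, f_min: float = 1.0,
                 f_max: float = 250.0, refine: bool = True) -> PeakTable:
    """Extract narrowband peaks from a spectrum.

    A peak is a local maximum exceeding the running-median baseline
    (window ``baseline_window`` Hz) by at least ``min_prominence`` dB.
    If ``spec`` holds several channels their median curve is analysed
    and per-peak channel support is counted against each channel's own
    baseline.  With ``refine`` the reported frequency is sharpened by
    parabolic interpolation of the dB curve around the maximum bin
    (always staying within half a bin of it).
    """
    df = spec.df
    if df > 0.5:
        raise ValueError(
            f"frequency resolution {df:.3g} Hz too coarse for peak "
            "detection; use segments of at least 2 s"
        )
    sel = (spec.freqs >= f_min) & (spec.freqs <= f_max)
    freqs = spec.freqs[sel]
    block = spec.asd[:, sel]
    with np.errstate(invalid="ignore"):
        curve = np.nanmedian(block, axis=0)
    good = np.isfinite(curve) & (curve > 0)
    if not good.all():
        curve = np.where(good, curve, np.nanmin(curve[good]) if good.any() else 1.0)

    n_base = int(round(baseline_window / df))
    baseline = _running_median_baseline(curve, n_base)
    ratio_db = 20.0 * np.log10(np.maximum(curve, 1e-300)
                               / np.maximum(baseline, 1e-300))
    idx, props = sps.find_peaks(ratio_db, height=min_prominence, distance=2)
    if len(idx) == 0:
        z = np.zeros(0)
        return PeakTable(z, z, z, z, df)
    widths = sps.peak_widths(ratio_db, idx, rel_height=0.5)[0] * df

    # per-channel support: channel's own dB ratio at the peak bin
    n_support = np.zeros(len(idx), dtype=int)
    for c in range(block.shape[0]):
        ch = block[c]
        if not np.all(np.isfinite(ch)):
            continue
        ch_base = _running_median_baseline(np.maximum(ch, 1e-300), n_base)
        ch_db = 20.0 * np.log10(np.maximum(ch, 1e-300)
                                / np.maximum(ch_base, 1e-300))
        n_support += (ch_db[idx] >= min_prominence).astype(int)

    f_peak = freqs[idx].astype(float)
    if refine:
        interior = (idx > 0) & (idx < len(ratio_db) - 1)
        ii = idx[interior]
        y0, y1, y2 = ratio_db[ii - 1], ratio_db[ii], ratio_db[ii + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (y0 - y2) / denom, 0.0)
        f_peak[interior] += np.clip(shift, -0.5, 0.5) * df

    return PeakTable(
        frequency=f_peak,
        prominence_db=props["peak_heights"],
        width=widths,
        n_channels=n_support,
        df=df,
    )


def estimate_comb(peaks: PeakTable, f0_range=(1.0, 50.0),
                  tolerance: float = 0.25,
                  step: float | None = None) -> CombEstimate:
    """Grid-search the comb fundamental best explaining the peak table.

    Score of a candidate f0 is the number of peaks lying within
    ``tolerance`` Hz of an integer multiple of f0; ties are broken
    toward the larger fundamental (otherwise near-zero fundamentals
    trivially explain everything).
    """
    if len(peaks) == 0:
        raise ValueError("cannot estimate a comb from an empty peak table")
    lo, hi = f0_range
    if step is None:
        step = min(0.1, tolerance / 2.0)
    cands = np.arange(lo, hi + step / 2, step)
    f = peaks.frequency
    # distance of each peak to the nearest multiple of each candidate
    ratio = f[None, :] / cands[:, None]
    k = np.maximum(1, np.round(ratio))
    dist = np.abs(f[None, :] - k * cands[:, None])
    scores = np.sum(dist <= tolerance, axis=1)
    best_score = scores.max()
    best = cands[scores == best_score][-1]  # tie-break toward larger f0
    return CombEstimate(
        fundamental=float(round(best, 6)),
        matched_harmonics=int(best_score),
        coverage=float(best_score) / len(peaks),
    )


def predict_intermod(f_stim: float, f_mod: float, fs: float,
                     n_max: int = 14, m_max: int = 2,
                     f_ceiling: float = 200.0) -> np.ndarray:
    """Difference intermodulation products |n*f_stim - m*f_mod|.

    Products are folded into (0, fs/2], kept below ``f_ceiling`` and
    deduplicated at 0.1 Hz granularity.  ``m_max = 0`` yields the empty
    set (no mixing without a modulation tone).
    """
    if f_stim <= 0 or f_mod <= 0:
        raise ValueError("frequencies must be positive")
    out = set()
    for n in range(1, n_max + 1):
        for m in range(1, m_max + 1):
            raw = abs(n * f_stim - m * f_mod)
            raw = raw % fs
            if raw > fs / 2:
                raw = fs - raw
            if 0 < raw <= f_ceiling:
                out.add(round(raw, 1))
    return np.array(sorted(out))


@dataclass(frozen=True)
class Signature:
    """Expected peak generator of one artefact source."""

    name: str
    kind: str  # 'tones' | 'comb'
    freqs: tuple[float, ...] = ()  # tones, or comb (f0, fmin, fmax)
    group: str | None = None  # mutually exclusive group label

    def expected(self) -> np.ndarray:
        if self.kind == "tones":
            return np.asarray(self.freqs, float)
        f0, lo, hi = self.freqs
        ks = np.arange(int(np.ceil(lo / f0)), int(np.floor(hi / f0)) + 1)
        return ks * f0

    def explains(self, f: np.ndarray, tol: float) -> np.ndarray:
        """Which of the given frequencies lie on this source's grid."""
        if self.kind == "tones":
            exp = self.expected()
            return np.min(np.abs(f[:, None] - exp[None, :]), axis=1) <= tol
        f0, lo, hi = self.freqs
        k = np.maximum(1, np.round(f / f0))
        on_grid = np.abs(f - k * f0) <= tol
        return on_grid & (f >= lo - tol) & (f <= hi + tol)


@dataclass
class SignatureLibrary:
    signatures: tuple[Signature, ...]
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("signature library is empty")
        seen = {}
        for s in self.signatures:
            key = tuple(np.round(s.expected(), 3))
            if key in seen:
                raise ValueError(
                    f"signatures {seen[key]!r} and {s.name!r} are "
                    "indistinguishable at default tolerances"
                )
            seen[key] = s.name


def default_signature_library(stim_freq: float = 145.0,
                              sidelobe_offsets=(16.0, 11.0)) -> SignatureLibrary:
    below, above = sidelobe_offsets
    return SignatureLibrary(signatures=(
        Signature("sensight_telemetry", "tones", (123.0,), group="telemetry"),
        Signature("legacy_telemetry_open", "comb", (14.3, 14.3, 150.0),
                  group="telemetry"),
        Signature("legacy_streaming", "comb", (14.3 / 3.0, 4.0, 50.0),
                  group="telemetry"),
        Signature("communicator", "comb", (2.0, 4.0, 48.0)),
        Signature("stim_bipolar", "tones", (stim_freq,), group="stim"),
        Signature("stim_monopolar", "tones",
                  (stim_freq, stim_freq - below, stim_freq + above),
                  group="stim"),
    ))


@dataclass
class SourceScore:
    name: str
    match_fraction: float  # expected peaks found
    coverage: float  # observed peaks explained
    active: bool


def classify_condition(peaks: PeakTable, lib: SignatureLibrary,
                       threshold: float = 0.8) -> dict[str, SourceScore]:
    """Score artefact sources against a detected peak table.

    Mains peaks are removed first.  A source is reported active when at
    least ``threshold`` of its expected peaks are found; within a
    mutually exclusive group only the best-explaining source stays
    active (match fraction, then observed-peak coverage, as the key).
    """
    table = peaks.exclude(LINE_FREQS, tol=0.6)
    f = table.frequency
    scores: dict[str, SourceScore] = {}
    for sig in lib.signatures:
        exp = sig.expected()
        if len(f) == 0:
            scores[sig.name] = SourceScore(sig.name, 0.0, 0.0, False)
            continue
        found = np.min(np.abs(exp[:, None] - f[None, :]), axis=1) <= lib.tolerance
        match = float(np.mean(found))
        coverage = float(np.mean(sig.explains(f, lib.tolerance)))
        scores[sig.name] = SourceScore(sig.name, match, coverage,
                                       match >= threshold)
    # resolve exclusive groups
    groups: dict[str, list[SourceScore]] = {}
    for sig in lib.signatures:
        if sig.group:
            groups.setdefault(sig.group, []).append(scores[sig.name])
    for members in groups.values():
        active = [m for m in members if m.active]
        if len(active) > 1:
            best = max(active, key=lambda m: (m.match_fraction, m.coverage))
            for m in active:
                if m is not best:
                    m.active = False
    return scores
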