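"""Synthetic phantom simulator for stimulator/MEG interference studies.

Generates multichannel MEG recordings plus a bipolar LFP stream whose
spectra reproduce, per system profile and operating condition, the
characteristic artefact structure of a sensing-enabled DBS stimulator
inside three MEG systems:

* shaped sensor noise matching per-type empty-room noise-floor curves,
* mains peaks and system-intrinsic narrowband peaks,
* telemetry tones (123 Hz single line, or 14.3 Hz comb for the legacy
  protocol, with a dense ~4.77 Hz comb while streaming),
* a 2 Hz communicator comb between 4 and 48 Hz,
* charge-balanced biphasic stimulation pulse trains projected through a
  current dipole at the lead position (with per-system extras:
  sidelobes and extra tones on CTF, a wide 72.5 Hz subharmonic on a
  subset of planar gradiometers, SQUID step jumps on cryogenic channels
  under monopolar stimulation, and modulation-tone intermodulation on
  OPMs),
* breathing-like implant-movement artefact confined below 20 Hz.

Every stochastic component draws from its own seeded sub-stream, so
toggling one artefact source never changes the realization of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft, signal
from scipy.interpolate import CubicSpline

from .conditions import ConditionSpec, StimSettings
from .profiles import GRAD_PLANAR, SystemProfile

__all__ = [
    "Recording",
    "LfpStream",
    "pulse_train",
    "shaped_noise",
    "apply_opm_nonlinearity",
    "simulate_condition",
    "inject_clock_drift",
    "ecg_template_train",
    "alias_frequency",
]

LFP_FS = 250.0  # Hz; stream rate chosen to clear 2x the 35 Hz analysis band


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Recording:
    """Multichannel time series with per-channel metadata.

    ``data`` is channels x samples in native sensor units (fT, fT/mm or
    uV depending on channel type).  ``truth`` optionally carries the
    simulator's ground-truth block (injected tone frequencies, stim
    on/off intervals, jump times, clock map) for testing.
    """

    data: np.ndarray
    fs: float
    channels: tuple
    t0: float = 0.0
    provenance: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(self.data)
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channels)} channel descriptions"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def channel_types(self) -> np.ndarray:
        return np.array([ch.ctype for ch in self.channels])

    def pick(self, indices) -> "Recording":
        """Sub-recording with the selected channels (data is a view)."""
        indices = np.asarray(indices)
        return Recording(
            data=self.data[indices],
            fs=self.fs,
            channels=tuple(self.channels[i] for i in indices),
            t0=self.t0,
            provenance=self.provenance,
            truth=self.truth,
        )


@dataclass
class LfpStream:
    """Two-channel (left/right hemisphere) LFP stream from the stimulator.

    ``clock`` is the affine map (offset s, rate ratio) placing stream
    samples on the MEG time base: t_lfp = offset + rate * t_meg.
    """

    data: np.ndarray
    fs: float = LFP_FS
    clock: tuple[float, float] = (0.0, 1.0)
    channel_names: tuple[str, str] = ("LFP_L", "LFP_R")
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(self.data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times on the stream's own clock."""
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# seeded sub-streams


def _rng(seed: int, *keys) -> np.random.Generator:
    """Independent generator for one artefact source.

    Keyed by stable string/int hashes so that adding or removing one
    source leaves all other realizations untouched.
    """
    entropy = [int(seed)]
    for k in keys:
        if isinstance(k, str):
            entropy.append(zlib.crc32(k.encode()))
        else:
            entropy.append(int(k))
    return np.random.default_rng(entropy)


# ---------------------------------------------------------------------------
# primitive waveform generators


def pulse_train(stim: StimSettings, fs: float, duration: float) -> np.ndarray:
    """Charge-balanced biphasic rectangular pulse train.

    Each period carries a positive rectangle of ``pulse_width`` seconds
    immediately followed by an equal negative recharge rectangle, so the
    mean over every period is exactly zero and the fundamental sits at
    ``stim.frequency``.

    Raises
    ------
    ValueError
        If the pulse is narrower than one sample at ``fs``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs <= 2 * stim.frequency:
        raise ValueError("fs must exceed twice the stimulation frequency")
    n = int(round(duration * fs))
    if stim.amplitude == 0:
        return np.zeros(n)
    width = int(round(stim.pulse_width * fs))
    if width < 1:
        raise ValueError(
            "pulse width is narrower than one sample at this rate; "
            "raise fs (or synthesize oversampled and decimate)"
        )
    x = np.zeros(n)
    period = fs / stim.frequency  # samples, generally non-integer
    n_pulses = int(np.floor((n - 2 * width) / period)) + 1
    starts = np.round(np.arange(n_pulses) * period).astype(np.intp)
    for s in starts:
        x[s:s + width] += stim.amplitude
        x[s + width:s + 2 * width] -= stim.amplitude
    return x


def _bandlimited_pulse_train(stim: StimSettings, fs: float,
                             n_samples: int) -> np.ndarray:
    """Pulse train at ``fs`` synthesized on an oversampled grid.

    Guarantees at least two samples per pulse on the synthesis grid and
    anti-alias decimates back to ``fs``, so narrow pulses survive rates
    at which they span less than one native sample.
    """
    up = max(1, int(np.ceil(2.0 / (stim.pulse_width * fs))))
    x = pulse_train(stim, fs * up, n_samples * up / fs)
    if up > 1:
        x = signal.resample_poly(x, 1, up)
    return x[:n_samples]


def shaped_noise(spec, fs: float, n_samples: int, seed) -> np.ndarray:
    """Gaussian noise whose one-sided ASD follows a piecewise log-log curve.

    Parameters
    ----------
    spec : sequence of (freq_hz, level)
        Target amplitude spectral density in units/sqrt(Hz); levels must
        be positive.  Interpolated log-log, extended flat outside the
        given range.
    seed : int, Generator, or (n_channels, int/Generator) usage
        Seed or generator; pass a tuple ``(n_channels, seed)`` via
        :func:`_shaped_noise_block` for batched generation.
    """
    return _shaped_noise_block(spec, fs, n_samples, 1, seed)[0]


def _asd_response(spec, freqs: np.ndarray) -> np.ndarray:
    pts = np.asarray(spec, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("spec must be a sequence of (freq, level) pairs")
    if np.any(pts[:, 1] <= 0):
        raise ValueError("noise ASD levels must be positive")
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    f = np.clip(freqs, pts[0, 0], pts[-1, 0])
    return np.exp(np.interp(np.log(f), np.log(pts[:, 0]), np.log(pts[:, 1])))


def _shaped_noise_block(spec, fs: float, n_samples: int, n_channels: int,
                        rng, dtype=np.float64) -> np.ndarray:
    """Batched shaped-noise generation (channels x samples).

    float32 halves memory traffic at full CTF scale; the spectral
    shaping itself is exact in expectation either way.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if n_samples == 0:
        return np.zeros((n_channels, 0), dtype=dtype)
    pts = np.asarray(spec, float)
    if pts.ndim == 2 and np.all(pts[:, 1] > 0) and np.ptp(pts[:, 1]) == 0:
        # flat spec: white noise scaled to the target ASD, no FFT needed
        sigma = pts[0, 1] * np.sqrt(fs / 2.0)
        w = rng.standard_normal((n_channels, n_samples), dtype=dtype)
        w *= np.asarray(sigma, dtype=dtype)
        return w
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    # |H| such that unit-variance white noise acquires the target one-sided ASD
    H = _asd_response(spec, np.maximum(freqs, freqs[1] if len(freqs) > 1 else 1.0))
    H = (H * np.sqrt(fs / 2.0)).astype(dtype)
    w = rng.standard_normal((n_channels, n_samples), dtype=dtype)
    W = sfft.rfft(w, axis=-1)
    del w
    W *= H
    return sfft.irfft(W, n=n_samples, axis=-1).astype(dtype, copy=False)


def apply_opm_nonlinearity(x: np.ndarray, profile: SystemProfile,
                           oversample: int = 2) -> np.ndarray:
    """Second/third-order sensor nonlinearity around the modulation tone.

    The internal modulation tone is added, the polynomial
    ``y = x' + alpha x'^2 + beta x'^3`` applied, and the tone (plus its
    low-order images) notched back out.  The polynomial acts on an
    oversampled representation so that sum-frequency products land at
    their physical (high) frequencies and are removed by the sensor's
    band limit (the anti-alias decimation) instead of folding into the
    analysis band; only the difference products survive, as in the real
    sensor.  With both coefficients zero this is the identity on ``x``.
    """
    alpha, beta = profile.opm_nonlinearity
    if alpha == 0 and beta == 0:
        return np.asarray(x, float).copy()
    f_mod = profile.opm_modulation_freq
    if f_mod is None:
        raise ValueError("profile has no modulation frequency configured")
    x = np.asarray(x, float)
    n = x.shape[-1]
    up = max(1, int(oversample))
    xo = signal.resample_poly(x, up, 1, axis=-1) if up > 1 else x
    t = np.arange(n * up) / (profile.fs * up)
    tone = profile.opm_modulation_amp * np.cos(2 * np.pi * f_mod * t)
    xp = xo + tone
    del xo
    # y = xp + alpha xp^2 + beta xp^3, evaluated in place (Horner form)
    y = xp * beta
    y += alpha
    y *= xp
    y += 1.0
    y *= xp
    del xp
    if up > 1:
        y = signal.resample_poly(y, 1, up, axis=-1)
    y = y[..., :n]
    nyq = profile.fs / 2
    for f in (f_mod, 2 * f_mod, 3 * f_mod):
        if 0 < f < nyq:
            b, a = signal.iirnotch(f, Q=30.0, fs=profile.fs)
            y = signal.filtfilt(b, a, y, axis=-1)
    return y


def _tone_stack(freqs_amps, n: int, fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Sum of cosines with random phases; skips entries above Nyquist."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f, a in freqs_amps:
        if 0 < f < fs / 2 and a != 0:
            out += a * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _channel_gains(n_ch: int, rng: np.random.Generator) -> np.ndarray:
    """Log-uniform per-channel coupling gains with random sign."""
    g = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_ch))
    return g * rng.choice([-1.0, 1.0], size=n_ch)


def _noise_sigma(profile: SystemProfile, ctype: str) -> float:
    """RMS implied by a noise-floor curve (variance = integral of ASD^2)."""
    f = np.linspace(0.1, profile.fs / 2, 4096)
    asd = profile.noise_floor(f, ctype)
    return float(np.sqrt(np.trapezoid(asd**2, f)))


def alias_frequency(f: float, fs: float) -> float:
    """Frequency to which a tone at ``f`` folds when sampled at ``fs``."""
    f = f % fs
    return fs - f if f > fs / 2 else f


# ---------------------------------------------------------------------------
# condition composition


def _stim_dipole_gains(profile: SystemProfile) -> np.ndarray:
    """Per-channel coupling of the stimulation current dipole.

    A tangential dipole at the lead position inside the sensor sphere,
    median-normalized so artefact amplitude parameters stay in native
    sensor-unit terms.
    """
    lead_pos = profile.sphere_center + np.array([0.020, 0.010, 0.040])
    radial = lead_pos - profile.sphere_center
    radial = radial / np.linalg.norm(radial)
    q = np.cross(radial, [0.0, 0.0, 1.0])
    if np.linalg.norm(q) < 1e-6:
        q = np.cross(radial, [0.0, 1.0, 0.0])
    q = q / np.linalg.norm(q)
    from .forward import _channel_response  # local import to avoid cycle

    g = _channel_response(
        lead_pos, q, profile.channels, profile.sphere_center,
        axial_baseline=profile.gradiometer_baseline or 0.05,
        planar_baseline=profile.gradiometer_baseline or 0.0168,
    )
    # normalize per channel type so each type's reference amplitude applies
    out = np.zeros_like(g)
    ctypes = profile.channel_types()
    for ct in np.unique(ctypes):
        idx = ctypes == ct
        med = np.median(np.abs(g[idx]))
        out[idx] = np.clip(g[idx] / med, -5.0, 5.0) if med > 0 else 1.0
    return out


def _movement_gains(profile: SystemProfile) -> np.ndarray:
    """Distance-falloff gains for the implant located well below the array."""
    ipg = profile.sphere_center + np.array([0.0, 0.0, -0.33])
    d = np.array([np.linalg.norm(ch.position - ipg) for ch in profile.channels])
    g = (np.median(d) / d) ** 3
    return g


def _schedule_mask(schedule, n: int, fs: float) -> np.ndarray:
    if schedule is None:
        return np.ones(n)
    mask = np.zeros(n)
    for start, stop in schedule:
        i0 = max(0, int(round(start * fs)))
        i1 = min(n, int(round(stop * fs)))
        mask[i0:i1] = 1.0
    return mask


def ecg_template_train(beat_times, fs: float, duration: float,
                       amplitude: float = 1.0) -> np.ndarray:
    """Synthetic PQRST-like waveform with beats at the given times."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    # (delay s, width s, relative amplitude) of P, Q, R, S, T deflections
    waves = [(-0.17, 0.025, 0.12), (-0.03, 0.010, -0.15), (0.0, 0.012, 1.0),
             (0.03, 0.010, -0.25), (0.20, 0.060, 0.30)]
    for tb in beat_times:
        for d, w, a in waves:
            x += a * np.exp(-0.5 * ((t - tb - d) / w) ** 2)
    return amplitude * x


def _make_lfp(profile: SystemProfile, cond: ConditionSpec, duration: float,
              seed: int, coherent_osc: np.ndarray | None) -> LfpStream:
    n = int(round(duration * LFP_FS))
    rng = _rng(seed, "lfp")
    data = _shaped_noise_block(
        [(0.5, 20.0), (5.0, 5.0), (125.0, 2.0)], LFP_FS, n, 2, rng
    )
    truth: dict = {"clock": (0.0, 1.0)}
    t = np.arange(n) / LFP_FS

    if cond.stim_active or cond.stim_schedule is not None:
        f_alias = alias_frequency(cond.stim.frequency, LFP_FS)
        env = _schedule_mask(cond.stim_schedule, n, LFP_FS)
        art = 100.0 * np.cos(2 * np.pi * f_alias * t + rng.uniform(0, 2 * np.pi))
        data += env * art
        truth["stim"] = {
            "frequency": cond.stim.frequency,
            "alias_frequency": f_alias,
            "schedule": cond.stim_schedule,
        }

    if cond.lfp_ecg:
        hr = 1.1  # beats/s
        n_beats = int(duration * hr) + 1
        jitter = rng.normal(0.0, 0.03, size=n_beats)
        beats = np.arange(n_beats) / hr + jitter
        beats = beats[(beats > 0.3) & (beats < duration - 0.3)]
        data += ecg_template_train(beats, LFP_FS, duration, amplitude=15.0)
        truth["ecg_beat_times"] = beats

    if cond.lfp_coherent_source is not None and coherent_osc is not None:
        f0, level = cond.lfp_coherent_source
        # shared + independent narrowband parts in the ratio giving MSC = level
        ind = _narrowband_osc(f0, LFP_FS, n, _rng(seed, "lfp_indep"))
        osc = np.sqrt(level) * coherent_osc + np.sqrt(1 - level) * ind
        data[1] += 8.0 * osc  # right-hemisphere channel carries the coupling
        truth["coherent_source"] = {"freq": f0, "msc": level}

    return LfpStream(data=data, fs=LFP_FS, clock=(0.0, 1.0), truth=truth)


def _narrowband_osc(f0: float, fs: float, n: int,
                    rng: np.random.Generator, bw: float = 2.0) -> np.ndarray:
    """Unit-variance narrowband Gaussian oscillation centred at f0."""
    x = rng.standard_normal(n)
    lo = max(0.1, f0 - bw / 2)
    hi = min(fs / 2 * 0.95, f0 + bw / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / np.std(y)


def _gather_sources(profile: SystemProfile, cond: ConditionSpec,
                    duration: float, seed: int, n: int):
    """Build (waveform, per-channel gains, tone frequencies by type) triples."""
    fs = profile.fs
    n_ch = profile.n_channels
    ctypes = profile.channel_types()
    ref = profile.artefact_ref
    sources = []  # (wave, gains)
    tones_by_type: dict[str, set] = {ct: set() for ct in np.unique(ctypes)}

    def type_amp(rel: float) -> np.ndarray:
        """Per-channel amplitude scale: rel x that type's reference level."""
        return np.array([rel * ref[ct] for ct in ctypes])

    def add_tones(key: str, freqs_rel, gains=None, only_types=None):
        rng = _rng(seed, key)
        freqs_added = [(f, rel) for f, rel in freqs_rel if 0 < f < fs / 2]
        if not freqs_added:
            return
        full = _tone_stack(freqs_added, n, fs, rng)
        g = _channel_gains(n_ch, rng) if gains is None else gains
        scale = type_amp(1.0)
        if only_types is not None:
            sel = np.isin(ctypes, list(only_types))
            scale = np.where(sel, scale, 0.0)
        sources.append((full, g * scale))
        for ct in np.unique(ctypes):
            if only_types is not None and ct not in only_types:
                continue
            tones_by_type[ct].update(f for f, _ in freqs_added)

    # --- system-intrinsic and mains peaks (always on)
    rng_line = _rng(seed, "line")
    for ct in np.unique(ctypes):
        peaks = profile.intrinsic_peaks.get(ct, [])
        if not peaks:
            continue
        wave = _tone_stack(peaks, n, fs, rng_line)
        g = np.abs(_channel_gains(n_ch, rng_line))
        gains = np.where(ctypes == ct, g, 0.0)
        sources.append((wave, gains))
        tones_by_type[ct].update(f for f, _ in peaks if 0 < f < fs / 2)

    if not cond.ipg_present:
        return sources, tones_by_type

    # --- telemetry
    if cond.telemetry == "open_sensight":
        tel = [(cond.telemetry_freq * k, 1.0 if k == 1 else 0.3)
               for k in range(1, 6)]
        add_tones("telemetry", tel)
    elif cond.telemetry == "open_legacy":
        if cond.streaming and cond.legacy_streaming_dense_comb:
            f0 = cond.legacy_comb_fundamental / 3.0  # ~4.77 Hz dense comb
            comb = [(f0 * k, 0.5 / k) for k in range(1, int(150.0 / f0) + 1)]
        else:
            f0 = cond.legacy_comb_fundamental
            comb = [(f0 * k, 0.5) for k in range(1, int(150.0 / f0) + 1)]
        add_tones("legacy_comb", comb)

    # --- communicator comb
    if cond.communicator_near:
        f0, lo, hi = cond.communicator_comb
        comb = [(f0 * k, 0.3) for k in range(int(np.ceil(lo / f0)),
                                             int(np.floor(hi / f0)) + 1)]
        add_tones("comm_comb", comb)

    # --- quiescent-mode extra on planar gradiometers (18 Hz)
    if (profile.name == "megin" and cond.ipg_present
            and not cond.stim_active and cond.telemetry == "closed"
            and not cond.communicator_near):
        add_tones("quiescent18", [(18.0, 0.2)], only_types=(GRAD_PLANAR,))

    # --- per-condition extra tones (observed on the CTF system)
    if cond.extra_tones and profile.name == "ctf":
        add_tones("extra", list(cond.extra_tones))

    return sources, tones_by_type


def simulate_condition(profile: SystemProfile, cond: ConditionSpec,
                       duration: float, seed: int
                       ) -> tuple[Recording, LfpStream]:
    """Simulate one operating condition on one MEG system.

    Returns the MEG :class:`Recording` (float32, channels x samples) and
    the accompanying :class:`LfpStream` on an identity clock.  Spectral
    targets assume ``duration >= 30`` s; 120 s is recommended.
    """
    cond.validate_for(profile)
    fs = profile.fs
    n = int(round(duration * fs))
    n_ch = profile.n_channels
    ctypes = profile.channel_types()

    sources, tones_by_type = _gather_sources(profile, cond, duration, seed, n)
    truth: dict = {
        "condition": cond.name,
        "profile": profile.name,
        "seed": int(seed),
        "movement": bool(cond.movement),
    }

    # --- stimulation
    stim_on = cond.ipg_present and cond.stim_active
    if stim_on:
        rng_stim = _rng(seed, "stim")
        wave = _bandlimited_pulse_train(cond.stim, fs, n)
        if profile.name == "opm" and fs / 2 > 2300.0:
            # the stimulation field reaching the sensor cell is band-limited;
            # keeps pulse harmonics up to ~n=15, whose modulation-tone
            # difference products reproduce the observed low-frequency lines
            sos = signal.butter(8, 2300.0, btype="lowpass", fs=fs, output="sos")
            wave = signal.sosfiltfilt(sos, wave)
        # measure the fundamental and rescale to the per-type reference level
        t = np.arange(n) / fs
        probe = np.exp(-2j * np.pi * cond.stim.frequency * t)
        fund = 2.0 * abs(wave @ probe) / n
        rel = 10.0 if cond.stim.mode == "monopolar" else 1.0
        wave = wave * (rel / fund)
        env = _schedule_mask(cond.stim_schedule, n, fs)
        if cond.stim.ramping and cond.stim_schedule is not None:
            # ~2 s amplitude ramp after every onset (normally disabled for
            # alignment, where sharp boundaries are wanted)
            t_ax = np.arange(n) / fs
            for start, _stop in cond.stim_schedule:
                seg = (t_ax >= start) & (t_ax < start + 2.0)
                env[seg] *= (t_ax[seg] - start) / 2.0
        gains = _stim_dipole_gains(profile)
        amp = np.array([profile.artefact_ref[ct] for ct in ctypes])
        sources.append((wave * env, gains * amp))
        truth["stim"] = {
            "frequency": cond.stim.frequency,
            "mode": cond.stim.mode,
            "schedule": cond.stim_schedule,
            "gains": gains,
        }
        for ct in np.unique(ctypes):
            tones_by_type[ct].add(cond.stim.frequency)

        # CTF sidelobes around the stimulation frequency (monopolar)
        if profile.name == "ctf" and cond.stim.mode == "monopolar":
            below, above = cond.sidelobe_offsets
            side = [(cond.stim.frequency - below, rel / 10.0),
                    (cond.stim.frequency + above, rel / 10.0)]
            rng_side = _rng(seed, "sidelobes")
            wave_s = _tone_stack(side, n, fs, rng_side) * env
            sources.append((wave_s, gains * amp))
            for ct in np.unique(ctypes):
                tones_by_type[ct].update(
                    f for f, _ in side if 0 < f < fs / 2)
            truth["sidelobes"] = [f for f, _ in side]

        # MEGIN subharmonic on a subset of planar gradiometers (bipolar)
        if profile.name == "megin" and cond.stim.mode == "bipolar":
            rng_sub = _rng(seed, "subharmonic")
            grads = np.flatnonzero(ctypes == GRAD_PLANAR)
            n_aff = max(1, int(round(cond.subharmonic_fraction * len(grads))))
            affected = np.sort(rng_sub.choice(grads, size=n_aff, replace=False))
            f_sub = cond.stim.frequency / 2.0
            tone = np.cos(2 * np.pi * f_sub * np.arange(n) / fs
                          + rng_sub.uniform(0, 2 * np.pi))
            # slight AM widens the peak, as seen on the affected subset
            am = 1.0 + 0.25 * _narrowband_osc(0.15, fs, n, rng_sub, bw=0.2)
            g_sub = np.zeros(n_ch)
            g_sub[affected] = profile.artefact_ref[GRAD_PLANAR] * 0.5
            sources.append((tone * am * env, g_sub))
            truth["subharmonic"] = {"freq": f_sub,
                                    "channels": affected.tolist()}
            tones_by_type[GRAD_PLANAR].add(f_sub)

    # --- movement artefact (below 20 Hz, breathing-rate AM)
    if cond.movement:
        rng_mov = _rng(seed, "movement")
        base = rng_mov.standard_normal(n)
        sos = signal.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
        base = signal.sosfilt(sos, base)
        base = base / max(np.std(base), 1e-30)
        am = 0.5 * (1.0 + np.sin(2 * np.pi * 0.25 * np.arange(n) / fs))
        gains = _movement_gains(profile)
        amp = np.array([30.0 * profile.noise_floor(np.array([5.0]), ct)[0]
                        for ct in ctypes])
        sources.append((base * am, gains * amp))

    # --- coherent cortical source feeding the LFP stream
    coherent_osc = None
    if cond.lfp_coherent_source is not None:
        f0, _level = cond.lfp_coherent_source
        rng_coh = _rng(seed, "coherent_source")
        osc_meg = _narrowband_osc(f0, fs, n, rng_coh)
        src_pos = profile.sphere_center + np.array([0.035, 0.020, 0.050])
        radial = src_pos - profile.sphere_center
        radial = radial / np.linalg.norm(radial)
        q = np.cross(radial, [0.0, 0.0, 1.0])
        q = q / np.linalg.norm(q)
        from .forward import _channel_response

        g = _channel_response(
            src_pos, q, profile.channels, profile.sphere_center,
            axial_baseline=profile.gradiometer_baseline or 0.05,
            planar_baseline=profile.gradiometer_baseline or 0.0168,
        )
        g = g / np.median(np.abs(g)[np.abs(g) > 0])
        amp = np.array([20.0 * profile.noise_floor(np.array([f0]), ct)[0]
                        for ct in ctypes])
        sources.append((osc_meg, np.clip(g, -6, 6) * amp))
        # downsample the shared oscillation onto the LFP rate
        n_lfp = int(round(duration * LFP_FS))
        t_lfp = np.arange(n_lfp) / LFP_FS
        cs = CubicSpline(np.arange(n) / fs, osc_meg)
        osc_lfp = cs(np.clip(t_lfp, 0, (n - 1) / fs))
        osc_lfp = osc_lfp / np.std(osc_lfp)
        truth["coherent_source"] = {"position": src_pos.tolist(), "freq": f0}
    else:
        osc_lfp = None

    # --- SQUID jumps on cryogenic channels under monopolar stimulation
    jump_truth: dict[int, list] = {}
    jump_steps: dict[int, tuple] = {}
    if (profile.squid_jump_susceptible and stim_on
            and cond.stim.mode == "monopolar"):
        rng_j = _rng(seed, "jumps")
        for c in range(n_ch):
            k = rng_j.poisson(0.05 * duration)
            if k == 0:
                continue
            times = np.sort(rng_j.uniform(0.5, duration - 0.5, size=k))
            sigma = _noise_sigma(profile, ctypes[c])
            heights = (rng_j.uniform(50, 500, size=k)
                       * rng_j.choice([-1.0, 1.0], size=k) * sigma)
            jump_steps[c] = (np.round(times * fs).astype(np.intp), heights)
            jump_truth[c] = times.tolist()
    if jump_truth:
        truth["jumps"] = jump_truth

    # monopolar stimulation lifts the broadband floor of cryogenic sensors
    monopolar_lift = (profile.squid_jump_susceptible and stim_on
                      and cond.stim.mode == "monopolar")

    # --- assemble channels in chunks (memory-bounded at full scale)
    data = np.empty((n_ch, n), dtype=np.float32)
    noise_rng = _rng(seed, "noise")
    lift_rng = _rng(seed, "monopolar_lift")
    is_opm = profile.name == "opm"
    waves32 = [(wave.astype(np.float32), gains) for wave, gains in sources]
    chunk = max(1, int(5e7 // max(n * (2 if is_opm else 1), 1)))
    for start in range(0, n_ch, chunk):
        stop = min(n_ch, start + chunk)
        block = np.zeros((stop - start, n), dtype=np.float32)
        for ct in np.unique(ctypes[start:stop]):
            rows = np.flatnonzero(ctypes[start:stop] == ct)
            block[rows] = _shaped_noise_block(
                profile.noise_floor_spec[ct], fs, n, len(rows), noise_rng,
                dtype=np.float32,
            )
            if monopolar_lift:
                block[rows] += _shaped_noise_block(
                    [(f, 9.0 * a) for f, a in profile.noise_floor_spec[ct]],
                    fs, n, len(rows), lift_rng, dtype=np.float32,
                )
        for wave, gains in waves32:
            g = gains[start:stop].astype(np.float32)
            nz = np.flatnonzero(g)
            if len(nz):
                block[nz] += g[nz, None] * wave
        if is_opm:
            # nonlinearity needs float64: alpha*x^2 terms lose the small
            # products to float32 rounding at modulation-tone amplitudes
            block = apply_opm_nonlinearity(
                block.astype(np.float64), profile).astype(np.float32)
        for c, (idx, heights) in jump_steps.items():
            if start <= c < stop:
                row = block[c - start]
                for s, h in zip(idx, heights):
                    row[s:] += np.float32(h)
        data[start:stop] = block

    truth["tones_by_type"] = {ct: sorted(v) for ct, v in tones_by_type.items()}

    rec = Recording(
        data=data,
        fs=fs,
        channels=profile.channels,
        provenance={"condition": cond.to_dict(), "profile": profile.name,
                    "seed": int(seed), "duration": duration},
        truth=truth,
    )
    lfp = _make_lfp(profile, cond, duration, seed, osc_lfp)
    lfp.truth["clock"] = (0.0, 1.0)
    return rec, lfp


# ---------------------------------------------------------------------------
# clock drift


def inject_clock_drift(lfp: LfpStream, offset: float, rate: float) -> LfpStream:
    """Resample an LFP stream onto a drifted clock t_lfp = offset + rate * t.

    The returned stream's sample ``i`` holds the signal value at MEG time
    ``(i / fs - offset) / rate``; the true map is recorded in
    ``truth["clock"]``.
    """
    if abs(rate - 1.0) >= 1e-3:
        raise ValueError("clock rate must satisfy |rate - 1| < 1e-3")
    if offset == 0.0 and rate == 1.0:
        truth = dict(lfp.truth)
        truth["clock"] = lfp.clock
        return LfpStream(data=lfp.data.copy(), fs=lfp.fs, clock=lfp.clock,
                         channel_names=lfp.channel_names, truth=truth)
    n = lfp.n_samples
    t_native = np.arange(n) / lfp.fs
    t_meg = (t_native - offset) / rate
    t_meg = np.clip(t_meg, 0.0, (n - 1) / lfp.fs)
    data = np.empty_like(lfp.data, dtype=float)
    for c in range(lfp.data.shape[0]):
        cs = CubicSpline(t_native, lfp.data[c])
        data[c] = cs(t_meg)
    old_off, old_rate = lfp.clock
    clock = (offset + rate * old_off, rate * old_rate)
    truth = dict(lfp.truth)
    truth["clock"] = clock
    return LfpStream(data=data, fs=lfp.fs, clock=clock,
                     channel_names=lfp.channel_names, truth=truth)
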