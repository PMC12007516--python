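"""MEG system profiles: sensor layouts, sampling rates and noise-floor models.

Three system profiles are supported:

``ctf``
    275 axial gradiometers sampled at 19.2 kHz, flat noise floor.
``megin``
    102 sensor triplets (one magnetometer + two orthogonal planar
    gradiometers, 306 channels total) sampled at 5 kHz.  Planar
    gradiometer levels are expressed per millimetre of baseline.
``opm``
    62 channels (31 dual-axis sensors) sampled at 6 kHz, with an internal
    923 Hz modulation tone and a weak even/odd-order nonlinearity that
    produces intermodulation products with strong interferers.

Noise floors are piecewise log-log amplitude-spectral-density curves in
native sensor units per sqrt(Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelInfo",
    "SystemProfile",
    "make_profile",
    "PROFILE_NAMES",
]

PROFILE_NAMES = ("ctf", "megin", "opm")

#: channel type tags
MAG = "mag"
GRAD_AXIAL = "grad_axial"
GRAD_PLANAR = "grad_planar"
LFP = "lfp"


@dataclass(frozen=True)
class ChannelInfo:
    """Static description of a single channel."""

    name: str
    ctype: str  # mag | grad_axial | grad_planar | lfp
    units: str  # fT | fT/mm | uV
    position: np.ndarray  # (3,) m, sensor location
    orientation: np.ndarray  # (3,) unit vector, measurement direction
    tangential: np.ndarray | None = None  # planar-grad difference direction

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "ctype": self.ctype,
            "units": self.units,
            "position": [float(v) for v in self.position],
            "orientation": [float(v) for v in self.orientation],
        }
        if self.tangential is not None:
            d["tangential"] = [float(v) for v in self.tangential]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelInfo":
        tang = d.get("tangential")
        return cls(
            name=d["name"],
            ctype=d["ctype"],
            units=d["units"],
            position=np.asarray(d["position"], float),
            orientation=np.asarray(d["orientation"], float),
            tangential=None if tang is None else np.asarray(tang, float),
        )


@dataclass(frozen=True)
class SystemProfile:
    """Declarative description of an MEG system used by the simulator."""

    name: str
    fs: float
    channels: tuple[ChannelInfo, ...]
    #: ctype -> [(freq_hz, asd_level), ...] piecewise log-log noise floor
    noise_floor_spec: dict
    #: ctype -> [(freq_hz, tone_amplitude), ...] system-intrinsic narrowband peaks
    intrinsic_peaks: dict
    line_freqs: tuple[float, ...]
    #: reference amplitude per ctype for injected artefact tones (sensor units)
    artefact_ref: dict
    opm_modulation_freq: float | None = None
    opm_modulation_amp: float = 0.0
    opm_nonlinearity: tuple[float, float] = (0.0, 0.0)  # (alpha, beta)
    squid_jump_susceptible: bool = False
    gradiometer_baseline: float = 0.0  # m; axial baseline or planar span
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.09

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for ctype, pts in self.noise_floor_spec.items():
            if any(level <= 0 for _, level in pts):
                raise ValueError(f"non-positive noise floor level for {ctype!r}")
        for ch in self.channels:
            if abs(np.linalg.norm(ch.orientation) - 1.0) > 1e-9:
                raise ValueError(f"orientation of {ch.name} is not unit-norm")
        if self.opm_modulation_freq is not None:
            if not 0 < self.opm_modulation_freq < self.fs / 2:
                raise ValueError("opm_modulation_freq must lie below Nyquist")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_types(self) -> np.ndarray:
        return np.array([ch.ctype for ch in self.channels])

    def channels_of_type(self, ctype: str) -> np.ndarray:
        """Indices of channels with the given type tag."""
        return np.flatnonzero(self.channel_types() == ctype)

    def noise_floor(self, freqs: np.ndarray, ctype: str) -> np.ndarray:
        """Evaluate the noise-floor ASD curve at ``freqs`` (log-log interp)."""
        pts = np.asarray(self.noise_floor_spec[ctype], float)
        f = np.maximum(np.asarray(freqs, float), pts[0, 0])
        f = np.minimum(f, pts[-1, 0])
        return np.exp(np.interp(np.log(f), np.log(pts[:, 0]), np.log(pts[:, 1])))


def _cap_points(n: int, radius: float, cap_deg: float = 75.0, z0: float = 0.0):
    """Quasi-uniform points on a spherical cap (Fibonacci lattice).

    Returns positions (n, 3) and outward radial unit vectors (n, 3) on a
    sphere of ``radius`` centred at (0, 0, z0), covering polar angles up
    to ``cap_deg`` from the +z axis.
    """
    i = np.arange(n) + 0.5
    cos_max = np.cos(np.deg2rad(cap_deg))
    z = 1.0 - (1.0 - cos_max) * i / n  # cos(theta) from 1 down to cos_max
    phi = np.pi * (1.0 + 5.0**0.5) * i
    sin_t = np.sqrt(1.0 - z**2)
    normals = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), z], axis=1)
    pos = radius * normals
    pos[:, 2] += z0
    return pos, normals


def _tangent_basis(normal: np.ndarray):
    """Two orthonormal tangent vectors for a unit normal."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def _ctf_profile() -> SystemProfile:
    n = 275
    pos, normals = _cap_points(n, radius=0.12)
    channels = tuple(
        ChannelInfo(
            name=f"CTF{i + 1:03d}",
            ctype=GRAD_AXIAL,
            units="fT",
            position=pos[i],
            orientation=normals[i],
        )
        for i in range(n)
    )
    return SystemProfile(
        name="ctf",
        fs=19200.0,
        channels=channels,
        # flat floor, safely under the 5 fT/sqrt(Hz) empty-room ceiling
        noise_floor_spec={GRAD_AXIAL: [(0.1, 3.5), (9600.0, 3.5)]},
        intrinsic_peaks={
            GRAD_AXIAL: [(50.0, 60.0), (60.0, 40.0), (120.0, 30.0),
                         (150.0, 40.0), (180.0, 30.0)],
        },
        line_freqs=(50.0, 60.0),
        artefact_ref={GRAD_AXIAL: 350.0},
        squid_jump_susceptible=True,
        gradiometer_baseline=0.05,
    )


def _megin_profile() -> SystemProfile:
    n_sites = 102
    pos, normals = _cap_points(n_sites, radius=0.12)
    channels: list[ChannelInfo] = []
    for i in range(n_sites):
        t1, t2 = _tangent_basis(normals[i])
        channels.append(
            ChannelInfo(
                name=f"MAG{i + 1:03d}",
                ctype=MAG,
                units="fT",
                position=pos[i],
                orientation=normals[i],
            )
        )
        for tag, tang in (("A", t1), ("B", t2)):
            channels.append(
                ChannelInfo(
                    name=f"GRD{i + 1:03d}{tag}",
                    ctype=GRAD_PLANAR,
                    units="fT/mm",
                    position=pos[i],
                    orientation=normals[i],
                    tangential=tang,
                )
            )
    return SystemProfile(
        name="megin",
        fs=5000.0,
        channels=tuple(channels),
        noise_floor_spec={
            # gradiometers: elevated under 20 Hz, flat 0.4 fT/(mm sqrt(Hz)) above
            GRAD_PLANAR: [(0.3, 8.0), (3.0, 1.5), (20.0, 0.4), (2500.0, 0.4)],
            # magnetometers: ~100 under 50 Hz falling below 10 over 100 Hz
            MAG: [(0.3, 900.0), (5.0, 90.0), (20.0, 65.0), (50.0, 15.0),
                  (100.0, 7.0), (2500.0, 7.0)],
        },
        intrinsic_peaks={
            GRAD_PLANAR: [(50.0, 8.0), (100.0, 4.0), (150.0, 5.0)],
            MAG: [(50.0, 800.0), (100.0, 300.0), (150.0, 400.0)],
        },
        line_freqs=(50.0,),
        artefact_ref={GRAD_PLANAR: 40.0, MAG: 2000.0},
        squid_jump_susceptible=True,
        gradiometer_baseline=0.0168,
    )


def _opm_profile() -> SystemProfile:
    n_sensors = 31
    pos, normals = _cap_points(n_sensors, radius=0.10)
    channels: list[ChannelInfo] = []
    for i in range(n_sensors):
        t1, _ = _tangent_basis(normals[i])
        channels.append(
            ChannelInfo(
                name=f"OPM{i + 1:02d}R",
                ctype=MAG,
                units="fT",
                position=pos[i],
                orientation=normals[i],
            )
        )
        channels.append(
            ChannelInfo(
                name=f"OPM{i + 1:02d}T",
                ctype=MAG,
                units="fT",
                position=pos[i],
                orientation=t1,
            )
        )
    return SystemProfile(
        name="opm",
        fs=6000.0,
        channels=tuple(channels),
        # 540 fT/sqrt(Hz) around 10 Hz, under 30 above 30 Hz
        noise_floor_spec={
            MAG: [(0.3, 3000.0), (10.0, 540.0), (20.0, 100.0), (30.0, 25.0),
                  (45.0, 20.0), (3000.0, 20.0)],
        },
        intrinsic_peaks={
            MAG: [(26.0, 300.0), (50.0, 600.0), (100.0, 200.0), (120.0, 150.0),
                  (150.0, 300.0), (155.0, 150.0), (160.0, 150.0),
                  (173.0, 150.0), (180.0, 150.0)],
        },
        line_freqs=(50.0,),
        artefact_ref={MAG: 2000.0},
        opm_modulation_freq=923.0,
        opm_modulation_amp=1.0e5,
        opm_nonlinearity=(1.0e-9, 5.0e-12),
        squid_jump_susceptible=False,
    )


_BUILDERS = {"ctf": _ctf_profile, "megin": _megin_profile, "opm": _opm_profile}


def make_profile(name: str) -> SystemProfile:
    """Build a fully populated :class:`SystemProfile` by name.

    Parameters
    ----------
    name
        One of ``"ctf"``, ``"megin"``, ``"opm"``.

    Raises
    ------
    ValueError
        If ``name`` is not a known profile.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown system profile {name!r}; valid options: "
            + ", ".join(sorted(_BUILDERS))
        ) from None
    return builder()
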