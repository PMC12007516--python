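"""Operating-condition descriptions driving the phantom simulator.

A :class:`ConditionSpec` combines the stimulator telemetry mode, the
stimulation settings, implant movement and communicator proximity into a
single declarative object.  A registry of named conditions mirrors the
operating modes of the stimulator (quiescent, streaming in either
telemetry protocol, bipolar/monopolar stimulation, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "StimSettings",
    "ConditionSpec",
    "named_condition",
    "CONDITION_NAMES",
]

TELEMETRY_MODES = ("closed", "open_sensight", "open_legacy")
STIM_MODES = ("off", "bipolar", "monopolar")


@dataclass(frozen=True)
class StimSettings:
    """Stimulation parameters of the implanted pulse generator."""

    amplitude: float = 0.0  # mA
    pulse_width: float = 60e-6  # s
    frequency: float = 145.0  # Hz
    mode: str = "off"
    ramping: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("stimulation amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("stimulation frequency must be > 0")
        if self.mode not in STIM_MODES:
            raise ValueError(f"stim mode must be one of {STIM_MODES}")
        # biphasic pulse pair must fit within one period (duty cycle < 1)
        if 2 * self.pulse_width * self.frequency >= 1.0:
            raise ValueError("pulse width times frequency implies duty cycle >= 1")


def default_stim(mode: str = "bipolar") -> StimSettings:
    """Worst-case-typical stimulation settings: 5 mA, 60 us, 145 Hz."""
    return StimSettings(amplitude=5.0, pulse_width=60e-6, frequency=145.0, mode=mode)


@dataclass(frozen=True)
class ConditionSpec:
    """One operating condition of the stimulator inside the MEG."""

    name: str = "custom"
    telemetry: str = "closed"
    streaming: bool = False
    stim: StimSettings = field(default_factory=StimSettings)
    movement: bool = False
    communicator_near: bool = False
    ipg_present: bool = True

    # telemetry / communicator artefact structure
    telemetry_freq: float = 123.0
    legacy_comb_fundamental: float = 14.3
    legacy_streaming_dense_comb: bool = False
    communicator_comb: tuple[float, float, float] = (2.0, 4.0, 48.0)  # f0, lo, hi

    # per-system extras
    sidelobe_offsets: tuple[float, float] = (16.0, 11.0)  # Hz below / above f_stim
    subharmonic_fraction: float = 0.15  # megin bipolar: fraction of planar grads
    extra_tones: tuple[tuple[float, float], ...] = ()  # (freq, rel level)

    # stimulation on/off schedule, seconds; None means "on throughout"
    stim_schedule: tuple[tuple[float, float], ...] | None = None

    # LFP stream content
    lfp_ecg: bool = False
    lfp_coherent_source: tuple[float, float] | None = None  # (freq Hz, msc level)

    def __post_init__(self) -> None:
        if self.telemetry not in TELEMETRY_MODES:
            raise ValueError(f"telemetry must be one of {TELEMETRY_MODES}")
        if self.streaming and self.telemetry == "closed":
            raise ValueError("streaming requires an open telemetry session")
        if self.lfp_coherent_source is not None:
            level = self.lfp_coherent_source[1]
            if not 0.0 <= level <= 1.0:
                raise ValueError("coherence level must lie in [0, 1]")
        if not 0.0 <= self.subharmonic_fraction <= 1.0:
            raise ValueError("subharmonic_fraction must lie in [0, 1]")

    @property
    def stim_active(self) -> bool:
        return self.stim.mode != "off" and self.stim.amplitude > 0

    def validate_for(self, profile) -> None:
        """Check all deterministic artefact frequencies against Nyquist."""
        nyq = profile.fs / 2
        freqs = [self.telemetry_freq, self.legacy_comb_fundamental,
                 self.communicator_comb[0], self.stim.frequency]
        freqs += [f for f, _ in self.extra_tones]
        bad = [f for f in freqs if f >= nyq]
        if bad:
            raise ValueError(
                f"artefact frequencies {bad} exceed Nyquist ({nyq} Hz) "
                f"of profile {profile.name!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        d = dict(d)
        stim = d.pop("stim", None)
        if isinstance(stim, dict):
            stim = StimSettings(**stim)
        elif stim is None:
            stim = StimSettings()
        for key in ("communicator_comb", "sidelobe_offsets"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("extra_tones"):
            d["extra_tones"] = tuple(tuple(t) for t in d["extra_tones"])
        if d.get("stim_schedule"):
            d["stim_schedule"] = tuple(tuple(t) for t in d["stim_schedule"])
        if d.get("lfp_coherent_source"):
            d["lfp_coherent_source"] = tuple(d["lfp_coherent_source"])
        return cls(stim=stim, **d)


def _registry() -> dict:
    conds = {
        "empty_room": ConditionSpec(name="empty_room", ipg_present=False),
        "quiescent": ConditionSpec(name="quiescent"),
        "movement": ConditionSpec(name="movement", movement=True),
        "communicator_near": ConditionSpec(
            name="communicator_near", communicator_near=True
        ),
        "sensight_streaming": ConditionSpec(
            name="sensight_streaming", telemetry="open_sensight", streaming=True
        ),
        "sensight_open": ConditionSpec(
            name="sensight_open", telemetry="open_sensight", streaming=False
        ),
        "legacy_streaming": ConditionSpec(
            name="legacy_streaming",
            telemetry="open_legacy",
            streaming=True,
            legacy_streaming_dense_comb=True,
        ),
        "legacy_open": ConditionSpec(
            name="legacy_open", telemetry="open_legacy", streaming=False
        ),
        "bipolar_stim": ConditionSpec(
            name="bipolar_stim",
            stim=default_stim("bipolar"),
            # extra tones observed with bipolar stimulation on the CTF system
            extra_tones=((32.6, 0.3), (65.0, 0.3), (80.0, 0.3), (112.0, 0.3),
                         (177.0, 0.3)),
        ),
        "monopolar_stim": ConditionSpec(
            name="monopolar_stim", stim=default_stim("monopolar")
        ),
        "brainsense_zero": ConditionSpec(
            name="brainsense_zero",
            telemetry="open_sensight",
            streaming=True,
            stim=StimSettings(amplitude=0.0, mode="monopolar"),
            extra_tones=((52.0, 0.2),),
        ),
        "brainsense_stim": ConditionSpec(
            name="brainsense_stim",
            telemetry="open_sensight",
            streaming=True,
            stim=default_stim("monopolar"),
        ),
    }
    return conds


_CONDITIONS = _registry()
CONDITION_NAMES = tuple(sorted(_CONDITIONS))


def named_condition(name: str, **overrides) -> ConditionSpec:
    """Look up a named condition, optionally overriding fields.

    >>> named_condition("sensight_streaming").telemetry
    'open_sensight'
    """
    try:
        cond = _CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid names: " + ", ".join(CONDITION_NAMES)
        ) from None
    return replace(cond, **overrides) if overrides else cond
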