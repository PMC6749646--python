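"""Dynamic light/measurement protocols for pulse-amplitude-modulated imaging.

A protocol is an ordered sequence of phases: an initial dark-adaptation
phase followed by actinic light steps.  Saturating pulses probe the PSII
state at scheduled times; the dark-adaptation phase ends with the single
pulse that yields Fo/Fm (and hence Fv/Fm), while lit phases carry a train
of pulses at a fixed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SaturatingPulse",
    "ProtocolPhase",
    "LightProtocol",
    "ProtocolError",
    "build_protocol",
    "preset_protocol",
    "pulse_schedule",
    "ppfd_at",
    "PRESET_NAMES",
]

#: Pulse intensity used throughout, µmol m⁻² s⁻¹ PPFD.
DEFAULT_PULSE_INTENSITY = 5500.0
#: Pulse duration, milliseconds.
DEFAULT_PULSE_DURATION_MS = 800.0
#: Default PPFD ladder for light-response curves, µmol m⁻² s⁻¹.
DEFAULT_LIGHT_CURVE_LADDER = (26.0, 130.0, 260.0, 520.0, 830.0, 1140.0)


class ProtocolError(ValueError):
    """Raised when a protocol specification is invalid."""


@dataclass(frozen=True)
class SaturatingPulse:
    """A single saturating flash closing all PSII centres.

    Attributes
    ----------
    time_s : float
        Seconds from protocol start.
    ppfd : float
        Actinic PPFD in force at the pulse time (µmol m⁻² s⁻¹), *not* the
        flash intensity.
    intensity : float
        Flash intensity, µmol m⁻² s⁻¹ PPFD.
    duration_ms : float
        Flash duration in milliseconds.
    label : str
        Free text; the dark-adapted Fv/Fm pulse is labelled ``"dark"``.
    """

    time_s: float
    ppfd: float = 0.0
    intensity: float = DEFAULT_PULSE_INTENSITY
    duration_ms: float = DEFAULT_PULSE_DURATION_MS
    label: str = ""

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ProtocolError(f"pulse time must be >= 0, got {self.time_s}")
        if self.intensity <= 0:
            raise ProtocolError(f"pulse intensity must be > 0, got {self.intensity}")
        if self.duration_ms <= 0:
            raise ProtocolError(f"pulse duration must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class ProtocolPhase:
    """One contiguous stretch of constant actinic PPFD.

    ``pulse_interval_s == 0`` means a single pulse at the phase end (the
    convention used for the dark-adaptation phase).
    """

    kind: str  # {"dark_adapt", "actinic_step"}
    ppfd: float
    duration_s: float
    pulse_interval_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("dark_adapt", "actinic_step"):
            raise ProtocolError(f"unknown phase kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ProtocolError(f"phase duration must be > 0, got {self.duration_s}")
        if self.ppfd < 0:
            raise ProtocolError(f"phase PPFD must be >= 0, got {self.ppfd}")
        if self.kind == "dark_adapt" and self.ppfd != 0:
            raise ProtocolError("dark_adapt phase must have ppfd == 0")
        if self.pulse_interval_s < 0:
            raise ProtocolError("pulse interval must be >= 0")
        if self.pulse_interval_s > self.duration_s:
            raise ProtocolError(
                f"pulse interval {self.pulse_interval_s} exceeds phase duration "
                f"{self.duration_s}"
            )


@dataclass(frozen=True)
class LightProtocol:
    """A named, validated sequence of phases starting with dark adaptation."""

    name: str
    phases: tuple[ProtocolPhase, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ProtocolError("protocol needs at least one phase")
        if self.phases[0].kind != "dark_adapt":
            raise ProtocolError(
                "first phase must be dark_adapt (dark-adapted Fv/Fm convention)"
            )
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    def phase_starts(self) -> list[float]:
        """Start time of each phase, seconds from protocol start."""
        starts, t = [], 0.0
        for p in self.phases:
            starts.append(t)
            t += p.duration_s
        return starts


def build_protocol(
    phase_specs: Sequence[Mapping[str, object]], name: str = "custom"
) -> LightProtocol:
    """Build a validated protocol from a list of phase descriptors.

    Each descriptor is a mapping with keys ``kind``, ``ppfd``,
    ``duration_s`` and optional ``pulse_interval_s``/``label`` (the dialect
    used by YAML/JSON protocol files).
    """
    if not phase_specs:
        raise ProtocolError("protocol needs at least one phase")
    phases = []
    for i, spec in enumerate(phase_specs):
        try:
            phases.append(
                ProtocolPhase(
                    kind=str(spec["kind"]),
                    ppfd=float(spec.get("ppfd", 0.0)),  # type: ignore[arg-type]
                    duration_s=float(spec["duration_s"]),  # type: ignore[arg-type]
                    pulse_interval_s=float(spec.get("pulse_interval_s", 0.0)),  # type: ignore[arg-type]
                    label=str(spec.get("label", f"phase{i}")),
                )
            )
        except KeyError as exc:
            raise ProtocolError(f"phase {i} missing required key {exc}") from exc
    return LightProtocol(name=name, phases=tuple(phases))


def _fig5_steps() -> LightProtocol:
    # 1 h dark adaptation, then 500/100/1000 µmol m⁻² s⁻¹ for 15/10/10 min,
    # saturating pulses every 60 s in the lit phases.
    return LightProtocol(
        name="fig5_steps",
        phases=(
            ProtocolPhase("dark_adapt", 0.0, 3600.0, 0.0, "dark"),
            ProtocolPhase("actinic_step", 500.0, 900.0, 60.0, "step1"),
            ProtocolPhase("actinic_step", 100.0, 600.0, 60.0, "step2"),
            ProtocolPhase("actinic_step", 1000.0, 600.0, 60.0, "step3"),
        ),
    )


def _light_curve(
    ladder: Iterable[float] = DEFAULT_LIGHT_CURVE_LADDER,
    pulses_per_step: int = 6,
    pulse_interval_s: float = 60.0,
) -> LightProtocol:
    phases = [ProtocolPhase("dark_adapt", 0.0, 3600.0, 0.0, "dark")]
    for i, ppfd in enumerate(ladder):
        phases.append(
            ProtocolPhase(
                "actinic_step",
                float(ppfd),
                pulses_per_step * pulse_interval_s,
                pulse_interval_s,
                f"step{i + 1}",
            )
        )
    return LightProtocol(name="light_curve", phases=tuple(phases))


_PRESETS = {"fig5_steps": _fig5_steps, "light_curve": _light_curve}
PRESET_NAMES = tuple(_PRESETS)


def preset_protocol(name: str, **kwargs) -> LightProtocol:
    """Return a built-in protocol preset (``fig5_steps`` or ``light_curve``)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ProtocolError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return factory(**kwargs)


def pulse_schedule(protocol: LightProtocol) -> list[SaturatingPulse]:
    """The ordered saturating-pulse train implied by a protocol.

    Dark-adaptation phases contribute a single pulse at the phase end
    (labelled ``"dark"`` for the first phase).  Lit phases place pulses at
    ``t0 + k * interval`` for k = 1, 2, ... up to and including the phase
    end; a zero interval again means one pulse at the phase end.  Each
    pulse records the actinic PPFD in force at its time.
    """
    pulses: list[SaturatingPulse] = []
    t0 = 0.0
    for i, phase in enumerate(protocol.phases):
        t_end = t0 + phase.duration_s
        if phase.kind == "dark_adapt" or phase.pulse_interval_s == 0:
            label = "dark" if i == 0 else (phase.label or f"phase{i}")
            pulses.append(SaturatingPulse(time_s=t_end, ppfd=phase.ppfd, label=label))
        else:
            n = int(round(phase.duration_s / phase.pulse_interval_s))
            # guard against float drift placing a pulse past the phase end
            while n * phase.pulse_interval_s > phase.duration_s + 1e-9:
                n -= 1
            for k in range(1, n + 1):
                pulses.append(
                    SaturatingPulse(
                        time_s=t0 + k * phase.pulse_interval_s,
                        ppfd=phase.ppfd,
                        label=phase.label or f"phase{i}",
                    )
                )
        t0 = t_end
    times = [p.time_s for p in pulses]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ProtocolError("pulse schedule is not strictly increasing")
    return pulses


def ppfd_at(protocol: LightProtocol, time_s: float) -> float:
    """Actinic PPFD at ``time_s``.

    Phase boundaries are half-open ``[start, end)``; the final instant of
    the protocol belongs to the last phase.
    """
    total = protocol.total_duration_s
    if time_s < 0 or time_s > total:
        raise ProtocolError(
            f"time {time_s} s outside protocol duration [0, {total}] s"
        )
    t0 = 0.0
    for phase in protocol.phases:
        t_end = t0 + phase.duration_s
        if time_s < t_end:
            return phase.ppfd
        t0 = t_end
    return protocol.phases[-1].ppfd  # time_s == total
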