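"""Zeitgeber forcing: light-dark cycles and transient pulses.

Light (or a pharmacological cue) acts by multiplying the maximal
transcription rate of a target gene while the cue is on — the rate is the
baseline ``Vmax`` with lights off and ``f * Vmax`` with lights on. A
:class:`ZeitgeberSchedule` combines a periodic light-dark (LD) baseline
acting on one gene (*PER* for light) with any number of transient
:class:`PulseSpec` windows on *PER* or *NR1D*.

Zeitgeber time (ZT) convention: ZT 0 = lights-on; with a 12:12 LD cycle
lights are on for ZT in [0, 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PulseSpec", "ZeitgeberSchedule", "effective_transcription_rate"]

PULSE_TARGETS = ("PER", "NR1D")


@dataclass(frozen=True)
class PulseSpec:
    """A single transient increase in a target gene's maximal transcription.

    ``t_start`` is absolute simulation time in hours (ZT equals simulation
    time modulo the cycle when the schedule starts at lights-on at t = 0);
    use :meth:`at_zt` to place a pulse at a Zeitgeber time on a given day.
    """

    t_start: float
    duration: float = 1.0
    strength: float = 3.0
    gene: str = "PER"

    def __post_init__(self):
        if not np.isfinite(self.t_start):
            raise ValueError("pulse start time must be finite")
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.strength <= 0:
            raise ValueError("pulse strength must be positive")
        if self.gene not in PULSE_TARGETS:
            raise ValueError(
                f"pulse target must be one of {PULSE_TARGETS}, got {self.gene!r}")

    @classmethod
    def at_zt(cls, zt: float, day: int, period: float = 24.0, **kw) -> "PulseSpec":
        """Pulse at Zeitgeber time ``zt`` (may be negative) on cycle ``day``."""
        return cls(t_start=day * period + zt, **kw)

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def active(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class ZeitgeberSchedule:
    """Periodic LD forcing plus transient pulses.

    Parameters
    ----------
    period : float
        Zeitgeber cycle length in hours (24 for a day-night rhythm).
    light_fraction : float
        Fraction of the cycle with lights on (0.5 = 12:12 LD).
    f_light : float
        Baseline multiplier on the LD target's maximal transcription rate
        while lights are on; 1 disables the LD forcing.
    ld_target : str
        Gene driven by the LD baseline (light increases *PER*).
    pulses : list of PulseSpec
    pulse_mode : {'replace', 'multiply'}
        During a pulse window on the LD target while lights are on, the
        pulse factor either replaces the LD baseline factor (default) or
        multiplies it.
    """

    period: float = 24.0
    light_fraction: float = 0.5
    f_light: float = 1.0
    ld_target: str = "PER"
    pulses: list = field(default_factory=list)
    pulse_mode: str = "replace"

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 <= self.light_fraction <= 1.0:
            raise ValueError("light_fraction must be in [0, 1]")
        if self.f_light < 1.0:
            raise ValueError("f_light must be >= 1")
        if self.ld_target not in PULSE_TARGETS:
            raise ValueError(f"ld_target must be one of {PULSE_TARGETS}")
        if self.pulse_mode not in ("replace", "multiply"):
            raise ValueError("pulse_mode must be 'replace' or 'multiply'")
        self.pulses = list(self.pulses)

    # -- queries -------------------------------------------------------------
    def light_on(self, t: float) -> bool:
        """LD light state at absolute time t (lights-on at t = 0)."""
        return (t % self.period) < self.light_fraction * self.period

    def factor(self, t: float, gene: str) -> float:
        """Multiplier on ``gene``'s maximal transcription rate at time t."""
        pulse_f = None
        for p in self.pulses:
            if p.strength == 1.0:
                continue  # strength-1 pulse is a no-op, not an LD override
            if p.gene == gene and p.active(t):
                pulse_f = p.strength if pulse_f is None else max(pulse_f, p.strength)
        ld_f = self.f_light if (gene == self.ld_target and self.f_light != 1.0
                                and self.light_on(t)) else 1.0
        if pulse_f is None:
            return ld_f
        if self.pulse_mode == "multiply":
            return pulse_f * ld_f
        return pulse_f  # replace: pulse overrides the LD baseline

    def is_trivial(self) -> bool:
        """True when the schedule never changes any rate (all factors 1)."""
        return self.f_light == 1.0 and all(p.strength == 1.0 for p in self.pulses)

    def switch_times(self, t0: float, t1: float) -> np.ndarray:
        """All forcing discontinuities in (t0, t1), for piecewise integration."""
        times = []
        if self.f_light != 1.0 and 0.0 < self.light_fraction < 1.0:
            on_len = self.light_fraction * self.period
            k0 = int(np.floor(t0 / self.period)) - 1
            k1 = int(np.ceil(t1 / self.period)) + 1
            for k in range(k0, k1 + 1):
                times.extend((k * self.period, k * self.period + on_len))
        for p in self.pulses:
            if p.strength == 1.0:
                continue  # no-op pulse introduces no discontinuity
            times.extend((p.t_start, p.t_end))
        times = np.array(sorted({float(x) for x in times}))
        return times[(times > t0) & (times < t1)]

    def with_pulse(self, pulse: PulseSpec) -> "ZeitgeberSchedule":
        return ZeitgeberSchedule(period=self.period,
                                 light_fraction=self.light_fraction,
                                 f_light=self.f_light,
                                 ld_target=self.ld_target,
                                 pulses=self.pulses + [pulse],
                                 pulse_mode=self.pulse_mode)


def effective_transcription_rate(base_rate: float,
                                 schedule: "ZeitgeberSchedule | None",
                                 t: float, gene: str) -> float:
    """Light-sensitive maximal transcription rate of ``gene`` at time ``t``.

    Returns ``base_rate`` with the cue off and ``f * base_rate`` with the
    cue on, where ``f`` comes from the schedule's LD baseline and/or an
    active pulse on ``gene``.
    """
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if schedule is None:
        return base_rate
    return base_rate * schedule.factor(t, gene)
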