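"""Deterministic external drives for the thalamocortical model.

Three channels: a sensory drive onto TC, a cortical drive onto PY (both
biased sinusoids, in pps) and a constant reticular drive onto RE.  A
``FrequencySchedule`` steps the frequency of one sinusoidal channel
through an ordered sequence of segments; switching is phase-continuous
(the sine argument accumulates the phase integral of the piecewise
frequency) so the drive itself never jumps.

Drives are *not* clipped at zero: a lumped mean-field input may swing
negative when the amplitude exceeds the bias, mirroring fluctuations
about the mean of the pulse-density input it stands in for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusSpec", "StimulusSet", "FrequencySchedule", "evaluate",
           "evaluate_schedule"]


@dataclass(frozen=True)
class StimulusSpec:
    """Biased sinusoid  phi_b + phi_a sin(2 pi f t)  (all rates in pps, f in Hz)."""

    bias: float = 0.0
    amplitude: float = 0.0
    frequency: float = 0.0

    def __post_init__(self):
        if self.frequency < 0:
            raise ValueError("stimulus frequency must be >= 0")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")


@dataclass(frozen=True)
class FrequencySchedule:
    """Piecewise-constant frequency program for one sinusoidal channel.

    ``segments`` is an ordered list of (start_time s, frequency Hz); the
    first start time must be 0 and start times strictly increase.  Phase
    offsets are accumulated so the drive is continuous at switches.
    """

    segments: tuple[tuple[float, float], ...]
    _phase0: tuple[float, ...] = field(init=False, repr=False, compare=False)

    def __init__(self, segments):
        segs = tuple((float(t0), float(f)) for t0, f in segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first schedule segment must start at t = 0")
        times = [t0 for t0, _ in segs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule start times must be strictly increasing")
        if any(f < 0 for _, f in segs):
            raise ValueError("schedule frequencies must be >= 0")
        object.__setattr__(self, "segments", segs)
        # cumulative phase (cycles) at each segment start
        phase = [0.0]
        for (t0, f), (t1, _) in zip(segs, segs[1:]):
            phase.append(phase[-1] + f * (t1 - t0))
        object.__setattr__(self, "_phase0", tuple(phase))

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(t0 for t0, _ in self.segments[1:])

    def segment_index(self, t: float) -> int:
        if t < 0:
            raise ValueError("schedule evaluated before its first segment")
        idx = 0
        for i, (t0, _) in enumerate(self.segments):
            if t >= t0:
                idx = i
        return idx

    def frequency_at(self, t: float) -> float:
        return self.segments[self.segment_index(t)][1]

    def phase_cycles(self, t: float) -> float:
        """Accumulated phase integral  int_0^t f dt'  in cycles."""
        i = self.segment_index(t)
        t0, f = self.segments[i]
        return self._phase0[i] + f * (t - t0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(start_times, frequencies, phase0_cycles) for compiled evaluation."""
        t0 = np.array([s[0] for s in self.segments])
        f = np.array([s[1] for s in self.segments])
        p0 = np.array(self._phase0)
        return t0, f, p0


def evaluate(spec: StimulusSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Drive value phi_b + phi_a sin(2 pi f t) at time(s) ``t`` (pps)."""
    return spec.bias + spec.amplitude * np.sin(2.0 * np.pi * spec.frequency * t)


def evaluate_schedule(
    sched: FrequencySchedule, base: StimulusSpec, t: float | np.ndarray
) -> float | np.ndarray:
    """Scheduled drive: bias and amplitude from ``base``, frequency from the
    schedule, with phase accumulated continuously across switches."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("schedule evaluated before its first segment")
    phase = np.vectorize(sched.phase_cycles)(t_arr)
    out = base.bias + base.amplitude * np.sin(2.0 * np.pi * phase)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class StimulusSet:
    """The model's three external drives.

    ``sensory`` feeds TC, ``cortical`` feeds PY, ``reticular_bias`` (pps)
    is the constant inhibitory drive onto RE.  At most one sinusoidal
    channel may carry a :class:`FrequencySchedule`.
    """

    sensory: StimulusSpec = StimulusSpec()
    cortical: StimulusSpec = StimulusSpec()
    reticular_bias: float = 0.0
    schedule: FrequencySchedule | None = None
    schedule_channel: str | None = None  # "sensory" | "cortical"

    def __post_init__(self):
        if (self.schedule is None) != (self.schedule_channel is None):
            raise ValueError("schedule and schedule_channel must be set together")
        if self.schedule_channel not in (None, "sensory", "cortical"):
            raise ValueError("schedule_channel must be 'sensory' or 'cortical'")

    def sensory_at(self, t):
        if self.schedule_channel == "sensory":
            return evaluate_schedule(self.schedule, self.sensory, t)
        return evaluate(self.sensory, t)

    def cortical_at(self, t):
        if self.schedule_channel == "cortical":
            return evaluate_schedule(self.schedule, self.cortical, t)
        return evaluate(self.cortical, t)

    @property
    def switch_times(self) -> tuple[float, ...]:
        return self.schedule.switch_times if self.schedule else ()

    def with_frequency(self, channel: str, f: float) -> "StimulusSet":
        """Copy with one channel's frequency replaced (used by scans)."""
        from dataclasses import replace

        if channel == "sensory":
            return replace(self, sensory=replace(self.sensory, frequency=f))
        if channel == "cortical":
            return replace(self, cortical=replace(self.cortical, frequency=f))
        raise ValueError(f"unknown channel {channel!r}")

    def with_bias(self, channel: str, value: float) -> "StimulusSet":
        from dataclasses import replace

        if channel == "sensory":
            return replace(self, sensory=replace(self.sensory, bias=value))
        if channel == "cortical":
            return replace(self, cortical=replace(self.cortical, bias=value))
        if channel == "reticular":
            return replace(self, reticular_bias=value)
        raise ValueError(f"unknown channel {channel!r}")
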