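"""Bifurcation scans, frequency-response sweeps and transition protocols.

A scan steps one parameter (an input bias, a drive frequency, or a
fixture parameter) through an ordered grid, integrating at each value and
extracting post-transient metrics.  With continuation on, each point
starts from the final state of the previous one -- the mechanism that
makes direction matter in bistable regions and lets sweeps trace the
branch structure (jump phenomenon, hysteresis) of a bent resonance
curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .integrate import (
    ContinuationState,
    IntegrationSettings,
    Trajectory,
    continue_from,
    integrate,
)
from .metrics import (
    ExtremaSet,
    InsufficientDataError,
    RegimeLabel,
    RegimeThresholds,
    classify_regime,
    local_extrema,
    max_lyapunov,
    steady_state_amplitude,
    strip_transient,
    stroboscopic_section,
)
from .model import (
    build_system,
    depolarized_state,
    equilibrium_state,
    rebound_kick_state,
    settled_equilibrium,
)
from .params import ModelParameters
from .stimuli import StimulusSet
from .systems import ContinuousSystem

__all__ = [
    "ScanSpec",
    "ScanProblem",
    "ScanRecord",
    "ScanResult",
    "FrequencyResponse",
    "RegimeMap",
    "JumpEvent",
    "run_scan",
    "model_scan_problem",
    "fixture_scan_problem",
    "bias_scan_bidirectional",
    "compose_regime_map",
    "bistability_probe",
    "frequency_bifurcation_scan",
    "sweep_frequency_response",
    "detect_jumps",
    "hysteresis_region",
    "transition_protocol",
]


@dataclass(frozen=True)
class ScanSpec:
    """What to scan and how long to simulate per grid point.

    ``grid`` is executed in the order given (ascending = forward sweep,
    descending = backward).  Per-point duration defaults to
    max(``min_duration``, ``min_periods`` drive periods), with the first
    ``transient_fraction`` discarded before metrics -- regimes near
    bifurcations settle slowly, so the discard is generous.
    """

    parameter: str
    grid: tuple[float, ...]
    continuation: bool = True
    min_duration: float = 30.0
    min_periods: int = 30
    transient_fraction: float = 2.0 / 3.0
    compute_mle: bool = False
    mle_horizon: float = 60.0
    mle_renorm: float = 0.5
    mle_transient: float = 15.0
    mle_d0: float = 1e-6
    seed: int = 0
    first_point_settle: float = 10.0

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ValueError("scan grid is empty")
        diffs = np.diff(self.grid)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("scan grid must be strictly monotone")

    @property
    def direction(self) -> str:
        if len(self.grid) < 2 or self.grid[1] > self.grid[0]:
            return "forward"
        return "backward"


@dataclass
class ScanProblem:
    """Adapter between a scan and a concrete family of systems.

    ``build(v)`` returns the system at parameter value ``v``;
    ``initial_state(v)`` the default initial condition; ``drive_period(v)``
    the forcing period (``None`` for autonomous/constant-input systems).
    """

    build: Callable[[float], ContinuousSystem]
    initial_state: Callable[[float], np.ndarray]
    drive_period: Callable[[float], float | None]
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)


@dataclass
class ScanRecord:
    value: float
    amplitude: float
    extrema: ExtremaSet
    mle: float | None
    label: RegimeLabel
    final: ContinuationState


@dataclass
class ScanResult:
    spec: ScanSpec
    records: list[ScanRecord]
    thresholds: RegimeThresholds

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([r.amplitude for r in self.records])

    @property
    def mles(self) -> np.ndarray:
        return np.array(
            [r.mle if r.mle is not None else np.nan for r in self.records]
        )

    @property
    def labels(self) -> list[RegimeLabel]:
        return [r.label for r in self.records]


@dataclass
class FrequencyResponse:
    """Steady-state amplitude vs drive frequency for one sweep direction."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    direction: str

    def __post_init__(self):
        d = np.diff(self.frequencies)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("frequencies must be strictly monotone")


@dataclass
class RegimeMap:
    """Contiguous intervals of the scanned parameter with a composite
    class: FIXED_POINT_ONLY, BISTABLE or LIMIT_CYCLE_ONLY."""

    intervals: list[tuple[float, float, str]]

    @property
    def classes(self) -> list[str]:
        return [c for _, _, c in self.intervals]


@dataclass(frozen=True)
class JumpEvent:
    frequency: float  # midpoint of the offending grid step
    direction: str  # "up" | "down"
    ratio: float


def _point_metrics(problem, spec, value, traj, thresholds, mle_seed):
    t_cut = traj.t[0] + spec.transient_fraction * (traj.t[-1] - traj.t[0])
    post = strip_transient(traj, t_cut)
    amp = steady_state_amplitude(post)
    extrema = local_extrema(post, thresholds.cluster_tol)
    period = problem.drive_period(value)
    section = None
    if period is not None and post.span >= 3 * period:
        section = stroboscopic_section(post, period)
    mle = None
    if spec.compute_mle:
        mle = max_lyapunov(
            problem.build(value),
            post.final.y,
            horizon=spec.mle_horizon,
            renorm_interval=spec.mle_renorm,
            d0=spec.mle_d0,
            seed=mle_seed,
            transient=spec.mle_transient,
            settings=problem.settings,
        )
    label = classify_regime(extrema, section, mle, thresholds)
    return amp, extrema, mle, label


def run_scan(
    problem: ScanProblem,
    spec: ScanSpec,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> ScanResult:
    """Execute a scan in grid order; with continuation on, each point's
    initial condition is the previous point's final state.  Any point's
    integration failure aborts the scan naming the failing value."""
    records: list[ScanRecord] = []
    carried: ContinuationState | None = None
    for i, v in enumerate(spec.grid):
        system = problem.build(v)
        period = problem.drive_period(v)
        t_sim = spec.min_duration
        if period is not None:
            t_sim = max(t_sim, spec.min_periods * period)
        try:
            if spec.continuation and carried is not None:
                ic: np.ndarray | ContinuationState = carried
            else:
                ic = problem.initial_state(v)
                if spec.continuation and spec.first_point_settle > 0:
                    settle = integrate(
                        system, ic, (0.0, spec.first_point_settle),
                        problem.settings,
                    )
                    ic = continue_from(settle)
            traj = integrate(system, ic, (0.0, t_sim), problem.settings)
        except Exception as err:
            raise RuntimeError(
                f"scan of {spec.parameter!r} failed at value {v!r}: {err}"
            ) from err
        amp, extrema, mle, label = _point_metrics(
            problem, spec, v, traj, thresholds, mle_seed=spec.seed + i
        )
        carried = continue_from(traj)
        records.append(
            ScanRecord(
                value=float(v), amplitude=amp, extrema=extrema,
                mle=mle, label=label, final=carried,
            )
        )
    return ScanResult(spec=spec, records=records, thresholds=thresholds)


# ---------------------------------------------------------------------------
# problem adapters
# ---------------------------------------------------------------------------

_BIAS_CHANNELS = {
    "cortical.bias": "cortical",
    "sensory.bias": "sensory",
    "reticular.bias": "reticular",
}
_FREQ_CHANNELS = {"cortical.frequency": "cortical", "sensory.frequency": "sensory"}


def model_scan_problem(
    params: ModelParameters,
    stimuli: StimulusSet,
    parameter: str,
    settings: IntegrationSettings | None = None,
) -> ScanProblem:
    """Scan adapter for the thalamocortical model.

    ``parameter`` is one of cortical.bias, sensory.bias, reticular.bias,
    cortical.frequency, sensory.frequency.  The default initial state is
    the decoupled leak equilibrium.
    """
    settings = settings or IntegrationSettings(rtol=1e-7, atol=1e-9)

    if parameter in _BIAS_CHANNELS:
        ch = _BIAS_CHANNELS[parameter]

        def build(v):
            return build_system(params, stimuli.with_bias(ch, v))

        def drive_period(v):
            fs = [s.frequency for s in (stimuli.sensory, stimuli.cortical)
                  if s.amplitude > 0 and s.frequency > 0]
            return 1.0 / max(fs) if fs else None

    elif parameter in _FREQ_CHANNELS:
        ch = _FREQ_CHANNELS[parameter]

        def build(v):
            return build_system(params, stimuli.with_frequency(ch, v))

        def drive_period(v):
            return 1.0 / v if v > 0 else None

    else:
        raise ValueError(f"unknown scan parameter {parameter!r}")

    def initial_state(v):
        # quiet-branch start: the solved fixed point of the constant inputs;
        # fall back to the decoupled leak state if no equilibrium exists
        stim = (stimuli.with_bias(ch, v) if parameter in _BIAS_CHANNELS
                else stimuli.with_frequency(ch, v))
        try:
            return settled_equilibrium(params, stim)
        except Exception:
            return equilibrium_state(params)

    return ScanProblem(
        build=build,
        initial_state=initial_state,
        drive_period=drive_period,
        settings=settings,
    )


def fixture_scan_problem(
    fixture,
    settings: IntegrationSettings | None = None,
    ic: np.ndarray | None = None,
) -> ScanProblem:
    """Scan adapter for a forced benchmark fixture whose scanned parameter
    is the drive angular frequency ``omega``."""
    settings = settings or IntegrationSettings(rtol=1e-8, atol=1e-10)
    ic0 = np.zeros(fixture.make().dim) if ic is None else np.asarray(ic, float)
    return ScanProblem(
        build=lambda w: fixture.make(omega=w),
        initial_state=lambda w: ic0.copy(),
        drive_period=lambda w: 2 * math.pi / w if w > 0 else None,
        settings=settings,
    )


# ---------------------------------------------------------------------------
# composite experiments
# ---------------------------------------------------------------------------


def bias_scan_bidirectional(
    params: ModelParameters,
    stimuli: StimulusSet,
    parameter: str,
    grid: Sequence[float],
    thresholds: RegimeThresholds = RegimeThresholds(),
    settings: IntegrationSettings | None = None,
    probe: bool = False,
    **spec_kw,
) -> tuple[ScanResult, ScanResult, RegimeMap]:
    """Forward and backward continuation scans of an input bias, composed
    into a regime map.  Requires both sinusoidal amplitudes to be zero
    (the map characterises the static-input attractor structure)."""
    if stimuli.sensory.amplitude != 0 or stimuli.cortical.amplitude != 0:
        raise ValueError("bias scans require zero sinusoidal amplitudes")
    if parameter not in _BIAS_CHANNELS:
        raise ValueError(f"{parameter!r} is not a bias channel")
    grid = tuple(sorted(float(v) for v in grid))
    problem = model_scan_problem(params, stimuli, parameter, settings)
    fwd = run_scan(problem, ScanSpec(parameter, grid, **spec_kw), thresholds)
    bwd = run_scan(
        problem, ScanSpec(parameter, grid[::-1], **spec_kw), thresholds
    )
    probes = None
    if probe:
        probes = {}
        ch = _BIAS_CHANNELS[parameter]
        for v in grid:
            stim_v = stimuli.with_bias(ch, v)
            system = build_system(params, stim_v)
            # probe both basins: the solved quiet equilibrium, the raw leak
            # state, a depolarised state and a thalamic rebound kick
            ics = [equilibrium_state(params), depolarized_state(params),
                   rebound_kick_state(params)]
            try:
                ics.insert(0, settled_equilibrium(params, stim_v))
            except Exception:
                pass
            inventory = bistability_probe(
                system, ics, settings=problem.settings, thresholds=thresholds
            )
            probes[v] = {a.kind for a in inventory}
    rmap = compose_regime_map(fwd, bwd, probes, thresholds)
    return fwd, bwd, rmap


def _is_oscillating(record: ScanRecord, thresholds: RegimeThresholds) -> bool:
    return record.extrema.output_range >= thresholds.fixed_point_range


def compose_regime_map(
    forward: ScanResult,
    backward: ScanResult,
    probes: dict[float, set] | None = None,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> RegimeMap:
    """Per grid value: FIXED_POINT_ONLY when all evidence settles to
    equilibrium, LIMIT_CYCLE_ONLY when all of it oscillates, BISTABLE
    when the two scan directions or the initial-condition probes find
    both kinds of attractor; contiguous equal classes merge into
    intervals.  ``probes`` maps a grid value to the set of attractor
    kinds ('fixed_point' / 'oscillation') its probe inventory found."""
    fv = forward.values
    bv = backward.values[::-1]
    if len(fv) != len(bv) or not np.allclose(fv, bv):
        raise ValueError("forward and backward scans ran on different grids")
    brec = backward.records[::-1]
    classes = []
    for i, v in enumerate(fv):
        kinds = set()
        for osc in (
            _is_oscillating(forward.records[i], thresholds),
            _is_oscillating(brec[i], thresholds),
        ):
            kinds.add("oscillation" if osc else "fixed_point")
        if probes is not None:
            kinds |= set(probes.get(float(v), ()))
        if kinds == {"oscillation"}:
            classes.append("LIMIT_CYCLE_ONLY")
        elif kinds == {"fixed_point"}:
            classes.append("FIXED_POINT_ONLY")
        else:
            classes.append("BISTABLE")
    intervals: list[tuple[float, float, str]] = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            intervals.append((float(fv[start]), float(fv[i - 1]), classes[start]))
            start = i
    return RegimeMap(intervals=intervals)


@dataclass
class Attractor:
    kind: str  # "fixed_point" | "oscillation"
    amplitude: float
    mean_level: float


def bistability_probe(
    system: ContinuousSystem,
    ics: Sequence[np.ndarray],
    t_sim: float = 30.0,
    transient_fraction: float = 2.0 / 3.0,
    settings: IntegrationSettings | None = None,
    thresholds: RegimeThresholds = RegimeThresholds(),
    amp_tol: float = 0.1,
) -> list[Attractor]:
    """Integrate each initial condition and inventory the distinct
    terminal attractors, classified by oscillation amplitude and mean
    output level.  With all probes in one basin the inventory undercounts
    -- it is a lower bound on the number of attractors."""
    if len(ics) < 2:
        raise ValueError("need at least 2 distinct initial conditions")
    settings = settings or IntegrationSettings(rtol=1e-7, atol=1e-9)
    found: list[Attractor] = []
    for ic in ics:
        traj = integrate(system, np.asarray(ic, float), (0.0, t_sim), settings)
        post = strip_transient(traj, transient_fraction * t_sim)
        amp = steady_state_amplitude(post)
        mean = float(post.output.mean())
        kind = (
            "fixed_point"
            if 2 * amp < thresholds.fixed_point_range
            else "oscillation"
        )
        matched = False
        for a in found:
            same_kind = a.kind == kind
            close = (
                abs(a.amplitude - amp) <= amp_tol * max(1.0, abs(a.amplitude))
                and abs(a.mean_level - mean) <= max(amp_tol, 0.05 * abs(a.mean_level))
            )
            if same_kind and close:
                matched = True
                break
        if not matched:
            found.append(Attractor(kind=kind, amplitude=amp, mean_level=mean))
    return found


def frequency_bifurcation_scan(
    params: ModelParameters,
    stimuli: StimulusSet,
    channel: str,
    grid: Sequence[float],
    thresholds: RegimeThresholds = RegimeThresholds(),
    settings: IntegrationSettings | None = None,
    compute_mle: bool = True,
    **spec_kw,
) -> ScanResult:
    """Continuation scan over one drive channel's frequency with
    per-point extrema and maximal Lyapunov exponent -- the bifurcation
    diagram of the driven model."""
    if channel not in ("cortical", "sensory"):
        raise ValueError("channel must be 'cortical' or 'sensory'")
    problem = model_scan_problem(params, stimuli, f"{channel}.frequency", settings)
    spec = ScanSpec(
        f"{channel}.frequency", tuple(float(v) for v in grid),
        compute_mle=compute_mle, **spec_kw,
    )
    return run_scan(problem, spec, thresholds)


def sweep_frequency_response(
    problem: ScanProblem,
    grid: Sequence[float],
    direction: str = "forward",
    thresholds: RegimeThresholds = RegimeThresholds(),
    **spec_kw,
) -> FrequencyResponse:
    """Directional frequency sweep with forced continuation; returns the
    steady-state amplitude at each frequency in sweep order."""
    grid = sorted(float(v) for v in grid)
    if direction == "backward":
        grid = grid[::-1]
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'backward'")
    spec = ScanSpec("frequency", tuple(grid), continuation=True, **spec_kw)
    result = run_scan(problem, spec, thresholds)
    return FrequencyResponse(
        frequencies=result.values,
        amplitudes=result.amplitudes,
        direction=direction,
    )


def detect_jumps(
    resp: FrequencyResponse, ratio_threshold: float = 2.0
) -> list[JumpEvent]:
    """Frequencies where the amplitude changes by more than
    ``ratio_threshold`` between adjacent grid points (midpoint reported)."""
    if len(resp.frequencies) < 2:
        raise ValueError("need at least 2 response points")
    events = []
    eps = 1e-300
    for i in range(len(resp.frequencies) - 1):
        a0, a1 = resp.amplitudes[i], resp.amplitudes[i + 1]
        ratio = (max(a0, a1) + eps) / (min(a0, a1) + eps)
        if ratio > ratio_threshold:
            events.append(
                JumpEvent(
                    frequency=float(
                        0.5 * (resp.frequencies[i] + resp.frequencies[i + 1])
                    ),
                    direction="up" if a1 > a0 else "down",
                    ratio=float(ratio),
                )
            )
    return events


def hysteresis_region(
    forward: FrequencyResponse,
    backward: FrequencyResponse,
    tol: float | None = None,
) -> list[tuple[float, float]]:
    """Maximal frequency intervals where forward and backward sweep
    amplitudes differ by more than ``tol`` (default: 10% of the larger
    amplitude at that frequency)."""
    ff = forward.frequencies
    bf = backward.frequencies[::-1]
    if len(ff) != len(bf) or not np.allclose(ff, bf):
        raise ValueError("forward and backward sweeps ran on different grids")
    fa = forward.amplitudes
    ba = backward.amplitudes[::-1]
    if tol is None:
        thresh = 0.1 * np.maximum(fa, ba)
    else:
        thresh = np.full(len(ff), tol)
    differs = np.abs(fa - ba) > thresh
    intervals = []
    start = None
    for i, d in enumerate(differs):
        if d and start is None:
            start = i
        elif not d and start is not None:
            intervals.append((float(ff[start]), float(ff[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(ff[start]), float(ff[-1])))
    return intervals


@dataclass
class SegmentReport:
    t_start: float
    t_end: float
    frequency: float
    label: RegimeLabel
    amplitude: float | None


def transition_protocol(
    params: ModelParameters,
    stimuli: StimulusSet,
    duration: float,
    segment_transient: float = 5.0,
    thresholds: RegimeThresholds = RegimeThresholds(),
    settings: IntegrationSettings | None = None,
    initial: np.ndarray | None = None,
    compute_mle: bool = False,
    mle_kw: dict | None = None,
) -> tuple[Trajectory, list[SegmentReport]]:
    """One continuous integration across a frequency schedule, with
    per-segment regime labels (per-segment transients excluded).

    Segments shorter than the transient are flagged INSUFFICIENT_DATA.
    """
    if stimuli.schedule is None:
        raise ValueError("transition protocol requires a frequency schedule")
    settings = settings or IntegrationSettings(rtol=1e-7, atol=1e-9)
    system = build_system(params, stimuli)
    y0 = equilibrium_state(params) if initial is None else initial
    traj = integrate(system, y0, (0.0, duration), settings)
    edges = [0.0, *stimuli.schedule.switch_times, duration]
    reports = []
    for (a, b), (_, freq) in zip(
        zip(edges[:-1], edges[1:]), stimuli.schedule.segments
    ):
        b = min(b, duration)
        if b - a <= segment_transient + 1e-9:
            reports.append(
                SegmentReport(a, b, freq,
                              RegimeLabel("INSUFFICIENT_DATA"), None)
            )
            continue
        win = traj.window(a + segment_transient, b)
        amp = steady_state_amplitude(win)
        extrema = local_extrema(win, thresholds.cluster_tol)
        period = 1.0 / freq if freq > 0 else None
        section = None
        if period is not None and win.span >= 3 * period:
            section = stroboscopic_section(win, period)
        mle = None
        if compute_mle:
            frozen = stimuli.with_frequency(
                stimuli.schedule_channel, freq
            )
            frozen = replace(frozen, schedule=None, schedule_channel=None)
            mle = max_lyapunov(
                build_system(params, frozen), win.y[-1],
                settings=settings, **(mle_kw or {}),
            )
        reports.append(
            SegmentReport(
                a, b, freq,
                classify_regime(extrema, section, mle, thresholds), amp,
            )
        )
    return traj, reports
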