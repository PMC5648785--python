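"""Adaptive embedded Runge-Kutta integration with dense uniform output.

Undelayed systems are solved with SciPy's adaptive 4(5) embedded
Runge-Kutta pair.  Systems with transport delays are solved by the method
of steps on the same stepper: completed steps' dense-output interpolants
form the history record, delayed state is read from it by polynomial
interpolation, and the step size is capped at the smallest delay so a
stage never needs history beyond the last completed step.

Trajectories are sampled on a fixed uniform grid (default 1 ms)
independent of the internal adaptive steps, so downstream extrema and
Poincare operators always see uniform sampling.  ``continue_from`` hands
the exact terminal state (including the history tail a delayed system
needs) to the next run, which is how parameter-continuation scans chain
runs together.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.integrate._ivp.rk import RK45

from .systems import ContinuousSystem

__all__ = [
    "IntegrationError",
    "DivergenceError",
    "StiffnessError",
    "InsufficientHistoryError",
    "IntegrationSettings",
    "ContinuationState",
    "Trajectory",
    "integrate",
    "continue_from",
    "propagate",
    "tolerance_refinement_drift",
]


class IntegrationError(RuntimeError):
    pass


class StiffnessError(IntegrationError):
    """Step size underflow; message names the failing time."""


class DivergenceError(IntegrationError):
    """Non-finite state encountered."""


class InsufficientHistoryError(IntegrationError):
    """Trajectory too short to seed the delay history of the next run."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Tolerances and output sampling of a run.

    ``rtol``/``atol`` control the local error of the embedded pair;
    ``sample_dt`` is the uniform output interval (s).
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    sample_dt: float = 1e-3

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")


@dataclass
class ContinuationState:
    """State handed from one run to the next: time, state vector and (for
    delayed systems) a callable history over at least the maximum delay."""

    t: float
    y: np.ndarray
    history: Callable[[float], np.ndarray] | None = None


@dataclass
class Trajectory:
    """Uniformly sampled solution with integration metadata."""

    t: np.ndarray
    y: np.ndarray  # (len(t), dim)
    output: np.ndarray
    d_output: np.ndarray
    final: ContinuationState
    settings: IntegrationSettings
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.t) != len(self.output):
            raise ValueError("output length must equal time length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self):
        return len(self.t)

    @property
    def sample_dt(self) -> float:
        return self.settings.sample_dt

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def window(self, t_start: float, t_end: float | None = None) -> "Trajectory":
        """Sub-trajectory with absolute time >= t_start (and < t_end)."""
        mask = self.t >= t_start
        if t_end is not None:
            mask &= self.t <= t_end
        return replace(
            self,
            t=self.t[mask],
            y=self.y[mask],
            output=self.output[mask],
            d_output=self.d_output[mask],
        )


class _History:
    """Piecewise history record: an initial-history function for t <= t0
    followed by the dense outputs of completed integration steps."""

    def __init__(self, t0: float, h0: Callable[[float], np.ndarray]):
        self.t0 = t0
        self.h0 = h0
        self.starts: list[float] = []
        self.interps: list = []
        self.t_end = t0

    def append(self, interp) -> None:
        self.starts.append(interp.t_min)
        self.interps.append(interp)
        self.t_end = interp.t_max

    def __call__(self, t: float) -> np.ndarray:
        if t <= self.t0 or not self.interps:
            return np.asarray(self.h0(min(t, self.t0)), dtype=float)
        i = bisect.bisect_right(self.starts, t) - 1
        i = min(max(i, 0), len(self.interps) - 1)
        # queries slightly past the last completed step (delay smaller than
        # the current step) evaluate the final interpolant's polynomial,
        # i.e. a short extrapolation
        return self.interps[i](t)


def _constant_history(y0: np.ndarray) -> Callable[[float], np.ndarray]:
    y0 = np.asarray(y0, dtype=float).copy()
    return lambda t: y0


def _sample_grid(t0: float, t1: float, dt: float) -> np.ndarray:
    n = int(np.floor((t1 - t0) / dt + 1e-9))
    return t0 + dt * np.arange(n + 1)


def _segment_bounds(t0, t1, breakpoints):
    cuts = sorted(b for b in breakpoints if t0 < b < t1)
    edges = [t0, *cuts, t1]
    return list(zip(edges[:-1], edges[1:]))


def _integrate_ode(system, y0, t0, t1, settings, grid):
    """Piecewise solve_ivp over breakpoint segments; returns (Y_on_grid, y_end)."""
    y = np.asarray(y0, dtype=float)
    out = np.empty((len(grid), system.dim))
    for a, b in _segment_bounds(t0, t1, system.breakpoints):
        sol = solve_ivp(
            system.f,
            (a, b),
            y,
            method="RK45",
            args=system.args or None,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            dense_output=True,
        )
        if sol.status == -1:
            raise StiffnessError(
                f"integration failed near t = {sol.t[-1]:.6g} s: {sol.message}"
            )
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            raise DivergenceError(
                f"non-finite state at t = {sol.t[-1]:.6g} s (trajectory diverged)"
            )
        first = a == t0
        mask = (grid >= a) if first else (grid > a)
        mask &= grid <= b + 1e-12
        if mask.any():
            out[mask] = sol.sol(np.clip(grid[mask], a, b)).T
    return out, y


def _integrate_dde(system, state0: ContinuationState, t1, settings, grid):
    """Method of steps on the RK45 stepper with interpolated history."""
    t0, y0 = state0.t, np.asarray(state0.y, dtype=float)
    h0 = state0.history or _constant_history(y0)
    hist = _History(t0, h0)
    delays = np.array(system.delays, dtype=float)
    pos = delays[delays > 0]
    # steps are capped at the smallest delay so delayed queries stay inside
    # completed history; delays below 1 ms instead rely on the short
    # extrapolation of the last dense segment (capping there would make
    # the step size collapse)
    tau_min = float(pos.min()) if len(pos) else np.inf
    max_step = min(settings.max_step, max(tau_min, 1e-3))

    def fun(t, y):
        ydel = np.empty((len(delays), system.dim))
        for i, d in enumerate(delays):
            ydel[i] = y if d == 0.0 else hist(t - d)
        return system.f_delayed(t, y, ydel, *system.args)

    y = y0
    t = t0
    for a, b in _segment_bounds(t0, t1, system.breakpoints):
        stepper = RK45(
            fun, a, y, b,
            rtol=settings.rtol, atol=settings.atol, max_step=max_step,
            first_step=min(max_step, (b - a) / 10) if np.isfinite(max_step) else None,
        )
        while stepper.status == "running":
            msg = stepper.step()
            if stepper.status == "failed":
                raise StiffnessError(
                    f"integration failed near t = {stepper.t:.6g} s: {msg}"
                )
            hist.append(stepper.dense_output())
            if not np.all(np.isfinite(stepper.y)):
                raise DivergenceError(
                    f"non-finite state at t = {stepper.t:.6g} s (trajectory diverged)"
                )
        t, y = stepper.t, stepper.y

    out = np.empty((len(grid), system.dim))
    for k, tk in enumerate(grid):
        out[k] = hist(tk)
    return out, y, hist


def integrate(
    system: ContinuousSystem,
    initial: np.ndarray | ContinuationState,
    t_span: tuple[float, float],
    settings: IntegrationSettings | None = None,
) -> Trajectory:
    """Integrate ``system`` over ``t_span`` from ``initial``.

    ``initial`` may be a plain state vector or a :class:`ContinuationState`
    returned by :func:`continue_from` (required for delayed systems that
    resume mid-trajectory).  Deterministic: identical inputs produce
    identical trajectories.
    """
    settings = settings or IntegrationSettings()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    if isinstance(initial, ContinuationState):
        state0 = initial
        if abs(state0.t - t0) > 1e-12:
            state0 = ContinuationState(t0, state0.y, state0.history)
    else:
        y0 = np.asarray(initial, dtype=float)
        if y0.shape != (system.dim,):
            raise ValueError(
                f"initial state has shape {y0.shape}, expected ({system.dim},)"
            )
        state0 = ContinuationState(t0, y0, None)
    if not np.all(np.isfinite(state0.y)):
        raise DivergenceError("initial state is non-finite")

    grid = _sample_grid(t0, t1, settings.sample_dt)
    if system.has_delays:
        Y, y_end, hist = _integrate_dde(system, state0, t1, settings, grid)
        final = ContinuationState(t1, y_end, hist)
        d_output = np.gradient(Y[:, system.output_index], grid, edge_order=2)
    else:
        Y, y_end = _integrate_ode(system, state0.y, t0, t1, settings, grid)
        final = ContinuationState(t1, y_end, None)
        d_output = _rhs_output_derivative(system, grid, Y)

    return Trajectory(
        t=grid,
        y=Y,
        output=Y[:, system.output_index].copy(),
        d_output=d_output,
        final=final,
        settings=settings,
        meta={"system": system.name, "t_span": (t0, t1)},
    )


def _rhs_output_derivative(system, grid, Y):
    # mechanical systems carry the output's derivative as a state coordinate
    didx = system.meta.get("d_output_index")
    if didx is not None:
        return Y[:, didx].copy()
    out = np.empty(len(grid))
    for k, tk in enumerate(grid):
        out[k] = system.f(tk, Y[k], *system.args)[system.output_index]
    return out


def continue_from(traj: Trajectory, min_history: float = 0.0) -> ContinuationState:
    """Terminal state of a trajectory, usable as the next run's initial
    condition (final-state continuation between scan points)."""
    if len(traj) == 0:
        raise InsufficientHistoryError("cannot continue from an empty trajectory")
    # a delayed run carries a history record that extends back through its
    # (constant) initial history, so it is always deep enough; a plain run
    # resumed into a delayed system must span the required history itself
    if min_history > 0 and traj.final.history is None and traj.span < min_history:
        raise InsufficientHistoryError(
            f"trajectory spans {traj.span:.3g} s < required history "
            f"{min_history:.3g} s"
        )
    return traj.final


def propagate(
    system: ContinuousSystem,
    y0: np.ndarray,
    t_span: tuple[float, float],
    settings: IntegrationSettings | None = None,
) -> np.ndarray:
    """Terminal state only, without dense sampling (fast path used by the
    Lyapunov estimator). Undelayed systems only."""
    settings = settings or IntegrationSettings()
    if system.has_delays:
        raise NotImplementedError("propagate requires an undelayed system")
    sol = solve_ivp(
        system.f,
        t_span,
        np.asarray(y0, dtype=float),
        method="RK45",
        args=system.args or None,
        rtol=settings.rtol,
        atol=settings.atol,
        max_step=settings.max_step,
    )
    if sol.status != 0:
        raise StiffnessError(
            f"integration failed near t = {sol.t[-1]:.6g} s: {sol.message}"
        )
    y = sol.y[:, -1]
    if not np.all(np.isfinite(y)):
        raise DivergenceError(f"non-finite state at t = {sol.t[-1]:.6g} s")
    return y


def tolerance_refinement_drift(
    system: ContinuousSystem,
    y0: np.ndarray,
    t_span: tuple[float, float],
    settings: IntegrationSettings | None = None,
) -> float:
    """Max-norm terminal-state difference between a run at the given
    tolerances and one at half the tolerances (a convergence check for
    'sufficiently small tolerance' claims)."""
    settings = settings or IntegrationSettings()
    tight = replace(settings, rtol=settings.rtol / 2, atol=settings.atol / 2)
    a = integrate(system, y0, t_span, settings).final.y
    b = integrate(system, y0, t_span, tight).final.y
    return float(np.max(np.abs(a - b)))
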