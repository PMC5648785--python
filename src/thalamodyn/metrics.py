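"""Dynamical signatures extracted from trajectories.

Post-transient extrema (the dots of a bifurcation diagram), stroboscopic
Poincare sections of periodically driven runs, period detection by
cluster cycling, steady-state response amplitude, maximal Lyapunov
exponents (Benettin two-trajectory renormalisation) and a composite
regime classifier (fixed point / period-k / chaotic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist

from .integrate import (
    IntegrationSettings,
    Trajectory,
    propagate,
)
from .systems import ContinuousSystem

__all__ = [
    "ExtremaSet",
    "PoincareSection",
    "RegimeLabel",
    "RegimeThresholds",
    "strip_transient",
    "local_extrema",
    "stroboscopic_section",
    "detect_period",
    "steady_state_amplitude",
    "max_lyapunov",
    "classify_regime",
    "cluster_values",
]


class InsufficientDataError(ValueError):
    pass


def cluster_values(values: np.ndarray, tol: float) -> list[np.ndarray]:
    """Single-linkage clustering of scalars: sorted values split where the
    gap exceeds ``tol``."""
    values = np.sort(np.asarray(values, dtype=float))
    if len(values) == 0:
        return []
    splits = np.nonzero(np.diff(values) > tol)[0] + 1
    return np.split(values, splits)


def _cluster_labels(points: np.ndarray, tol: float) -> np.ndarray:
    """Single-linkage cluster labels (0-based) for a point cloud."""
    if len(points) == 1:
        return np.zeros(1, dtype=int)
    d = pdist(points)
    if np.all(d == 0):
        return np.zeros(len(points), dtype=int)
    return fcluster(linkage(d, method="single"), t=tol, criterion="distance") - 1


@dataclass
class ExtremaSet:
    """Post-transient local extrema of the output signal."""

    maxima: np.ndarray
    minima: np.ndarray
    max_clusters: list[np.ndarray]
    min_clusters: list[np.ndarray]
    output_range: float
    cluster_tol: float

    @property
    def n_max_clusters(self) -> int:
        return len(self.max_clusters)

    @property
    def n_min_clusters(self) -> int:
        return len(self.min_clusters)

    def cluster_representatives(self) -> np.ndarray:
        reps = [float(np.median(c)) for c in self.max_clusters]
        reps += [float(np.median(c)) for c in self.min_clusters]
        return np.array(sorted(reps))


@dataclass
class PoincareSection:
    """Stroboscopic samples of (output, d_output) once per drive period."""

    points: np.ndarray  # (k, 2)
    times: np.ndarray
    period: float
    phase: float


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision constants of the regime classifier.

    ``chaos_mle``: guard band above zero absorbing estimator noise (1/s);
    ``fixed_point_range``: output range (mV) below which a run counts as a
    fixed point; ``cluster_tol``: extrema/section clustering tolerance (mV).
    """

    chaos_mle: float = 0.005
    fixed_point_range: float = 0.01
    cluster_tol: float = 0.05


@dataclass
class RegimeLabel:
    """FIXED_POINT, PERIODIC(k), CHAOTIC or UNRESOLVED, with evidence."""

    category: str
    k: int | None = None
    evidence: dict = field(default_factory=dict)

    def __str__(self):
        return f"PERIODIC({self.k})" if self.category == "PERIODIC" else self.category


def strip_transient(traj: Trajectory, t_cut: float) -> Trajectory:
    """Discard all samples before absolute time ``t_cut``.  Idempotent for
    equal ``t_cut``; ``t_cut`` at/after the final sample is an error."""
    if t_cut >= traj.t[-1]:
        raise ValueError(
            f"t_cut = {t_cut:.6g} s is at/after the trajectory end {traj.t[-1]:.6g} s"
        )
    return traj.window(t_cut)


def local_extrema(traj: Trajectory, cluster_tol: float = 0.05) -> ExtremaSet:
    """Interior local maxima/minima of the output by three-point
    comparison; values within ``cluster_tol`` merge into one cluster.  A
    constant trajectory yields an empty extrema set."""
    x = traj.output
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 samples for extrema")
    mid = x[1:-1]
    is_max = (mid > x[:-2]) & (mid > x[2:])
    is_min = (mid < x[:-2]) & (mid < x[2:])
    maxima = mid[is_max]
    minima = mid[is_min]
    return ExtremaSet(
        maxima=maxima,
        minima=minima,
        max_clusters=cluster_values(maxima, cluster_tol),
        min_clusters=cluster_values(minima, cluster_tol),
        output_range=float(x.max() - x.min()),
        cluster_tol=cluster_tol,
    )


def stroboscopic_section(
    traj: Trajectory, period: float, phase: float | None = None
) -> PoincareSection:
    """Sample (output, d_output) at ``phase + k * period`` by cubic
    interpolation of the uniformly sampled trajectory."""
    if period <= 0:
        raise ValueError("period must be > 0")
    t0, t1 = traj.t[0], traj.t[-1]
    if t1 - t0 < 3 * period:
        raise InsufficientDataError(
            f"span {t1 - t0:.3g} s < 3 drive periods ({3 * period:.3g} s)"
        )
    if phase is None:
        phase = float(t0)
    k0 = int(np.ceil((t0 - phase) / period - 1e-9))
    k1 = int(np.floor((t1 - phase) / period + 1e-9))
    times = phase + period * np.arange(k0, k1 + 1)
    sx = CubicSpline(traj.t, traj.output)
    sv = CubicSpline(traj.t, traj.d_output)
    pts = np.column_stack([sx(times), sv(times)])
    return PoincareSection(points=pts, times=times, period=period, phase=phase)


def detect_period(
    section: PoincareSection, cluster_tol: float = 0.05
) -> int | None:
    """Number of recurrent clusters visited cyclically, or ``None`` for an
    aperiodic section.

    Points are clustered by single linkage; the section is period-k when
    there are k clusters and consecutive samples cycle through them with
    period k.  Scattered sections (many clusters, or clusters not visited
    cyclically) return ``None``.
    """
    pts = section.points
    if len(pts) < 20:
        raise InsufficientDataError(
            f"need >= 20 section points, got {len(pts)}"
        )
    labels = _cluster_labels(pts, cluster_tol)
    k = labels.max() + 1
    if k > max(2, len(pts) // 3):
        return None
    # cyclic visiting: label sequence must repeat with period k
    if k > 1 and not np.all(labels[k:] == labels[:-k]):
        return None
    return int(k)


def steady_state_amplitude(traj: Trajectory) -> float:
    """(max - min) / 2 of the output over the analysis window (mV)."""
    if len(traj) == 0:
        raise InsufficientDataError("empty analysis window")
    return float(traj.output.max() - traj.output.min()) / 2.0


def max_lyapunov(
    system: ContinuousSystem,
    ic: np.ndarray,
    horizon: float = 200.0,
    renorm_interval: float = 0.5,
    d0: float = 1e-6,
    seed: int = 0,
    transient: float = 50.0,
    settings: IntegrationSettings | None = None,
) -> float:
    """Maximal Lyapunov exponent by Benettin two-trajectory
    renormalisation (1/s).

    A companion trajectory offset by ``d0`` along a seeded random direction
    is co-integrated; every ``renorm_interval`` the log stretch ln(d/d0) is
    recorded (after ``transient``) and the offset is rescaled back to
    ``d0``.  The estimate is the time average of the recorded stretches.
    Deterministic given ``seed``.
    """
    if system.has_delays:
        raise NotImplementedError(
            "Lyapunov estimation is implemented for undelayed systems"
        )
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    if horizon < transient + 5 * renorm_interval:
        raise InsufficientDataError(
            "horizon too short: need transient + at least 5 renorm intervals"
        )
    settings = settings or IntegrationSettings(rtol=1e-8, atol=1e-10)
    n = system.dim
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=n)
    direction /= np.linalg.norm(direction)

    f, args = system.f, system.args

    def f2(t, Y):
        return np.concatenate((f(t, Y[:n], *args), f(t, Y[n:], *args)))

    coupled = ContinuousSystem(
        name=f"{system.name}+companion", dim=2 * n, f=f2,
        breakpoints=system.breakpoints,
    )
    u = np.asarray(ic, dtype=float)
    v = u + d0 * direction
    t = 0.0
    acc = 0.0
    t_acc = 0.0
    while t < horizon - 1e-12:
        t_next = min(t + renorm_interval, horizon)
        Y = propagate(coupled, np.concatenate((u, v)), (t, t_next), settings)
        u, v = Y[:n], Y[n:]
        d = float(np.linalg.norm(v - u))
        if d == 0.0:
            # perturbation collapsed below representable separation
            v = u + d0 * direction
            t = t_next
            continue
        if t_next > transient:
            acc += np.log(d / d0)
            t_acc += t_next - t
        v = u + (v - u) * (d0 / d)
        t = t_next
    if t_acc == 0.0:
        raise InsufficientDataError("no post-transient renormalisations recorded")
    return float(acc / t_acc)


def classify_regime(
    extrema: ExtremaSet,
    section: PoincareSection | None,
    mle: float | None,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> RegimeLabel:
    """Composite label from extrema, Poincare section and MLE evidence.

    Fixed point when the output range is below the fixed-point tolerance;
    chaotic when the MLE clears its guard band (unless the section is a
    single tight cluster, which conflicts and yields UNRESOLVED);
    otherwise periodic with the section's cluster count.
    """
    ev: dict = {
        "output_range": extrema.output_range,
        "n_max_clusters": extrema.n_max_clusters,
        "mle": mle,
    }
    if extrema.output_range < thresholds.fixed_point_range:
        return RegimeLabel("FIXED_POINT", evidence=ev)
    k = None
    if section is not None:
        try:
            k = detect_period(section, thresholds.cluster_tol)
        except InsufficientDataError:
            k = None
    ev["section_period"] = k
    if mle is not None and mle > thresholds.chaos_mle:
        if k == 1:
            return RegimeLabel("UNRESOLVED", evidence=ev)
        return RegimeLabel("CHAOTIC", evidence=ev)
    if k is None and section is not None:
        # aperiodic section without MLE support for chaos
        if mle is None:
            return RegimeLabel("UNRESOLVED", evidence=ev)
        return RegimeLabel("UNRESOLVED", evidence=ev)
    return RegimeLabel("PERIODIC", k=k if k is not None else 1, evidence=ev)
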