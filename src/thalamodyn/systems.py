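"""Generic continuous-time system container used by the integrator.

A :class:`ContinuousSystem` wraps a right-hand side ``f(t, y, *args)``
(optionally compiled with numba) together with its dimension, optional
transport delays and the index of the scalar observable that downstream
analysis operates on.  Delayed systems provide ``f_delayed(t, y, ydel,
*args)`` where ``ydel[i]`` is the full state vector at ``t - delays[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

__all__ = ["ContinuousSystem"]


@dataclass
class ContinuousSystem:
    name: str
    dim: int
    f: Callable | None = None
    args: tuple = ()
    delays: tuple[float, ...] = ()
    f_delayed: Callable | None = None
    #: index of the scalar output observable in the state vector
    output_index: int = 0
    #: times at which the rhs is non-smooth (e.g. stimulus-frequency
    #: switches); the integrator restarts a step exactly there
    breakpoints: tuple[float, ...] = ()
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if any(d < 0 for d in self.delays):
            raise ValueError("delays must be >= 0")
        if self.has_delays and self.f_delayed is None:
            raise ValueError("delayed system requires f_delayed")
        if not self.has_delays and self.f is None:
            if self.f_delayed is None:
                raise ValueError("system requires a right-hand side")
            # degenerate: delayed form with no (positive) delays
            fd, n = self.f_delayed, self.dim

            def _f(t, y, *args, _fd=fd):
                ydel = np.broadcast_to(y, (max(1, len(self.delays)), n))
                return _fd(t, y, ydel, *args)

            self.f = _f

    @property
    def has_delays(self) -> bool:
        return any(d > 0 for d in self.delays)

    @property
    def max_delay(self) -> float:
        return max(self.delays) if self.delays else 0.0

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Evaluate the undelayed right-hand side (delays treated as 0)."""
        if self.f is not None and not self.has_delays:
            return np.asarray(self.f(t, y, *self.args))
        ydel = np.broadcast_to(y, (len(self.delays), self.dim)).copy()
        return np.asarray(self.f_delayed(t, y, ydel, *self.args))
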