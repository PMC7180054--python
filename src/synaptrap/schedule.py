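"""Piecewise-constant kinetic schedules k_on(t), k_off(t).

Times are on the recorded axis: t = 0 is the start of the baseline window,
so the burn-in occupies negative times and a plasticity induction placed at
the end of the baseline sits at t = t_baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError

__all__ = ["KineticSchedule"]


@dataclass(frozen=True)
class KineticSchedule:
    """Right-continuous piecewise-constant binding/unbinding rates.

    ``breakpoints[i]`` is the start time of interval *i*; the rates
    ``k_on_values[i]`` and ``k_off_values[i]`` apply on
    [breakpoints[i], breakpoints[i+1]). The last interval extends to +inf.
    """

    breakpoints: tuple[float, ...]
    k_on_values: tuple[float, ...]
    k_off_values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = tuple(float(t) for t in self.breakpoints)
        kon = tuple(float(k) for k in self.k_on_values)
        koff = tuple(float(k) for k in self.k_off_values)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "k_on_values", kon)
        object.__setattr__(self, "k_off_values", koff)
        if not bp:
            raise ConfigurationError("schedule needs at least one interval")
        if len(kon) != len(bp) or len(koff) != len(bp):
            raise ConfigurationError(
                "breakpoints, k_on_values and k_off_values must align"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ConfigurationError("breakpoints must be strictly increasing")
        if any(k < 0 for k in kon + koff):
            raise ConfigurationError("kinetic rates must be >= 0")

    @classmethod
    def constant(
        cls, k_on: float, k_off: float, t_start: float = -np.inf
    ) -> "KineticSchedule":
        start = t_start if np.isfinite(t_start) else -1e30
        return cls((start,), (k_on,), (k_off,))

    @property
    def t_start(self) -> float:
        return self.breakpoints[0]

    def rates_at(self, t: float) -> tuple[float, float]:
        """(k_on, k_off) governing the step that begins at time ``t``."""
        if t < self.breakpoints[0]:
            raise ConfigurationError(
                f"time {t} precedes the schedule start {self.breakpoints[0]}"
            )
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.k_on_values[i], self.k_off_values[i]

    def covers(self, t_start: float, t_end: float) -> bool:
        return self.breakpoints[0] <= t_start and t_start <= t_end
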