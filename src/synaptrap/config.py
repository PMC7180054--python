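"""Simulation geometry and parameter records.

The model domain is a rectangular patch of dendritic membrane containing a
row of square synapses (postsynaptic densities, PSDs). All lengths are in
micrometres, times in seconds, diffusion coefficients in µm²/s and kinetic
rates in s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "ConfigurationError",
    "SynapseRegion",
    "SimulationConfig",
    "default_synapses",
]


class ConfigurationError(ValueError):
    """Raised when a configuration record violates its invariants."""


@dataclass(frozen=True)
class SynapseRegion:
    """An immobile square synapse (PSD) inside the membrane region."""

    id: int
    center_x: float
    center_y: float
    side: float = 0.3

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ConfigurationError(f"synapse {self.id}: side must be > 0")

    @property
    def x_min(self) -> float:
        return self.center_x - self.side / 2.0

    @property
    def x_max(self) -> float:
        return self.center_x + self.side / 2.0

    @property
    def y_min(self) -> float:
        return self.center_y - self.side / 2.0

    @property
    def y_max(self) -> float:
        return self.center_y + self.side / 2.0

    @property
    def area(self) -> float:
        return self.side * self.side

    def contains(self, x, y):
        """Vectorised membership test (closed square)."""
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


def default_synapses(
    n: int = 5,
    region_length: float = 10.0,
    region_width: float = 2.0,
    side: float = 0.3,
) -> tuple[SynapseRegion, ...]:
    """Evenly spaced synapses along the mid-line of the region.

    For the default 10 µm segment this places 5 synapses at
    x = 1, 3, 5, 7, 9 µm, y = 1 µm — a linear density of 0.5 synapse/µm.
    """
    spacing = region_length / n
    return tuple(
        SynapseRegion(
            id=i,
            center_x=spacing * (i + 0.5),
            center_y=region_width / 2.0,
            side=side,
        )
        for i in range(n)
    )


BarrierMode = Literal["symmetric", "entry-only", "exit-only"]
BoundEdgeMode = Literal["hold", "reflect"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one diffusion-trapping simulation.

    Defaults reproduce the reference conditions: a 2 µm × 10 µm dendritic
    segment holding five 0.3 µm PSD squares and a closed population of 1000
    receptors, advanced in 0.1 s steps. Free receptors diffuse at ``D_out``
    outside synapses and ``D_in`` inside (slower, from steric hindrance in
    the cleft); scaffold-bound receptors are confined at ``D_trap``. Moves
    that cross a synapse border are accepted with probability
    ``p_crossing`` (a diffusion barrier at the synapse edge).
    ``barrier_mode`` selects which crossings are gated: ``entry-only`` (the
    default) gates moves into a synapse, so the barrier scales the
    synaptic density by p_crossing as in the mean-field enrichment
    formula; ``symmetric`` gates both directions (which slows exchange but
    leaves the stationary density unchanged); ``exit-only`` gates exits.

    Timing: ``t_burn_in`` seconds of unrecorded equilibration precede the
    recorded span of ``t_baseline`` + ``t_post`` seconds; counts are
    sampled every ``sample_interval`` seconds on the recorded axis, whose
    origin t=0 is the start of the baseline.
    """

    region_length: float = 10.0
    region_width: float = 2.0
    synapses: tuple[SynapseRegion, ...] = ()
    n_receptors: int = 1000
    dt: float = 0.1
    D_out: float = 0.1
    D_in: float = 0.05
    D_trap: float = 0.006
    p_crossing: float = 0.5
    t_burn_in: float = 300.0
    t_baseline: float = 300.0
    t_post: float = 1800.0
    sample_interval: float = 10.0
    seed: int = 0
    barrier_mode: BarrierMode = "entry-only"
    bound_edge: BoundEdgeMode = "hold"

    def __post_init__(self) -> None:
        if not self.synapses:
            object.__setattr__(
                self,
                "synapses",
                default_synapses(
                    region_length=self.region_length,
                    region_width=self.region_width,
                ),
            )
        else:
            object.__setattr__(self, "synapses", tuple(self.synapses))
        self.validate()

    def validate(self) -> None:
        if self.region_length <= 0 or self.region_width <= 0:
            raise ConfigurationError("region dimensions must be positive")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_receptors < 1:
            raise ConfigurationError("n_receptors must be >= 1")
        for name in ("D_out", "D_in", "D_trap"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.p_crossing <= 1.0:
            raise ConfigurationError("p_crossing must lie in [0, 1]")
        for name in ("t_burn_in", "t_baseline", "t_post"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be positive")
        if self.barrier_mode not in ("symmetric", "entry-only", "exit-only"):
            raise ConfigurationError(
                f"unknown barrier_mode {self.barrier_mode!r}"
            )
        if self.bound_edge not in ("hold", "reflect"):
            raise ConfigurationError(f"unknown bound_edge {self.bound_edge!r}")
        for syn in self.synapses:
            if (
                syn.x_min < 0
                or syn.x_max > self.region_length
                or syn.y_min < 0
                or syn.y_max > self.region_width
            ):
                raise ConfigurationError(
                    f"synapse {syn.id} extends outside the region"
                )
        for i, a in enumerate(self.synapses):
            for b in self.synapses[i + 1 :]:
                if (
                    a.x_min < b.x_max
                    and b.x_min < a.x_max
                    and a.y_min < b.y_max
                    and b.y_min < a.y_max
                ):
                    raise ConfigurationError(
                        f"synapses {a.id} and {b.id} overlap"
                    )

    # -- derived geometry -------------------------------------------------

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)

    @property
    def region_area(self) -> float:
        return self.region_length * self.region_width

    @property
    def synaptic_area(self) -> float:
        return sum(s.area for s in self.synapses)

    @property
    def t_total_recorded(self) -> float:
        return self.t_baseline + self.t_post

    def with_(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)
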