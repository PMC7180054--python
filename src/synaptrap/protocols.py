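"""Experiment protocols: basal steady state, LTP variants, replicates.

Long-term potentiation (LTP) is modelled purely as a kinetic step change at
the induction time (the end of the recorded baseline): the receptor/scaffold
unbinding rate k_off drops, so receptors diffusing through the synapse are
trapped longer and the synaptic pool grows toward a new equilibrium.
Elevated tyrosine-phosphorylation of neuroligin-1 is modelled as a higher
binding rate k_on from the start, which raises the basal synaptic pool. A
rejected alternative, stepping k_on up at induction, is kept as the
``kon_step_ltp`` protocol because its much faster rise time is itself an
informative prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import ConfigurationError, SimulationConfig
from .core import SynapseTimeSeries, run_simulation
from .schedule import KineticSchedule

__all__ = ["ProtocolSpec", "ReplicateSet", "make_schedule", "run_replicates",
           "PROTOCOL_NAMES"]

PROTOCOL_NAMES = (
    "basal",
    "ltp",
    "phospho_basal",
    "phospho_ltp",
    "ko_ltp",
    "kon_step_ltp",
)

# Default kinetic parameters per protocol.  LTP drops k_off 0.04 -> 0.004;
# the knockout variant only reaches 0.008; the phosphorylation condition
# triples k_on.  The kon-step variant raises k_on 1 -> 10 at induction,
# chosen so its final k_on/k_off equals that of the k_off-drop protocol
# (matched equilibrium plateau; only the kinetics differ).
_DEFAULTS = {
    "basal": dict(k_on_base=1.0, k_off_base=0.04),
    "ltp": dict(k_on_base=1.0, k_off_base=0.04, k_off_potentiated=0.004),
    "phospho_basal": dict(k_on_base=3.0, k_off_base=0.04),
    "phospho_ltp": dict(k_on_base=3.0, k_off_base=0.04, k_off_potentiated=0.004),
    "ko_ltp": dict(k_on_base=1.0, k_off_base=0.04, k_off_potentiated=0.008),
    "kon_step_ltp": dict(k_on_base=1.0, k_off_base=0.04, k_on_potentiated=10.0),
}


@dataclass(frozen=True)
class ProtocolSpec:
    """Kinetic parameterisation of one simulated experiment.

    ``t_induction`` is relative to the recording start; ``None`` means the
    end of the baseline window of the simulation config it is paired with.
    """

    name: str
    k_on_base: float = 1.0
    k_off_base: float = 0.04
    k_off_potentiated: Optional[float] = None
    k_on_potentiated: Optional[float] = None
    t_induction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ConfigurationError(
                f"unknown protocol {self.name!r}; expected one of {PROTOCOL_NAMES}"
            )
        if self.k_on_base < 0 or self.k_off_base < 0:
            raise ConfigurationError("kinetic rates must be >= 0")
        if self.name in ("ltp", "phospho_ltp", "ko_ltp"):
            if self.k_off_potentiated is None:
                raise ConfigurationError(
                    f"protocol {self.name!r} requires k_off_potentiated"
                )
            if not self.k_off_potentiated < self.k_off_base:
                raise ConfigurationError(
                    "k_off_potentiated must be below k_off_base for LTP"
                )
        if self.name == "kon_step_ltp":
            if self.k_on_potentiated is None:
                raise ConfigurationError(
                    "protocol 'kon_step_ltp' requires k_on_potentiated"
                )
            if not self.k_on_potentiated > self.k_on_base:
                raise ConfigurationError(
                    "k_on_potentiated must exceed k_on_base"
                )

    @classmethod
    def from_name(cls, name: str, **overrides) -> "ProtocolSpec":
        """Spec with the reference kinetic defaults for ``name``."""
        if name not in _DEFAULTS:
            raise ConfigurationError(
                f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}"
            )
        params = {**_DEFAULTS[name], **overrides}
        return cls(name=name, **params)

    @property
    def has_induction(self) -> bool:
        return self.name in ("ltp", "phospho_ltp", "ko_ltp", "kon_step_ltp")


def make_schedule(spec: ProtocolSpec, config: SimulationConfig) -> KineticSchedule:
    """Piecewise-constant k_on(t)/k_off(t) spanning burn-in through post.

    Schedules are deterministic functions of (spec, config). For protocols
    with an induction the rates change once, at ``spec.t_induction``
    (default: end of the baseline window); basal protocols are constant.
    """
    t_start = -config.t_burn_in
    if not spec.has_induction:
        return KineticSchedule(
            (t_start,), (spec.k_on_base,), (spec.k_off_base,)
        )
    t_ind = config.t_baseline if spec.t_induction is None else spec.t_induction
    if not (t_start < t_ind <= config.t_total_recorded):
        raise ConfigurationError("t_induction must lie inside the recorded span")
    if spec.name == "kon_step_ltp":
        k_on_post, k_off_post = spec.k_on_potentiated, spec.k_off_base
    else:
        k_on_post, k_off_post = spec.k_on_base, spec.k_off_potentiated
    return KineticSchedule(
        (t_start, t_ind),
        (spec.k_on_base, k_on_post),
        (spec.k_off_base, k_off_post),
    )


@dataclass
class ReplicateSet:
    """Independent seeded runs of one protocol with summary statistics.

    ``replicate_counts[r, t]`` is the per-synapse receptor count of
    replicate ``r`` at sample ``t`` (mean over the synapses of that run);
    ``mean_count``/``sem_count`` summarise across replicates (SEM with
    denominator n_replicates, NaN when a single replicate is run).
    """

    spec: ProtocolSpec
    config: SimulationConfig
    base_seed: int
    members: list[SynapseTimeSeries]
    times: np.ndarray = field(init=False)
    replicate_counts: np.ndarray = field(init=False)
    mean_count: np.ndarray = field(init=False)
    sem_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError("a ReplicateSet needs >= 1 member run")
        self.times = self.members[0].times
        self.replicate_counts = np.vstack(
            [m.mean_synaptic_count for m in self.members]
        )
        self.mean_count = self.replicate_counts.mean(axis=0)
        n = self.n_replicates
        if n > 1:
            self.sem_count = self.replicate_counts.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            self.sem_count = np.full_like(self.mean_count, np.nan)

    @property
    def n_replicates(self) -> int:
        return len(self.members)

    def baseline_window(self) -> tuple[float, float]:
        return (0.0, self.config.t_baseline)

    def plateau_window(self) -> tuple[float, float]:
        """Final five minutes of the recorded span (equilibrated)."""
        t_end = self.config.t_total_recorded
        return (t_end - 300.0, t_end)


def run_replicates(
    config: SimulationConfig,
    spec: ProtocolSpec,
    n_replicates: int = 10,
    base_seed: int = 0,
) -> ReplicateSet:
    """Run ``n_replicates`` independent simulations of one protocol.

    Replicate ``r`` uses seed ``base_seed + r``, so a ReplicateSet is fully
    reproducible from (config, spec, n_replicates, base_seed).
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    schedule = make_schedule(spec, config)
    members = []
    for r in range(n_replicates):
        series, _ = run_simulation(
            config, schedule, replicate_id=r, seed=base_seed + r
        )
        members.append(series)
    return ReplicateSet(
        spec=spec, config=config, base_seed=base_seed, members=members
    )
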