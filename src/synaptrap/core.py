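"""Stochastic engine: Brownian steps, border crossing, scaffold binding.

Each receptor is a point particle on the membrane rectangle. One time step
of length dt advances the ensemble through a fixed cycle:

1. binding/unbinding: a free receptor inside a synapse binds the scaffold
   with probability min(k_on·dt, 1); a bound receptor releases with
   probability min(k_off·dt, 1);
2. displacement: each receptor moves by independent Gaussian increments of
   standard deviation sqrt(2·D·dt) per axis, with D selected by its state
   (bound → D_trap, free inside a synapse → D_in, free outside → D_out);
3. reflection at the region contour (the system is closed);
4. border rule: a free receptor whose move changes synapse membership keeps
   its old position unless the crossing is accepted (prob. p_crossing);
   a bound receptor whose move would leave its synapse square is held in
   place (confinement in the PSD).

Kinetics are evaluated before movement so that binding depends on the
position at the start of the step. All random draws come from a single
numpy Generator in a fixed order (kinetics uniforms, displacement normals,
crossing uniforms), which makes trajectories bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ConfigurationError, SimulationConfig
from .schedule import KineticSchedule

__all__ = [
    "ReceptorEnsemble",
    "SynapseTimeSeries",
    "OccupancyGrid",
    "draw_displacement",
    "reflect_into_region",
    "synapse_index",
    "apply_crossing_rule",
    "update_binding_state",
    "step",
    "run_simulation",
]

FREE = -1  # sentinel in bound_synapse for unbound receptors


@dataclass
class ReceptorEnsemble:
    """Positions and binding state of every receptor (closed population).

    ``bound_synapse[i]`` is the id of the synapse receptor *i* is bound to,
    or -1 if the receptor is free.
    """

    x: np.ndarray
    y: np.ndarray
    bound_synapse: np.ndarray  # int array, -1 = free

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def bound(self) -> np.ndarray:
        return self.bound_synapse >= 0

    @classmethod
    def uniform_random(
        cls, config: SimulationConfig, rng: np.random.Generator
    ) -> "ReceptorEnsemble":
        """All receptors free, uniformly placed over the whole rectangle."""
        n = config.n_receptors
        return cls(
            x=rng.uniform(0.0, config.region_length, n),
            y=rng.uniform(0.0, config.region_width, n),
            bound_synapse=np.full(n, FREE, dtype=np.int64),
        )

    def check_invariants(self, config: SimulationConfig) -> None:
        if self.x.size != config.n_receptors or self.y.size != config.n_receptors:
            raise AssertionError("receptor count changed: system must be closed")
        if np.any(self.x < 0) or np.any(self.x > config.region_length):
            raise AssertionError("x coordinate outside region")
        if np.any(self.y < 0) or np.any(self.y > config.region_width):
            raise AssertionError("y coordinate outside region")
        for syn in config.synapses:
            m = self.bound_synapse == syn.id
            if m.any() and not np.all(syn.contains(self.x[m], self.y[m])):
                raise AssertionError(
                    f"bound receptor outside synapse {syn.id} square"
                )


@dataclass
class SynapseTimeSeries:
    """Sampled per-synapse and extra-synaptic receptor counts.

    ``total`` counts every receptor (bound or free) inside each synapse
    square; ``bound`` counts only scaffold-bound receptors. At every sample
    ``total.sum(axis=1) + extra == n_receptors``.
    """

    times: np.ndarray  # (n_samples,) seconds, 0 = start of baseline
    bound: np.ndarray  # (n_samples, n_synapses)
    total: np.ndarray  # (n_samples, n_synapses)
    extra: np.ndarray  # (n_samples,)
    replicate_id: int
    config: SimulationConfig

    @property
    def mean_synaptic_count(self) -> np.ndarray:
        """Per-sample receptor count per synapse, averaged over synapses."""
        return self.total.mean(axis=1)


@dataclass
class OccupancyGrid:
    """Time-averaged spatial receptor density on a regular grid.

    ``matrix[i, j]`` is the mean number of receptors found in spatial bin
    (i, j) per accumulation step (rows index x, columns index y).
    """

    bin_size: float
    matrix: np.ndarray
    window: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


# --------------------------------------------------------------------------
# elementary operations


def draw_displacement(
    D: float, dt: float, rng: np.random.Generator, n: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian increments: dx, dy ~ Normal(0, sqrt(2·D·dt)) independently."""
    if D < 0:
        raise ConfigurationError("diffusion coefficient must be >= 0")
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    sigma = np.sqrt(2.0 * D * dt)
    dx = sigma * rng.standard_normal(n)
    dy = sigma * rng.standard_normal(n)
    return dx, dy


def _fold(v: np.ndarray, length: float) -> np.ndarray:
    """Mirror-reflect coordinates into [0, length] (repeatedly if needed)."""
    period = 2.0 * length
    v = np.mod(v, period)
    return length - np.abs(v - length)


def reflect_into_region(x, y, config: SimulationConfig):
    """Mirror proposed coordinates back inside the closed rectangle."""
    x = _fold(np.asarray(x, dtype=float), config.region_length)
    y = _fold(np.asarray(y, dtype=float), config.region_width)
    return x, y


def synapse_index(x, y, config: SimulationConfig) -> np.ndarray:
    """Id of the synapse square containing each point, -1 outside all."""
    x = np.asarray(x, dtype=float)
    idx = np.full(x.shape, FREE, dtype=np.int64)
    for syn in config.synapses:
        idx = np.where(syn.contains(x, y), syn.id, idx)
    return idx


def apply_crossing_rule(
    old_x,
    old_y,
    new_x,
    new_y,
    config: SimulationConfig,
    rng: np.random.Generator,
    u: Optional[np.ndarray] = None,
    old_idx: Optional[np.ndarray] = None,
    new_idx: Optional[np.ndarray] = None,
):
    """Accept or reject moves of free receptors at synapse borders.

    A move that changes synapse membership is accepted with probability
    p_crossing, otherwise the receptor keeps its old position for this
    step. ``barrier_mode`` restricts the rule to entries only (the
    default), exits only, or both directions. Pre-drawn uniforms may be
    passed via ``u`` (and membership indices via ``old_idx``/``new_idx``)
    to keep the caller's random stream layout fixed.
    """
    old_x = np.asarray(old_x, dtype=float)
    new_x = np.asarray(new_x, dtype=float)
    if old_idx is None:
        old_idx = synapse_index(old_x, old_y, config)
    if new_idx is None:
        new_idx = synapse_index(new_x, new_y, config)
    if config.barrier_mode == "entry-only":
        gated = (new_idx != old_idx) & (new_idx >= 0)
    elif config.barrier_mode == "exit-only":
        gated = (new_idx != old_idx) & (old_idx >= 0)
    else:
        gated = new_idx != old_idx
    if u is None:
        u = rng.random(old_x.shape)
    reject = gated & (u >= config.p_crossing)
    x = np.where(reject, old_x, new_x)
    y = np.where(reject, old_y, new_y)
    return x, y


def update_binding_state(
    bound_synapse: np.ndarray,
    inside_synapse: np.ndarray,
    k_on: float,
    k_off: float,
    dt: float,
    rng: np.random.Generator,
    u: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One kinetic substep of the two-state binding chain.

    Free receptors inside a synapse bind it with probability min(k_on·dt,1);
    bound receptors release with probability min(k_off·dt,1). Free receptors
    outside any synapse never bind. ``inside_synapse`` holds the id of the
    containing synapse (-1 outside).
    """
    if k_on < 0 or k_off < 0:
        raise ConfigurationError("kinetic rates must be >= 0")
    p_bind = min(k_on * dt, 1.0)
    p_unbind = min(k_off * dt, 1.0)
    if u is None:
        u = rng.random(bound_synapse.shape)
    bound = bound_synapse >= 0
    binds = (~bound) & (inside_synapse >= 0) & (u < p_bind)
    unbinds = bound & (u < p_unbind)
    out = bound_synapse.copy()
    out[binds] = inside_synapse[binds]
    out[unbinds] = FREE
    return out


def step(
    ensemble: ReceptorEnsemble,
    config: SimulationConfig,
    k_on: float,
    k_off: float,
    rng: np.random.Generator,
) -> ReceptorEnsemble:
    """Advance the ensemble by one dt (kinetics, move, reflect, barrier)."""
    n = ensemble.n
    x, y = ensemble.x, ensemble.y
    here = synapse_index(x, y, config)

    u_kin = rng.random(n)
    bound_synapse = update_binding_state(
        ensemble.bound_synapse, here, k_on, k_off, config.dt, rng, u=u_kin
    )
    bound = bound_synapse >= 0

    D = np.where(bound, config.D_trap, np.where(here >= 0, config.D_in, config.D_out))
    sigma = np.sqrt(2.0 * D * config.dt)
    normals = rng.standard_normal((n, 2))
    new_x = x + sigma * normals[:, 0]
    new_y = y + sigma * normals[:, 1]
    new_x, new_y = reflect_into_region(new_x, new_y, config)

    u_cross = rng.random(n)
    # free receptors: permeable barrier at synapse borders
    free = ~bound
    new_idx = synapse_index(new_x, new_y, config)
    fx, fy = apply_crossing_rule(
        x[free],
        y[free],
        new_x[free],
        new_y[free],
        config,
        rng,
        u=u_cross[free],
        old_idx=here[free],
        new_idx=new_idx[free],
    )
    new_x[free] = fx
    new_y[free] = fy

    # bound receptors: confined to their synapse square
    if bound.any():
        bs = bound_synapse[bound]
        bx, by = new_x[bound], new_y[bound]
        inside_own = np.zeros(bs.shape, dtype=bool)
        for syn in config.synapses:
            m = bs == syn.id
            if m.any():
                inside_own[m] = syn.contains(bx[m], by[m])
        if config.bound_edge == "hold":
            bx = np.where(inside_own, bx, x[bound])
            by = np.where(inside_own, by, y[bound])
        else:  # reflect at the square edges
            for syn in config.synapses:
                m = (bs == syn.id) & ~inside_own
                if m.any():
                    bx[m] = syn.x_min + _fold(bx[m] - syn.x_min, syn.side)
                    by[m] = syn.y_min + _fold(by[m] - syn.y_min, syn.side)
        new_x[bound] = bx
        new_y[bound] = by

    return ReceptorEnsemble(x=new_x, y=new_y, bound_synapse=bound_synapse)


# --------------------------------------------------------------------------
# trajectory generation


def _count_sample(
    ensemble: ReceptorEnsemble, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    idx = synapse_index(ensemble.x, ensemble.y, config)
    n_syn = config.n_synapses
    total = np.bincount(idx[idx >= 0], minlength=n_syn)[:n_syn]
    bs = ensemble.bound_synapse
    bound = np.bincount(bs[bs >= 0], minlength=n_syn)[:n_syn]
    extra = ensemble.n - int(total.sum())
    return bound, total, extra


def run_simulation(
    config: SimulationConfig,
    schedule: KineticSchedule,
    replicate_id: int = 0,
    seed: Optional[int] = None,
    record_occupancy: bool = False,
    occupancy_bin_size: float = 0.05,
    check_invariants: bool = True,
) -> tuple[SynapseTimeSeries, Optional[OccupancyGrid]]:
    """Generate one full trajectory and its sampled count time series.

    The ensemble starts uniform and unbound, equilibrates for ``t_burn_in``
    seconds (unrecorded), then counts are sampled every ``sample_interval``
    seconds on the recorded axis t ∈ [0, t_baseline + t_post], with t = 0
    at the start of the baseline. The schedule must cover the whole span
    including burn-in.
    """
    if seed is None:
        seed = config.seed
    t0 = -config.t_burn_in
    t_end = config.t_total_recorded
    if schedule.t_start > t0:
        raise ConfigurationError(
            "schedule starts after the burn-in begins; it must span "
            "burn-in + baseline + post"
        )
    dt = config.dt
    n_steps = int(round((t_end - t0) / dt))
    sample_every = max(1, int(round(config.sample_interval / dt)))
    burn_steps = int(round(config.t_burn_in / dt))

    rng = np.random.default_rng(seed)
    ensemble = ReceptorEnsemble.uniform_random(config, rng)

    times, bounds, totals, extras = [], [], [], []

    occ = None
    if record_occupancy:
        nx = int(round(config.region_length / occupancy_bin_size))
        ny = int(round(config.region_width / occupancy_bin_size))
        occ = np.zeros((nx, ny))
        occ_steps = 0

    def record(t: float) -> None:
        b, tot, ex = _count_sample(ensemble, config)
        times.append(t)
        bounds.append(b)
        totals.append(tot)
        extras.append(ex)

    for i in range(n_steps):
        t = t0 + i * dt
        k_on, k_off = schedule.rates_at(t)
        ensemble = step(ensemble, config, k_on, k_off, rng)
        after = i + 1
        t_after = t0 + after * dt
        if after >= burn_steps:
            rec_step = after - burn_steps  # steps since t = 0
            if rec_step % sample_every == 0:
                record(t_after)
            if occ is not None:
                ix = np.minimum(
                    (ensemble.x / occupancy_bin_size).astype(int), occ.shape[0] - 1
                )
                iy = np.minimum(
                    (ensemble.y / occupancy_bin_size).astype(int), occ.shape[1] - 1
                )
                np.add.at(occ, (ix, iy), 1)
                occ_steps += 1

    if check_invariants:
        ensemble.check_invariants(config)

    series = SynapseTimeSeries(
        times=np.asarray(times),
        bound=np.asarray(bounds),
        total=np.asarray(totals),
        extra=np.asarray(extras),
        replicate_id=replicate_id,
        config=config,
    )
    grid = None
    if occ is not None and occ_steps:
        grid = OccupancyGrid(
            bin_size=occupancy_bin_size,
            matrix=occ / occ_steps,
            window=(0.0, t_end),
        )
    return series, grid
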