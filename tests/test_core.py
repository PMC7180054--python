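"""Unit and property tests for the stochastic engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptrap import ConfigurationError, KineticSchedule, SimulationConfig, run_simulation
from synaptrap.core import (
    FREE,
    ReceptorEnsemble,
    apply_crossing_rule,
    draw_displacement,
    reflect_into_region,
    step,
    synapse_index,
    update_binding_state,
)


# --------------------------------------------------------------------------
# displacements


def test_zero_diffusion_never_moves(rng):
    dx, dy = draw_displacement(0.0, 0.1, rng, n=100)
    assert np.all(dx == 0) and np.all(dy == 0)


def test_displacement_std_matches_closed_form(rng):
    # per-axis std must be sqrt(2 D dt) = sqrt(2*0.1*0.1) ~ 0.1414 µm
    n = 100_000
    dx, dy = draw_displacement(0.1, 0.1, rng, n=n)
    expected = np.sqrt(2 * 0.1 * 0.1)
    se = expected / np.sqrt(2 * n)  # std error of a sample std
    assert abs(dx.std() - expected) < 4 * se
    assert abs(dy.std() - expected) < 4 * se
    assert abs(dx.mean()) < 4 * expected / np.sqrt(n)


@pytest.mark.parametrize("D,dt", [(-0.1, 0.1), (0.1, 0.0), (0.1, -1.0)])
def test_displacement_invalid_parameters(D, dt, rng):
    with pytest.raises(ConfigurationError):
        draw_displacement(D, dt, rng)


# --------------------------------------------------------------------------
# reflection


@pytest.mark.parametrize(
    "pt,expected",
    [
        ((5.0, 1.0), (5.0, 1.0)),       # inside: unchanged
        ((-0.2, 1.0), (0.2, 1.0)),      # mirror about x = 0
        ((10.3, 2.5), (9.7, 1.5)),      # mirror about x = 10 and y = 2
        ((0.0, 0.0), (0.0, 0.0)),       # boundary is inside
    ],
)
def test_reflection_examples(pt, expected, config):
    x, y = reflect_into_region(*pt, config)
    assert (float(x), float(y)) == pytest.approx(expected)


def _fold_oracle(v: float, length: float) -> float:
    # independent iterative fold used to cross-check the vectorised version
    while v < 0 or v > length:
        if v < 0:
            v = -v
        if v > length:
            v = 2 * length - v
    return v


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    x=st.floats(-50, 60, allow_nan=False),
    y=st.floats(-50, 60, allow_nan=False),
)
def test_reflection_matches_iterative_fold(x, y):
    config = SimulationConfig()
    rx, ry = reflect_into_region(x, y, config)
    assert 0 <= rx <= config.region_length and 0 <= ry <= config.region_width
    assert float(rx) == pytest.approx(_fold_oracle(x, config.region_length), abs=1e-9)
    assert float(ry) == pytest.approx(_fold_oracle(y, config.region_width), abs=1e-9)


# --------------------------------------------------------------------------
# crossing rule

# moves straddling the border of synapse 2 (centred at x = 5, side 0.3)
_OUT = (4.7, 1.0)   # just outside the square
_IN = (5.0, 1.0)    # centre


def test_no_barrier_accepts_every_move(rng):
    cfg = SimulationConfig(p_crossing=1.0)
    n = 1000
    ox, oy = np.full(n, _OUT[0]), np.full(n, _OUT[1])
    nx, ny = np.full(n, _IN[0]), np.full(n, _IN[1])
    ax, ay = apply_crossing_rule(ox, oy, nx, ny, cfg, rng)
    assert np.all(ax == _IN[0])


@pytest.mark.parametrize("mode", ["symmetric", "entry-only", "exit-only"])
def test_closed_barrier_blocks_gated_crossings(mode, rng):
    cfg = SimulationConfig(p_crossing=0.0, barrier_mode=mode)
    n = 200
    ox, oy = np.full(n, _OUT[0]), np.full(n, _OUT[1])
    nx, ny = np.full(n, _IN[0]), np.full(n, _IN[1])
    # entry attempt
    ax, _ = apply_crossing_rule(ox, oy, nx, ny, cfg, rng)
    if mode in ("symmetric", "entry-only"):
        assert np.all(ax == _OUT[0])
    else:
        assert np.all(ax == _IN[0])
    # exit attempt
    ax, _ = apply_crossing_rule(nx, ny, ox, oy, cfg, rng)
    if mode in ("symmetric", "exit-only"):
        assert np.all(ax == _IN[0])
    else:
        assert np.all(ax == _OUT[0])


def test_half_barrier_acceptance_frequency(rng):
    # Monte-Carlo acceptance of membership-changing proposals ~ Bernoulli(0.5)
    cfg = SimulationConfig(p_crossing=0.5, barrier_mode="symmetric")
    n = 100_000
    ox, oy = np.full(n, _OUT[0]), np.full(n, _OUT[1])
    nx, ny = np.full(n, _IN[0]), np.full(n, _IN[1])
    ax, _ = apply_crossing_rule(ox, oy, nx, ny, cfg, rng)
    frac = np.mean(ax == _IN[0])
    se = 0.5 / np.sqrt(n)
    assert abs(frac - 0.5) < 3 * se


def test_non_crossing_moves_never_gated(rng):
    cfg = SimulationConfig(p_crossing=0.0, barrier_mode="symmetric")
    ax, ay = apply_crossing_rule(
        np.array([2.0]), np.array([0.5]), np.array([2.1]), np.array([0.6]), cfg, rng
    )
    assert ax.item() == 2.1 and ay.item() == 0.6


# --------------------------------------------------------------------------
# binding kinetics


def test_free_receptor_outside_synapse_never_binds(rng):
    state = np.full(1000, FREE)
    inside = np.full(1000, FREE)  # outside all synapses
    out = update_binding_state(state, inside, k_on=1e9, k_off=0.0, dt=0.1, rng=rng)
    assert np.all(out == FREE)


def test_binding_probability_is_kon_dt(rng):
    # k_on = 1 /s and dt = 0.1 s -> per-step binding probability 0.1
    n = 100_000
    state = np.full(n, FREE)
    inside = np.full(n, 2)
    out = update_binding_state(state, inside, k_on=1.0, k_off=0.04, dt=0.1, rng=rng)
    frac = np.mean(out == 2)
    se = np.sqrt(0.1 * 0.9 / n)
    assert abs(frac - 0.1) < 3 * se


def test_bound_with_zero_koff_stays_bound(rng):
    state = np.full(100, 3)
    inside = np.full(100, 3)
    for _ in range(200):
        state = update_binding_state(state, inside, 0.0, 0.0, 0.1, rng)
    assert np.all(state == 3)


def test_probability_clamped_at_one(rng):
    # k dt > 1 must behave as probability 1, not raise or overflow
    state = np.full(100, FREE)
    inside = np.full(100, 0)
    out = update_binding_state(state, inside, k_on=100.0, k_off=0.0, dt=0.1, rng=rng)
    assert np.all(out == 0)


def test_negative_rates_rejected(rng):
    with pytest.raises(ConfigurationError):
        update_binding_state(np.array([FREE]), np.array([0]), -1.0, 0.0, 0.1, rng)


def test_two_state_chain_stationary_fraction(rng):
    """Long-run bound fraction matches p_b/(p_b+p_u) of the discrete chain.

    At defaults p_b = 0.1, p_u = 0.004, the stationary bound fraction is
    0.1/0.104 ~ 0.9615. The chain is autocorrelated, so the Monte-Carlo
    standard error uses the effective sample size n (1-rho)/(1+rho) with
    rho = 1 - p_b - p_u.
    """
    n_steps = 100_000
    p_b, p_u = 0.1, 0.004
    state = np.array([FREE])
    inside = np.array([0])
    bound_flags = np.empty(n_steps, dtype=bool)
    for i in range(n_steps):
        state = update_binding_state(state, inside, 1.0, 0.04, 0.1, rng)
        bound_flags[i] = state[0] >= 0
    pi = p_b / (p_b + p_u)
    rho = 1.0 - p_b - p_u
    n_eff = n_steps * (1 - rho) / (1 + rho)
    se = np.sqrt(pi * (1 - pi) / n_eff)
    assert abs(bound_flags.mean() - pi) < 3 * se


def test_bound_dwell_times_are_geometric(rng):
    """Mean bound duration ~ 1/k_off (geometric dwell with parameter k_off dt)."""
    n_steps = 200_000
    state = np.array([FREE])
    inside = np.array([0])
    dwells = []
    current = 0
    for _ in range(n_steps):
        was_bound = state[0] >= 0
        state = update_binding_state(state, inside, 1.0, 0.04, 0.1, rng)
        if state[0] >= 0:
            current += 1
        elif was_bound:
            dwells.append(current)
            current = 0
    dwells = np.array(dwells, dtype=float) * 0.1  # steps -> seconds
    mean_expected = 1.0 / 0.04
    se = mean_expected / np.sqrt(dwells.size)  # exponential-limit SE
    assert dwells.size > 100
    assert abs(dwells.mean() - mean_expected) < 3 * se


# --------------------------------------------------------------------------
# full step and trajectories


def _fresh_ensemble(config, seed=0):
    return ReceptorEnsemble.uniform_random(config, np.random.default_rng(seed))


def test_step_conserves_receptors_and_containment(short_config):
    rng = np.random.default_rng(1)
    ens = _fresh_ensemble(short_config, 1)
    for _ in range(2000):
        ens = step(ens, short_config, k_on=1.0, k_off=0.04, rng=rng)
    ens.check_invariants(short_config)  # raises on violation
    assert ens.n == short_config.n_receptors


def test_step_without_binding_keeps_everyone_free(short_config):
    rng = np.random.default_rng(2)
    ens = _fresh_ensemble(short_config, 2)
    for _ in range(500):
        ens = step(ens, short_config, k_on=0.0, k_off=0.04, rng=rng)
    assert not ens.bound.any()


def test_identical_seeds_give_identical_trajectories(short_config):
    sched = KineticSchedule.constant(1.0, 0.04)
    a, _ = run_simulation(short_config, sched, seed=7)
    b, _ = run_simulation(short_config, sched, seed=7)
    assert np.array_equal(a.total, b.total)
    assert np.array_equal(a.bound, b.bound)
    assert np.array_equal(a.extra, b.extra)


def test_sampled_counts_always_sum_to_population(short_config):
    sched = KineticSchedule.constant(1.0, 0.04)
    ts, _ = run_simulation(short_config, sched, seed=3)
    assert np.all(ts.total.sum(axis=1) + ts.extra == short_config.n_receptors)
    assert np.all(ts.bound <= ts.total)
    assert np.all(ts.total >= 0)


def test_sample_times_span_recorded_axis(short_config):
    sched = KineticSchedule.constant(1.0, 0.04)
    ts, _ = run_simulation(short_config, sched, seed=4)
    assert ts.times[0] == pytest.approx(0.0)
    assert ts.times[-1] == pytest.approx(short_config.t_total_recorded)
    assert np.allclose(np.diff(ts.times), short_config.sample_interval)


def test_schedule_must_cover_burn_in(short_config):
    sched = KineticSchedule((0.0,), (1.0,), (0.04,))  # starts at baseline
    with pytest.raises(ConfigurationError, match="burn-in"):
        run_simulation(short_config, sched, seed=0)


def test_occupancy_grid_covers_region():
    cfg = SimulationConfig(t_burn_in=10.0, t_baseline=10.0, t_post=0.0)
    sched = KineticSchedule.constant(1.0, 0.04)
    _, grid = run_simulation(
        cfg, sched, seed=5, record_occupancy=True, occupancy_bin_size=0.5
    )
    assert grid.shape == (20, 4)
    assert np.all(grid.matrix >= 0)
    # per-step accumulation of the whole population: entries sum to n
    assert grid.matrix.sum() == pytest.approx(cfg.n_receptors)


def test_free_diffusion_density_is_uniform():
    """Null model: no binding, no barrier, homogeneous D -> uniform density.

    Pools >= 10^4 receptor positions from snapshots spaced 100 s apart
    (several diffusion lengths, so samples are decorrelated) and applies a
    chi-square goodness-of-fit test on a 20 x 4 grid at alpha = 0.001.
    """
    from scipy import stats

    cfg = SimulationConfig(p_crossing=1.0, D_in=0.1)
    rng = np.random.default_rng(0)
    ens = ReceptorEnsemble.uniform_random(cfg, rng)
    counts = np.zeros((20, 4))
    n_snapshots = 10
    for _ in range(n_snapshots):
        for _ in range(1000):  # 100 s between snapshots
            ens = step(ens, cfg, k_on=0.0, k_off=0.04, rng=rng)
        ix = np.minimum((ens.x / 0.5).astype(int), 19)
        iy = np.minimum((ens.y / 0.5).astype(int), 3)
        np.add.at(counts, (ix, iy), 1)
    total = counts.sum()
    assert total == n_snapshots * cfg.n_receptors
    stat, pval = stats.chisquare(counts.ravel())
    assert pval > 0.001
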