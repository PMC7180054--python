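"""Quantitative readouts: steady-state theory, plateaus, k_on sweep.

The mean-field steady state of the diffusion-trapping model has a closed
form: the synaptic/extra-synaptic density enrichment is

    E = P_crossing · (D_out / D_in) · (1 + k_on / k_off)

and, because the receptor population is closed, the absolute per-synapse
count follows from conservation: with extra-synaptic density rho the region
holds rho·A_out + E·rho·A_syn receptors. These closed forms are the
analytic oracle the stochastic simulation is compared against; the
discrete-step dynamics need not reproduce them exactly (finite step length
relative to the synapse size biases the boundary layer), and both values
are always reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ConfigurationError, SimulationConfig
from .protocols import ProtocolSpec, ReplicateSet, run_replicates

__all__ = [
    "PlateauResult",
    "SweepResult",
    "ExperimentalAnchors",
    "EXPERIMENTAL_ANCHORS",
    "enrichment_ratio_closed_form",
    "predicted_basal_count",
    "window_mean",
    "percent_of_baseline",
    "plateau_level",
    "fold_change_basal",
    "plateau_result",
    "sweep_kon",
    "map_epsc_to_receptor_count",
]


# --------------------------------------------------------------------------
# closed-form steady state


def enrichment_ratio_closed_form(
    p_crossing: float, D_out: float, D_in: float, k_on: float, k_off: float
) -> float:
    """Mean-field synaptic/extra-synaptic density ratio at steady state.

    Returns ``p_crossing * (D_out/D_in) * (1 + k_on/k_off)``; ``inf`` when
    binding is irreversible (k_off = 0 with k_on > 0).
    """
    if D_in <= 0:
        raise ConfigurationError("D_in must be positive")
    if k_on < 0 or k_off < 0:
        raise ConfigurationError("kinetic rates must be >= 0")
    if k_on == 0:
        occupancy = 1.0
    elif k_off == 0:
        return float("inf")
    else:
        occupancy = 1.0 + k_on / k_off
    return p_crossing * (D_out / D_in) * occupancy


def predicted_basal_count(config: SimulationConfig, ratio: float) -> float:
    """Per-synapse receptor count implied by an enrichment ratio.

    Solves the conservation budget n = rho·A_out + ratio·rho·A_syn for the
    extra-synaptic density rho and returns ratio·rho·side² receptors per
    synapse. With an infinite ratio every receptor is synaptic and the
    count saturates at n / n_synapses.
    """
    if ratio < 0:
        raise ConfigurationError("enrichment ratio must be >= 0")
    a_syn = config.synaptic_area
    a_out = config.region_area - a_syn
    if config.region_area <= 0 or config.n_synapses == 0:
        raise ConfigurationError("degenerate geometry")
    if np.isinf(ratio):
        return config.n_receptors / config.n_synapses
    rho = config.n_receptors / (a_out + ratio * a_syn)
    return ratio * rho * (a_syn / config.n_synapses)


# --------------------------------------------------------------------------
# time-series readouts


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi < lo:
        raise ConfigurationError("window end precedes its start")
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ConfigurationError(f"window {window} contains no samples")
    return mask


def window_mean(
    times: np.ndarray, values: np.ndarray, window: tuple[float, float]
) -> float:
    """Mean of ``values`` over the closed time window [lo, hi]."""
    return float(np.mean(np.asarray(values)[_window_mask(np.asarray(times), window)]))


def percent_of_baseline(
    times: np.ndarray, values: np.ndarray, baseline_window: tuple[float, float]
) -> np.ndarray:
    """Series rescaled so its baseline-window mean is 100 (%)."""
    base = window_mean(times, values, baseline_window)
    if base == 0:
        raise ConfigurationError("baseline mean is zero; normalisation undefined")
    return 100.0 * np.asarray(values, dtype=float) / base


def plateau_level(
    times: np.ndarray,
    normalized: np.ndarray,
    plateau_window: tuple[float, float],
) -> float:
    """Mean of a %-of-baseline series over the plateau window."""
    return window_mean(times, normalized, plateau_window)


def fold_change_basal(count_a: float, count_b: float) -> float:
    """count_b / count_a, e.g. phosphorylated vs control basal content."""
    if count_a <= 0:
        raise ConfigurationError("reference count must be positive")
    return count_b / count_a


@dataclass(frozen=True)
class PlateauResult:
    """Baseline and plateau of a replicate-mean synaptic count series."""

    baseline_mean: float
    plateau_mean: float
    plateau_percent: float
    baseline_window: tuple[float, float]
    plateau_window: tuple[float, float]


def plateau_result(
    reps: ReplicateSet,
    baseline_window: Optional[tuple[float, float]] = None,
    plateau_window: Optional[tuple[float, float]] = None,
) -> PlateauResult:
    """Quantify one ReplicateSet: baseline mean, plateau mean, plateau %.

    Normalisation is applied to the replicate-mean series (the averaged
    solid curves), not per replicate. Default windows: the configured
    baseline, and the final five minutes of the recording. To mirror the
    electrophysiological quantification window instead, pass
    ``plateau_window=(t_ind + 360, t_ind + 600)`` (6-10 min after
    induction).
    """
    if baseline_window is None:
        baseline_window = reps.baseline_window()
    if plateau_window is None:
        plateau_window = reps.plateau_window()
    baseline_mean = window_mean(reps.times, reps.mean_count, baseline_window)
    plateau_mean = window_mean(reps.times, reps.mean_count, plateau_window)
    normalized = percent_of_baseline(reps.times, reps.mean_count, baseline_window)
    return PlateauResult(
        baseline_mean=baseline_mean,
        plateau_mean=plateau_mean,
        plateau_percent=plateau_level(reps.times, normalized, plateau_window),
        baseline_window=baseline_window,
        plateau_window=plateau_window,
    )


# --------------------------------------------------------------------------
# k_on sweep: basal content vs LTP responsiveness


@dataclass(frozen=True)
class SweepResult:
    """(k_on, basal count, LTP plateau %) triples across a k_on grid."""

    k_on_values: tuple[float, ...]
    basal_counts: tuple[float, ...]
    plateau_percents: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.k_on_values)
        if len(self.basal_counts) != n or len(self.plateau_percents) != n:
            raise ConfigurationError("sweep columns must align")
        if any(
            b <= a for a, b in zip(self.k_on_values, self.k_on_values[1:])
        ):
            raise ConfigurationError("k_on_values must be strictly increasing")


def default_kon_grid(n: int = 20) -> np.ndarray:
    """Logarithmic k_on grid over 0.075-10 s⁻¹ (the full sweep range)."""
    return np.geomspace(0.075, 10.0, n)


def sweep_kon(
    config: SimulationConfig,
    k_on_values: Sequence[float],
    n_replicates: int = 10,
    base_seed: int = 0,
    k_off_base: float = 0.04,
    k_off_potentiated: float = 0.004,
) -> SweepResult:
    """Trace basal synaptic content vs LTP plateau across binding rates.

    For each k_on the full LTP protocol (k_off step down at induction) is
    run; the basal count is the baseline-window mean and the plateau the
    %-of-baseline level over the final window. Higher k_on fills synapses
    at rest but depletes the extra-synaptic reservoir, so basal content
    rises while relative LTP falls — the model's occlusion prediction.
    """
    k_on_values = [float(k) for k in k_on_values]
    if any(k <= 0 for k in k_on_values):
        raise ConfigurationError("k_on values must be positive")
    if any(a <= b for b, a in zip(k_on_values, k_on_values[1:])):
        raise ConfigurationError("k_on values must be strictly increasing")
    basal, plateau = [], []
    for i, k_on in enumerate(k_on_values):
        spec = ProtocolSpec(
            name="ltp",
            k_on_base=k_on,
            k_off_base=k_off_base,
            k_off_potentiated=k_off_potentiated,
        )
        reps = run_replicates(
            config, spec, n_replicates=n_replicates,
            base_seed=base_seed + 1000 * i,
        )
        res = plateau_result(reps)
        basal.append(res.baseline_mean)
        plateau.append(res.plateau_percent)
    return SweepResult(
        k_on_values=tuple(k_on_values),
        basal_counts=tuple(basal),
        plateau_percents=tuple(plateau),
    )


# --------------------------------------------------------------------------
# experimental anchors (overlay only)


@dataclass(frozen=True)
class ExperimentalAnchors:
    """Published anchor values used to overlay experiments on simulations.

    The only numeric anchor is the control synapse content (33 receptors)
    to which basal AMPAR-mediated EPSC amplitudes are normalised; the
    condition labels identify the experimental groups plotted against the
    sweep curve. These are for overlays only and never enter simulator
    correctness checks.
    """

    control_receptor_count: float = 33.0
    condition_labels: tuple[str, ...] = (
        "control",
        "optoFGFR1 + light",
        "Nlgn1-WT rescue",
        "Nlgn1-Y782A rescue",
    )


EXPERIMENTAL_ANCHORS = ExperimentalAnchors()


def map_epsc_to_receptor_count(
    epsc_percent_of_control: float,
    anchors: ExperimentalAnchors = EXPERIMENTAL_ANCHORS,
) -> float:
    """Linear EPSC → receptor-count map anchored at 100% = 33 receptors."""
    if epsc_percent_of_control < 0:
        raise ConfigurationError("EPSC percentage must be >= 0")
    return epsc_percent_of_control / 100.0 * anchors.control_receptor_count
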