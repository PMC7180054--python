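"""Configuration files, result serialisation and run manifests.

Configs are YAML or JSON mappings with two optional sections::

    simulation:        # SimulationConfig fields (µm, s, µm²/s)
      dt: 0.1
      n_receptors: 1000
    protocol:          # ProtocolSpec fields (rates in 1/s)
      name: ltp
      k_off_potentiated: 0.004

Omitted keys fall back to the reference defaults, so an empty file is a
valid full configuration. Unknown keys are rejected by name. Outputs are
plain CSV/JSON so that runs can be diffed and re-hashed; a RunManifest
records the config snapshot, seeds and content hashes needed to reproduce
a run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import PlateauResult, SweepResult
from .config import ConfigurationError, SimulationConfig, SynapseRegion
from .core import OccupancyGrid
from .protocols import ProtocolSpec, ReplicateSet

__all__ = [
    "RunManifest",
    "load_config",
    "write_outputs",
    "replicate_counts_frame",
    "replicate_summary_frame",
    "write_occupancy_grid",
    "read_occupancy_grid",
]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_PROTO_FIELDS = {f.name for f in dataclasses.fields(ProtocolSpec)}


def _build_simulation(raw: dict[str, Any]) -> SimulationConfig:
    unknown = set(raw) - _SIM_FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown simulation key(s): {', '.join(sorted(unknown))}"
        )
    if "synapses" in raw:
        raw = dict(raw)
        raw["synapses"] = tuple(
            SynapseRegion(**syn) for syn in raw["synapses"]
        )
    return SimulationConfig(**raw)


def _build_protocol(raw: dict[str, Any]) -> ProtocolSpec:
    unknown = set(raw) - _PROTO_FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown protocol key(s): {', '.join(sorted(unknown))}"
        )
    name = raw.get("name", "basal")
    return ProtocolSpec.from_name(name, **{k: v for k, v in raw.items() if k != "name"})


def load_config(path: str | Path) -> tuple[SimulationConfig, ProtocolSpec]:
    """Parse a YAML/JSON config file into validated parameter records.

    An empty file (or one with missing sections) yields the full reference
    default configuration and the basal protocol. Errors name the
    offending key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"simulation", "protocol"}
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown section(s): {', '.join(sorted(unknown))}"
        )
    config = _build_simulation(raw.get("simulation") or {})
    spec = _build_protocol(raw.get("protocol") or {})
    return config, spec


# --------------------------------------------------------------------------
# tabular output


def replicate_counts_frame(reps: ReplicateSet) -> pd.DataFrame:
    """Long-format per-synapse counts: time_s, replicate, synapse_id, n_bound, n_total.

    The extra-synaptic pool appears as synapse_id = "extra" (its n_bound is
    0 by construction; receptors only bind inside synapses).
    """
    rows = []
    for m in reps.members:
        n_t, n_s = m.total.shape
        for j in range(n_s):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": m.times,
                        "replicate": m.replicate_id,
                        "synapse_id": str(reps.config.synapses[j].id),
                        "n_bound": m.bound[:, j],
                        "n_total": m.total[:, j],
                    }
                )
            )
        rows.append(
            pd.DataFrame(
                {
                    "time_s": m.times,
                    "replicate": m.replicate_id,
                    "synapse_id": "extra",
                    "n_bound": 0,
                    "n_total": m.extra,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def replicate_summary_frame(reps: ReplicateSet) -> pd.DataFrame:
    """Cross-replicate summary: time_s, mean_count, sem_count."""
    return pd.DataFrame(
        {
            "time_s": reps.times,
            "mean_count": reps.mean_count,
            "sem_count": reps.sem_count,
        }
    )


def write_occupancy_grid(grid: OccupancyGrid, path: str | Path) -> None:
    """Plain-text matrix with a one-line header (bin size and window)."""
    header = (
        f"bin_size_um={grid.bin_size} "
        f"window_s={grid.window[0]},{grid.window[1]}"
    )
    np.savetxt(path, grid.matrix, header=header)


def read_occupancy_grid(path: str | Path) -> OccupancyGrid:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=") for item in header.split())
    lo, hi = (float(v) for v in fields["window_s"].split(","))
    return OccupancyGrid(
        bin_size=float(fields["bin_size_um"]),
        matrix=np.loadtxt(path),
        window=(lo, hi),
    )


# --------------------------------------------------------------------------
# manifests


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: SimulationConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["synapses"] = [dataclasses.asdict(s) for s in config.synapses]
    return d


@dataclass
class RunManifest:
    """Everything needed to re-run a result and verify it byte for byte."""

    config: dict[str, Any]
    protocol: dict[str, Any]
    base_seed: int
    seeds: list[int]
    version: str
    outputs: dict[str, str]  # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_outputs(
    reps: ReplicateSet,
    out_dir: str | Path,
    plateau: Optional[PlateauResult] = None,
    sweep: Optional[SweepResult] = None,
    occupancy: Optional[OccupancyGrid] = None,
) -> RunManifest:
    """Write count/summary CSVs (plus optional analyses) and a manifest.

    Floats are serialised with full repr precision and replicates are
    written in index order, so identical runs produce identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    counts = out / "counts.csv"
    replicate_counts_frame(reps).to_csv(counts, index=False)
    written["counts.csv"] = _sha256(counts)

    summary = out / "summary.csv"
    replicate_summary_frame(reps).to_csv(summary, index=False)
    written["summary.csv"] = _sha256(summary)

    if plateau is not None:
        pl = out / "plateau.csv"
        pd.DataFrame(
            [
                {
                    "condition": reps.spec.name,
                    "baseline_mean": plateau.baseline_mean,
                    "plateau_mean": plateau.plateau_mean,
                    "plateau_percent": plateau.plateau_percent,
                }
            ]
        ).to_csv(pl, index=False)
        written["plateau.csv"] = _sha256(pl)

    if sweep is not None:
        sw = out / "sweep.csv"
        pd.DataFrame(
            {
                "k_on": sweep.k_on_values,
                "basal_count": sweep.basal_counts,
                "plateau_percent": sweep.plateau_percents,
            }
        ).to_csv(sw, index=False)
        written["sweep.csv"] = _sha256(sw)

    if occupancy is not None:
        oc = out / "occupancy.txt"
        write_occupancy_grid(occupancy, oc)
        written["occupancy.txt"] = _sha256(oc)

    for name in written:
        frame = pd.read_csv(out / name) if name.endswith(".csv") else None
        if frame is not None and not np.all(np.isfinite(frame.select_dtypes("number").fillna(0.0))):
            raise ConfigurationError(f"{name}: non-finite values in output")

    manifest = RunManifest(
        config=_config_snapshot(reps.config),
        protocol=dataclasses.asdict(reps.spec),
        base_seed=reps.base_seed,
        seeds=[reps.base_seed + r for r in range(reps.n_replicates)],
        version=__version__,
        outputs=written,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
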