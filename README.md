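# synaptrap

Particle-based Monte-Carlo simulation of AMPA-receptor (AMPAR) lateral
diffusion and reversible trapping at postsynaptic densities (PSDs), for
quantitative interpretation of synaptic potentiation experiments.

Synapses hold their receptors not by permanent anchoring but by a dynamic
equilibrium: receptors diffuse laterally in the membrane, are slowed and
reversibly bound by scaffold proteins inside the PSD, and exchange
continuously with the extra-synaptic pool. `synaptrap` models a dendritic
segment as a closed 2 µm × 10 µm membrane rectangle with five 0.3 µm PSD
squares and 1000 diffusing receptors. Free receptors perform Brownian
motion (D_out = 0.1, D_in = 0.05 µm²/s), cross the synapse border against
a probabilistic barrier (P_crossing = 0.5), bind the scaffold at rate
k_on = 1 s⁻¹ while inside, unbind at k_off = 0.04 s⁻¹, and move with
D_trap = 0.006 µm²/s while bound. At steady state the mean-field
synaptic/extra-synaptic density enrichment is

    E = P_crossing · (D_out / D_in) · (1 + k_on / k_off)

and conservation of the closed 1000-receptor pool converts E into absolute
per-synapse counts. Long-term potentiation (LTP) is modelled as a step
drop of k_off at induction (stronger trapping); elevated neuroligin-1
tyrosine phosphorylation as a higher k_on from the start (more trapping
slots). Because the receptor pool is closed, a high basal k_on fills
synapses at rest, depletes the extra-synaptic reservoir, and occludes
subsequent LTP — the central prediction the package quantifies.

The package is aimed at computational neuroscientists and experimentalists
who want to interpret receptor-count or EPSC time courses through a
diffusion-trapping lens: it provides the stochastic engine, the experiment
protocols, replicate management, and the analysis readouts (baseline
content, percent-of-baseline plateaus, k_on sweeps, EPSC↔count mapping).

## Worked example

```bash
synaptrap reproduce-paper --replicates 3 --seed 0
```

```
  condition  basal_count  closed_form_basal  plateau_percent
      basal         59.9               74.9             99.0
        ltp         58.5               74.9            275.1
phospho_ltp        109.8              127.3            168.6
     ko_ltp         58.6               74.9            227.3
```

Reading the table: at the reference parameters each synapse holds ~59
receptors at rest (the mean-field closed form predicts 74.9; the gap is a
known discrete-step boundary effect analysed in `docs/methods.md`), and
without induction the count stays at ~100% of baseline. Dropping k_off
from 0.04 to 0.004 s⁻¹ at induction (`ltp`) raises synaptic content to
~275% of baseline; the same induction on top of a tripled k_on
(`phospho_ltp`) starts from a doubled basal pool (~110) and reaches only
~169% — partial occlusion of LTP by prior receptor recruitment. The
attenuated drop to 0.008 s⁻¹ (`ko_ltp`) gives an intermediate plateau.

The same machinery is available as a library:

```python
from synaptrap import (SimulationConfig, ProtocolSpec, run_replicates,
                       plateau_result)

config = SimulationConfig()                       # reference parameters
spec = ProtocolSpec.from_name("ltp")              # k_off 0.04 -> 0.004 s⁻¹
reps = run_replicates(config, spec, n_replicates=10, base_seed=1)
print(plateau_result(reps).plateau_percent)       # ~270 (% of baseline)
```

Other entry points: `synaptrap simulate` (one protocol, CSV output plus a
reproducibility manifest), `synaptrap sweep` (basal content vs LTP plateau
across a k_on grid), `synaptrap analyze` (plateau readouts from a summary
CSV). Configuration files are YAML/JSON with `simulation:` and
`protocol:` sections; an empty file means the full reference defaults.

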