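# Methods

## Model

`synaptrap` simulates lateral diffusion and reversible scaffold trapping of
AMPA-type glutamate receptors (AMPARs) on a patch of dendritic membrane.
The domain is a closed 2 µm × 10 µm rectangle carrying five immobile
0.3 µm × 0.3 µm squares — postsynaptic densities (PSDs) — on its mid-line
at x = 1, 3, 5, 7, 9 µm (0.5 synapse/µm linear density). A fixed population
of 1000 receptors moves by 2D Brownian motion; there is no exchange with
intracellular pools (no exocytosis/endocytosis), so synaptic enrichment can
only come from redistribution of the surface pool.

Each receptor is either FREE or BOUND to the scaffold of one synapse. One
time step Δt advances the ensemble through a fixed cycle:

1. **Kinetics.** A free receptor inside a synapse binds with probability
   min(k_on·Δt, 1); a bound receptor releases with probability
   min(k_off·Δt, 1). Rates are linear per-step probabilities, not
   exponentiated. Kinetics run first, so binding depends on the position at
   the start of the step.
2. **Displacement.** Independent Gaussian increments with per-axis standard
   deviation √(2DΔt), with D selected by state: D_out for free receptors
   outside synapses, D_in (slower; steric hindrance in the cleft) for free
   receptors inside, D_trap for bound receptors (confined motion in the
   PSD).
3. **Region reflection.** Mirror reflection at the rectangle contour,
   applied repeatedly if a step overshoots; the system is closed.
4. **Border rule.** A free receptor whose move changes synapse membership
   is subject to the crossing barrier (below); on rejection it keeps its
   previous position for this step. A bound receptor whose move would leave
   its synapse square is held in place (PSD confinement; mirror reflection
   at the square edges is available as `bound_edge="reflect"`).

All stochastic decisions of a replicate come from one seeded NumPy
generator, drawn in a fixed order (kinetics uniforms, displacement normals,
crossing uniforms), so a trajectory is bit-reproducible from
(config, schedule, seed); replicate r of a set uses seed base_seed + r.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| region | 10 × 2 | µm | dendritic segment |
| synapse side | 0.3 | µm | PSD square (~0.09 µm²) |
| n_receptors | 1000 | — | closed surface pool |
| dt | 0.1 | s | time step |
| D_out | 0.1 | µm²/s | free, extra-synaptic |
| D_in | 0.05 | µm²/s | free, synaptic |
| D_trap | 0.006 | µm²/s | scaffold-bound |
| p_crossing | 0.5 | — | border-crossing acceptance |
| k_on | 1 | s⁻¹ | scaffold binding rate |
| k_off | 0.04 | s⁻¹ | scaffold unbinding rate |
| t_burn_in | 300 | s | unrecorded equilibration |
| t_baseline / t_post | 300 / 1800 | s | recorded 5 + 30 min |
| sample_interval | 10 | s | count sampling cadence |

Diffusion coefficients and kinetic rates are the single-particle-tracking /
FRAP-derived values the model was built around. The burn-in (300 s) is an
order of magnitude longer than the slowest basal relaxation time
1/k_off = 25 s, so the recorded baseline is a steady state; receptors start
uniformly distributed over the whole rectangle (synapse interiors
included), all free.

## Barrier direction

The steady-state mean-field enrichment of synaptic over extra-synaptic
receptor density is

    E = P_crossing · (D_out / D_in) · (1 + k_on / k_off)

which evaluates to 26 at the defaults. For P_crossing to scale the
stationary density like this, the barrier must act on one direction of
crossing only: an accept/reject rule applied symmetrically to entries and
exits satisfies detailed balance, slows the exchange kinetics, and leaves
the stationary density ratio exactly unchanged — it makes P_crossing inert
at steady state. `barrier_mode` therefore defaults to `"entry-only"`
(moves into a synapse are accepted with probability p_crossing, exits are
free), which realises the formula's P_crossing factor; `"symmetric"` and
`"exit-only"` remain available for sensitivity analysis. Measured at the
defaults, the entry-only barrier also reproduces the model's reference
plateau behaviour (~270% control LTP plateau, ~1.9-fold basal effect of
tripling k_on), while the symmetric variant does not (~198%, 1.6-fold).

## Closed form vs simulation: the basal-content gap

Conservation turns E into an absolute prediction: with extra-synaptic
density ρ, n = ρ·A_out + E·ρ·A_syn, giving E = 26 → ≈ 74.9 receptors per
synapse at the defaults. The stochastic simulation instead equilibrates at
≈ 59 (10 replicates, SEM < 1%). The gap is a discrete-step boundary-layer
effect, not a defect: the per-step displacement (σ_out ≈ 0.14 µm,
σ_in ≈ 0.10 µm) is comparable to the 0.3 µm synapse, and a random walk
whose step length changes discontinuously at an interface establishes a
free-density ratio near √(D_out/D_in) rather than the continuum D_out/D_in.
Replacing that factor reproduces the measured count
(0.5·√2·26 ≈ 18.4 → ≈ 59). Where the mean-field algebra applies exactly —
fully permeable border, homogeneous free diffusion (p_crossing = 1,
D_in = D_out) — simulation and closed form agree to within replicate error
(74.9 ± 0.2 vs 74.88), which is enforced as a test. Both the simulated and
closed-form basal values are always reported side by side. Note that earlier reports of this model give
about 30 receptors per synapse at basal state; neither the closed form
(75) nor the faithful discrete dynamics (59) reproduce that figure, and no
parameter was adjusted to chase it. Relative readouts (plateau %, fold changes) are less sensitive to this
absolute offset than raw counts, but not immune: the elevated basal pool
at k_on = 3 s⁻¹ (≈ 110 vs a reported ≈ 60) depletes the extra-synaptic
reservoir further and lowers the phosphorylation-condition plateau
(≈ 168% vs a reported ≈ 190%).

## Protocols

All protocols share the burn-in + 5 min baseline + 30 min post recording;
induction, where present, is the kinetic step at the end of the baseline
(t = 300 s on the recorded axis; schedules are right-continuous).

- `basal`: k_on = 1 s⁻¹, k_off = 0.04 s⁻¹ throughout.
- `ltp` (control LTP): k_off steps 0.04 → 0.004 s⁻¹; models the higher
  TARP/PSD-95 affinity after induction.
- `phospho_basal` / `phospho_ltp`: k_on = 3 s⁻¹ from the start (the
  neuroligin-1 phosphorylation condition: more trapping slots), with the
  same k_off drop in the LTP variant.
- `ko_ltp`: k_on = 1 s⁻¹, k_off 0.04 → 0.008 s⁻¹ (attenuated potentiation
  in the knockout background).
- `kon_step_ltp`: k_on steps 1 → 10 s⁻¹ at induction with k_off constant.
  10 s⁻¹ is chosen so the post-induction k_on/k_off (10/0.04 = 250) equals
  the k_off-drop protocol's (1/0.004), i.e. the two protocols share an
  equilibrium plateau and differ only in kinetics. The variant reaches its
  half-plateau within ~20 s versus ~50 s (sampled at 10 s) — the
  minute-scale rise that argues against an on-rate mechanism for this LTP
  protocol.

Ten replicates per condition; the per-run count is the mean over the five
synapses, and the cross-replicate SEM uses denominator √n_replicates.
Percent-of-baseline normalisation is applied to the replicate-mean series
(a per-replicate option exists). The plateau window defaults to the final
5 min of the recording — the system has relaxed for ≥ 6×1/k_off' by then —
with the 6–10 min post-induction window (the electrophysiological
quantification window) available as an option.

## k_on sweep

`sweep_kon` traces the basal-content / plateau trade-off by running the
full LTP protocol across a logarithmic k_on grid (default 20 points over
0.075–10 s⁻¹). Basal content increases monotonically in k_on while the
relative plateau decreases — synapses that start full have little reserve
to recruit, the occlusion effect. The EPSC overlay maps experimental
amplitudes linearly onto receptor counts via the 33-receptors-at-100%
control anchor; anchors are plotting aids only and enter no correctness
test.

## Numerical choices and degenerate inputs

- Per-step event probabilities are clamped at min(k·Δt, 1); schedules with
  k·Δt > 1 are therefore valid saturating inputs, not errors.
- Synapse membership uses closed squares (border points count as inside);
  synapses may not overlap, so membership is unique.
- k_off = 0 with k_on > 0 yields an infinite enrichment flag (and a
  predicted count equal to the capacity n/n_synapses), not a crash.
- Counts are exact integers at every sample and must partition the
  population; this is asserted, not assumed.
- Cross-replicate reductions accumulate in replicate-index order, so
  summary floats are bit-stable.

## Test and script problem sizes

The packaged checks run the study conditions at full scale — 1000
receptors, 24 000 steps per replicate, 10 replicates per condition — for
the basal, control-LTP and phosphorylation-LTP conditions; the sweep
property uses a reduced grid (6 k_on values × 3 replicates) and the
rise-time comparison 3 replicates per protocol, sizes at which every
asserted ordering is far outside replicate noise. Statistical assertions
use 3-standard-error bands (with autocorrelation-corrected effective
sample sizes for chain occupancy) and α = 0.001 for the uniformity
goodness-of-fit null.

## What the generator does and does not emulate

The simulator is the data source: it realises exactly the statistical
structure the analysis assumes — region-dependent Brownian motion, a
probabilistic entry barrier, first-order binding to non-saturable
scaffolds, a closed receptor budget. It does not emulate vesicular
recycling or receptor turnover, saturable binding slots, spine geometry or
3D curvature, interactions between receptors (no crowding), photophysics,
or measurement noise of any imaging modality. Passing tests therefore
validate the trapping model's internal logic and its stated steady-state
theory, not the fidelity of any of those omitted processes to real
synapses; absolute receptor counts in particular inherit the
step-discretisation bias discussed above, and conclusions should lean on
the relative, cross-condition readouts.
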