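# Methods

This note documents the modeling assumptions, parameter conventions,
numerical choices and known limitations of `thermotx`. It describes what the
code computes; every empirical number it mentions is produced by the test
suite or `scripts/acceptance.py` at run time.

## Model structure and assumptions

The model is an equilibrium-binding, steady-state-initiation map from
(sequence, factor concentrations at one spatial position) to a transcription
rate. Its assumptions, in order of application:

* **Binding equilibrium.** TF–DNA binding equilibrates fast relative to
  changes in gene expression, so site occupancies are thermodynamic averages.
  PWM score is proportional to binding free energy; the per-factor constant
  `λ` converts score deficit to energy, giving relative affinity
  `K = exp(λ(S − S_max))` with `K = 1` for the consensus.
* **Exact configuration statistics.** Steric exclusion (overlapping
  footprints cannot be co-occupied) and pairwise cooperativity (a
  multiplicative weight `ω` when both partners are bound) are handled by
  exact enumeration of conflict-free configurations, not by approximation.
  Because weights factorize over connected components of the
  overlap+cooperativity graph, enumeration runs per group; this is
  mathematically identical to a single global enumeration (the suite checks
  agreement to 1e-12 against a brute-force oracle on random ≤12-site
  constructs). Groups larger than 20 sites raise an error rather than
  silently approximating; the cap is configurable.
* **Cooperativity assignment.** Only one factor (Bcd by default) binds
  cooperatively, and only in pairs: the strongest unpaired site pairs with
  the strongest remaining site within 60 bp (center-to-center), repeating
  until no assignable pair remains. Ties in affinity break toward the
  smaller start coordinate so the assignment is deterministic. The pairing
  depends only on score order, so it is computed once per site set, not per
  parameter evaluation.
* **Functional conversion.** A coactivation-target repressor (Hb) bound near
  bound coactivators (Bcd, Cad) acts as an activator with converted fraction
  `C = 1 − Π_j (1 − β_co f_j R(d))`. The complement-product form was chosen
  because it saturates, keeps `C ∈ [0,1]`, reduces to the single-coactivator
  case, and preserves `f_act + f_quench = f_phys` exactly — the constraint
  the decomposition is built around.
* **Short-range repression.** Quenchers attenuate activator-acting
  occupancies within ~150 bp and, when bound near the TSS, attenuate the
  summed activation itself (direct repression). Both use survival-factor
  products, so multiple repressors compound multiplicatively and a repressor
  beyond the range function's zero point has exactly no influence.
* **Initiation.** Activators recruit a single composite adapter species
  (uniformly expressed, so no spatial dependence of its own); recruitment
  contributions add, `E = Σ α_i f_i`. The rate law
  `R = R_max K/(1+K)`, `K = exp(E − θ)`, is the steady state of a
  three-state chain (no polymerase / stalled / initiating) in which the
  Arrhenius term sits in the barrier-crossing rate; the shipped mapping
  `k2 = K·k3(k1+k_-1)/(k1+k3)` makes the identity exact for any kinetic
  constants, and both routes are exposed (`transcription_rate`,
  `rate_from_markov`) with their agreement under test. The two asymptotics —
  exponential in `E` below the barrier, saturation at `R_max` above it — are
  what the data constrain; the constant mapping is configurable.

## Parameters

Energies are dimensionless (RT = 1); `θ` and the `α` absorb units.
Concentrations are relative fluorescence units times a per-factor free scale
`D`, so only products `D·v` matter.

| parameter | meaning | default | bounds |
|---|---|---|---|
| `D_tf` | concentration scale (1/fluorescence) | 1 | [1e-3, 1e3], log |
| `lambda_tf` | score→energy constant | 1 | [0.05, 5] |
| `threshold_tf` | min site score | 0 | [−2, 8]; fixed for Bcd, Hb |
| `alpha_tf` | adapter recruiting strength (activators) | 1 | [0, 50] |
| `beta_q_tf`, `beta_d_tf` | quench / direct-repression efficiency | 0.5 | [0, 1] |
| `omega_bcd` | cooperativity weight | 2 | [1, 100] |
| `coact_eff_co`, `coact_range_co` | coactivation efficiency / plateau (bp) | 0.5 / mid | eff [0,1]; range Bcd [150,200], Cad [10,200] |
| `alpha_coact_hb` | recruiting strength of coactivated target | 1 | [0, 50] |
| `theta` | activation barrier | 3 | [0, 20] |
| `R_max` | diffusion-limited ceiling | 255 | fixed by default |
| `pos_scale_c` | position-effect scale | 1 | free only for non-targeted constructs |

Under the default nine-factor roster this yields 49 free parameters
(10 position-effect/threshold + 4×3 activator + 5×4 repressor + ω + 2×2
coactivation + coactivated-target α + θ). The coactivation range carries one
free parameter (the plateau `r`); the falloff to zero is a fixed 20 bp
offset. The quench range function defaults to a trapezoid with plateau
100 bp and zero at 150 bp; both ends are configurable since only the total
reach is well constrained experimentally.

Distances are center-to-center of match intervals everywhere (cooperativity,
coactivation, quenching, TSS distance), one convention for all mechanisms.
Steric footprints are the match interval widened symmetrically to the
factor's physical size (14 bp minimum, 24 bp for Gt) and clipped at
construct boundaries; centering was chosen over 5′-anchoring as the less
biased default. PWM construction adds a pseudocount of 1 per cell before
normalization; windows containing non-ACGT characters score −∞ and are never
sites. Background base frequencies default to uniform 0.25 and are
configurable.

## Fitting

The objective is the summed squared residual over all (construct, position)
pairs; quality is reported as rms. Three seeded, budgeted backends share one
interface: a Lam-style adaptive annealer (temperature decrement controlled
online by running energy statistics, move sizes adapted toward a 0.44
acceptance ratio), plain Metropolis annealing with geometric cooling, and
multistart L-BFGS-B (10 starts by default). Scale-type parameters (`D`,
`R_max`) are searched in log space; efficiencies linearly. Stopping is by
evaluation budget, not wall clock, so runs are exactly reproducible from
(seed, budget, optimizer). Freed PWM thresholds change the site set, so the
evaluator caches the derived structure (sites, groups, configuration tables,
distance matrices) keyed by the threshold vector and rebuilds only when it
changes; all other parameters reuse the cached structure, which is what
makes 1e5-evaluation annealing runs practical.

The annealers' move sets (single-coordinate Gaussian steps with adaptive
widths) are a pragmatic default, documented here rather than claimed as
canonical; the multistart backend is the reference for the recovery
benchmark because its convergence is not schedule-dependent.

## Synthetic data

The generator emulates the *structure* of quantitative blastoderm training
data, not its biology: a 58-point grid over 35–92% egg length; an anterior
exponential gradient (Bcd-like), a posterior sigmoid (Cad-like), an anterior
step plus posterior bump (Hb-like), four bell-shaped gap-like domains and
two broad weak activators; constructs assembled from two planted "elements"
(a stripe-2-like element with a cooperative activator pair and quenchers,
including one near the TSS, and a stripe-3-like element with coactivation
targets and their repressors) alone, fused in both orders, and separated by
a 172 bp spacer — so spacer removal moves coactivator–target distances
across the coactivation range exactly as the fusion design does. Observed
expression is the forward model times `(1 + ε)`, `ε ~ N(0, 0.075²)`, clipped
at zero — inside the 5–10% accuracy band of the data class being emulated.
Toy motifs are 10-mers engineered so that no planted motif (even with one
mismatch) can deterministically trigger another factor's matrix, a shifted
offset, or the opposite strand; backgrounds are redrawn until scanning
recovers exactly the planted sites.

What passing tests on these fixtures shows: the thermodynamic machinery is
exact, mechanisms act in the right direction at the right ranges, and
parameters of a well-posed reduced problem are identifiable from noisy data.
What it does not show: that real enhancers are described by these parameter
values, that the profile shapes match real gradients, or that the full
49-parameter fit is identifiable from seven constructs — the training data
for that live outside this package.

## Numerical choices and degenerate inputs

* Occupancy enumeration is exact; the empty configuration anchors the
  partition function at ≥1, so no division by zero is possible.
* `exp` arguments in the rate law are clipped at ±700 to avoid overflow; the
  logistic is evaluated via `logaddexp`.
* Sequences shorter than a PWM yield no sites (not an error); a construct
  with zero sites predicts the basal rate `R_max/(1+exp(θ))` and dissection
  warns rather than fails.
* Group enumeration order, construct order and position order do not affect
  results (tested).
* The recovery benchmark frees six parameters spanning the mechanism
  classes (`alpha_bcd`, `alpha_coact_hb`, `theta`, `beta_q_kr`, `beta_d_kr`,
  `coact_eff_bcd`) over the four fusion constructs; problem sizes throughout
  the suite (500 oracle constructs, 1000 conservation/Markov instances, 100
  knockout constructs, a 2×10⁵-evaluation fitting cap) were chosen so the
  whole validation runs on a single CPU in minutes.

## Known limitations

* No temporal dynamics or mRNA decay: the model is a per-time-class
  steady-state map.
* No corepression, no heterologous cooperativity, no chromatin/silencing
  effects; activators act at unlimited range up to the construct boundary,
  which is known to bias predictions for long multi-enhancer segments.
* Freed thresholds make the objective piecewise-constant in those
  coordinates; annealing handles this, gradient-based backends do not, so
  threshold fitting should use an annealer.
* The Lam-style schedule is an adaptive-control implementation in the spirit
  of the cited approach, not a line-by-line reimplementation.
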