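# Methods

## Model

The receptor complex is an ensemble of M distinguishable binary switches.
A complexion x_w assigns ON (1) or OFF (0) to every switch location;
switch 1 occupies the most significant position of the bit-string form.
Two principles organize the model:

**Information storage.**  H(X) = −Σ Pr(x_w) log₂ Pr(x_w) over
complexions; the uniform distribution over the W = C(M, Mo) complexions
with Mo ON stores log₂ W bits, maximal at balanced ON/OFF.  Capacity is
log₂ W at the balanced count.  Mutual information across a
complexion→effector channel is computed as H(X) + H(Y) − H(X,Y); both
conditional decompositions are evaluated and must agree to 1e-9.  Plain
ligand binding partitions receptors into bound/unbound and stores at most
the binary entropy of the bound fraction, 1 bit at half occupancy.

**Entropy production.**  An ACTIVE switch carries per-receptor flux J_i
and dissipates −μ_i ≥ 0 per cycle; Tσ = −Σ J_i μ_i.  With ΣJ_i = J and
Σμ_i = ΔG fixed, the interior stationary point of the bilinear objective
has all J_i equal and all μ_i equal (∂/∂J_i ⇒ μ_i = const,
∂/∂μ_i ⇒ J_i = const).  Because a bilinear saddle admits perturbations in
either direction, the numerical optimality check
(`verify_uniform_flux_optimality`) closes the system with an explicit
flexible-response assumption: the drops co-vary with flux at equal
per-switch power (μ_i ∝ 1/J_i, rescaled so Σμ_i = ΔG exactly).  Under
that rule Tσ = M|ΔG|/Σ(1/J_i), which the uniform allocation maximizes
(harmonic–arithmetic mean inequality); random Dirichlet allocations are
used to confirm it numerically.  The check is advisory: it validates the
uniform-flux *result* under a stated constraint set, it does not re-derive
the variational argument.

## Kinetics

State C pools every ligand-bound receptor configuration that is not a
switch output.  With K_L = k_L⁻/k_L⁺ the ligand dissociation constant
(k_L⁺ = association, k_L⁻ = dissociation), the binding balance at steady
state is C = R_F·L/K_L, giving C = L·R_pool/(L + K_L) for a pool
R_pool not yet captured by ON switches.  ACTIVE switch i obeys
dR_i*/dt = J₀ − k_i⁻ R_i* and sits at R_i* = J₀/k_i⁻; the default
k_i⁻ = J₀ makes every ON plateau exactly 1 R_ref unit.  Mass
conservation R_T = R_F + C + ΣR_i* defines C during integration and is
enforced to 1e-9.

Starting from unexposed receptor, a finite J₀ would drive ON-state
concentrations negative, so all switches begin INACTIVE; an ON/OFF pair
activates each time C reaches 1, i.e. at L_k = K_L/(R_pool − k) for the
k-th activation with the pool depleted by the k−1 switches already ON.
The OFF partner of each pair resides in pool C, so only the ON switch
consumes 1 R_ref unit.  At most ⌈R_T⌉ − 1 switches (the largest integer
*strictly* below R_T; R_T = 3 allows 2) can turn ON.  Sweeps are
quasi-static: a sequence of steady-state solves with thresholds computed
in closed form and the grid merely sampling the staircase; this
sidesteps the transient partitioning of C at an activation event, which
the steady states do not constrain.  A time-dependent mode
(`integrate_to_steady_state`, LSODA, rtol 1e-8 / atol 1e-10) validates
the fixed points to 1e-6 and declares a configuration infeasible if the
trajectory leaves the non-negative region persistently (beyond 1e-6).
Ligand dissociates only from state C, so the reverse sweep holds every
ON plateau down to L = 0 — the hysteresis prediction.  Steps are kept
sharp: this is a mean-field model and no fluctuation smoothing is
applied.  Which pathway (GTPC vs PdPC) fires at each threshold is a
configuration policy (`activation_order`), not a model output.

The Black–Leff Operational comparator is implemented exactly as
R* = K_S L/(L + K_L + K_S L)·R_T with K_S = k⁺/k⁻, plus the
identical-switch equipartition variant (R_T/n per switch).  Its EC50 is
K_L/(1 + K_S) in closed form.  Heterogeneous Operational variants and
ternary-complex models are out of scope.

## Hebbian cycle simulation

Transition probabilities over the 2^M complexions start uniform
(self-transitions included, since singleton cycles exist).  A trajectory
samples 16 steps; each realized transition is reinforced
*multiplicatively* by 10% and its row renormalized — "increased by 10%"
is ambiguous between additive and multiplicative, and the multiplicative
form keeps entries below 1 before renormalization.  Trajectories restart
from uniformly drawn initial states until (a) every row's dominant
probability reaches p* = 0.99 and (b) the argmax graph is unchanged for
50 consecutive trajectories (both defaults configurable; hard cap 50 000
trajectories).  Cycles and basins are read off the converged argmax
functional graph; basin probability is the fraction of all 2^M states
whose greedy trajectory enters the cycle (weighting by cycle membership
is available as an option).  Runs with different seeds converge to
different cycle sets; the balance statistic therefore aggregates the
basin-weighted mean ON count over ≥ 30 independent runs.  For M = 4 and
100 runs the grand mean sits near M/2 = 2 with spread ≈ 0.5.

## Bias analysis

The packaged table carries, for each of 20 ligands, the normalized
maximal Gα and βarr responses and log₁₀ molar EC50s, with censored
entries ("X") contributing the maximum but no EC50 constraint.  The fit
has three free parameters: R_ref (estimated as the mean saturation level
of the pathways with observed activation), the first-switch EC50 (set to
the smallest uncensored measured EC50; ties broken toward Gα, the
observed ordering), and ΔR (default 0; optionally inferred from the
measured second EC50 via EC50₂/EC50₁ = (ρ−1)/(ρ−2), ρ = R_T − ΔR).  The
activation threshold *is* the model's entire rise, so the measured EC50
is placed at the step.  With the default pool ρ = 2.5 the predicted
second threshold is 3× the first.  Bias trajectories are built from the
kinetics module's forward sweep; an activated pathway contributes its
1-R_ref plateau, so endpoints are corners of the (Gα, βarr) plane by
construction — the common-saturation prediction, consistent with the
measured endpoints clustering near (0,0), (0,1), (1,0) and (1,1).
Classification thresholds the normalized maxima at 0.5 (a package choice
validated by exact agreement with the published narrative grouping).
For βarr-biased angiotensin ligands the hypothesized unmeasured first
switch is not inferred: the βarr EC50 is treated as the observed
activation and the hidden switch's threshold remains unidentifiable.

## Synthetic-data generator

`generate_synthetic_assay` emits tables with the structure the analysis
assumes: a common saturation level R_ref = 1, a pool of ρ = 2.5 R_ref
units (two activatable switches, matching the published fits), Gα
activating first at a log-uniform EC50 in [10⁻⁹·⁵, 10⁻⁶·⁵] M (the range
spanned by the published table), the βarr threshold from pool depletion,
log-normal multiplicative noise with coefficient of variation `noise_cv`
on maxima and EC50s, and βarr censoring with probability `censor_rate`
(censored maxima sit at 0.15·R_ref, sub-threshold).  The generator
reproduces the *structure* of assay data, not its full realism: no
baseline drift, no Hill-slope variation, no correlated replicate noise,
no partial agonism between 0.15 and 1.  Passing recovery tests therefore
demonstrate internal consistency of generator + fit, not performance on
raw experimental curves.  Recovery experiments use 50 ligands at
noise CV 0.05 (mean relative error of R_ref and first EC50 below 5%,
shrinking to float precision at zero noise).

## Numerical conventions and edge cases

- Information is base-2 by default (`units="nats"` optional); 0·log 0 = 0.
- Odd M: both ⌊M/2⌋ and ⌈M/2⌉ maximize W and both are returned; capacity
  uses either (equal).
- Complexion enumeration is lexicographic, switch 1 most significant.
- A flux exceeding a return rate raises an infeasibility error rather
  than clamping — the kinetics uses this signal to keep switches
  INACTIVE.
- Argmax ties in a transition matrix (tolerance 1e-9) mark it
  non-converged and cycle extraction refuses to proceed.
- Problem sizes: property tests enumerate up to M = 12 (4096 states);
  the balance campaign uses 100 runs of the 16-state protocol; recovery
  uses 50 synthetic ligands.  All chosen to characterize the statistics
  while keeping any run in seconds to a few minutes.

## Known limitations

- Mean-field sharpness: real transitions are broadened by fluctuations;
  the model's steps are discontinuous by design.
- The equal-power co-variation closing the entropy-production check is an
  assumption; other flexible-response rules could order allocations
  differently.
- Gα desensitization by core-bound arrestin, receptor internalization,
  RGS kinetics and spatial effects are outside the model.
- The hysteresis prediction is untested experimentally; the reverse
  sweep describes the model, not validated biology.
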