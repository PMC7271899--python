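# Methods

This note records the model, the statistical machinery, the numerical
choices, and the limits of what the synthetic-data experiments in this
repository can demonstrate.

## The kinetic model

Each KaiC subunit's CII domain is tracked by three properties: its
phosphoform (U, T, S, D — unphosphorylated, phospho-Thr432,
phospho-Ser431, doubly phosphorylated), the nucleotide in its catalytic
pocket (ATP or ADP), and whether a KaiA dimer is bound. The 4 × 2 × 2 = 16
states are connected by mass-action reactions of four classes:

* **Phosphotransfer.** CII is a bidirectional phosphotransferase: it moves
  the γ-phosphate of bound ATP onto a site (phosphorylation) and back onto
  bound ADP (dephosphorylation, regenerating ATP). Hence ATP-bound states
  cannot dephosphorylate, ADP-bound states cannot phosphorylate, and the
  allowed interconversions are C_TP^X ⇌ C_DP^Y for
  (X,Y) ∈ {(U,T), (U,S), (T,D), (S,D)}.
* **ATP hydrolysis.** C_TP^X → C_DP^X + Pi, irreversible. This is the only
  route to ADP-bound KaiC in the absence of KaiA, and it is what makes
  sustained autodephosphorylation possible.
* **KaiA (un)binding.** C + A ⇌ A·C, second-order in free KaiA dimer. Free
  KaiA is computed algebraically from conservation
  (A_free = A_total/2 − Σ bound) rather than integrated as a state —
  conservation is then exact and the system has one fewer stiff variable.
  All KaiA concentrations are divided by two on input (dimer convention).
* **Nucleotide exchange.** Only KaiA-bound, ADP-bound states exchange:
  A·C_DP^X → A·C_TP^X at rate krDP · ΔkTPA,X · (%ATP/100). The linear %ATP
  dependence comes from eliminating the transient apo state under a
  quasi-steady-state assumption with equal ATP/ADP on-rates; ATP release
  is fixed at zero, so solution ADP acts only by slowing exchange, and the
  dephosphorylation pathway is %ATP-independent by construction.

The nucleotide pool is constant (no depletion), KaiC is treated at the
subunit level (no hexamer, no CI ATPase, no KaiB in this model), and KaiA
does not interact with free nucleotides.

### Parameterization

Every rate is a base rate times a multiplicative, state-specific modifier,
e.g. kbT,TP = kb · ΔkbT,TP. The baseline throughout is the U phosphoform /
ATP-bound / KaiA-free combination, and the bare (kp, kd) pair anchors the
U ⇌ T reaction without KaiA; the scheme has 38 modifiers. Thermodynamic
detailed balance — the forward and reverse rate-constant products around
every reversible cycle must be equal, since hydrolysis and exchange are
the only irreversible steps — closes four cycles of the form
C_TP^X → C_DP^Y → A·C_DP^Y → A·C_TP^X and eliminates the four KaiA-on
modifiers δkaS,TP, δkaT,TP, δkaT,DP, δkaS,DP. Free parameters: 6 base
rates + 34 modifiers + the global error variance σ² + 7 initial-condition
fractions = 48 scalars. All rates and modifiers are sampled in log10
space, which enforces positivity.

Initial conditions for phosphorylation reactions put the fitted fractions
of total KaiC on the eight KaiA-free states (KaiA-bound states are empty
at mixing time); the eighth fraction follows by conservation. The
dephosphorylation protocol is simulated in two stages: 3.4 µM KaiC, all
C_TP^U, is phosphorylated with 1.3 µM KaiA at 100% ATP for 20 h; then all
free KaiA and all KaiA-bound KaiC are removed (the pull-down) and the
remaining mixture autodephosphorylates. Stage 2 therefore starts with less
than 3.4 µM KaiC, and percentages are relative to its own total.

## Priors and likelihood

* Base rates: log10-normal, sd 3 decades; means 0 except
  ka → log10(0.0279 s⁻¹µM⁻¹) and kb → log10(0.0663 s⁻¹), the measured
  KaiA on/off rates.
* Modifiers: log10-Laplace with scale b = 1 (an ℓ1 penalty: each modifier
  shrinks to "no state effect" unless the data say otherwise). Means are 0
  except the T/S/D off-rate modifiers, centred at −log10(τ_X · kb) for
  measured dwell times τ_T = 1.0 s, τ_S = 0.43 s, τ_D = 0.26 s, applied to
  both the ATP- and ADP-bound modifier of each phosphoform (the
  measurements did not resolve the nucleotide).
* σ²: inverse-gamma(1, 0.01) in µM². The likelihood is evaluated in
  percentage points; σ_pct = √σ² / [KaiC]_total × 100 with each
  trajectory's own total (relevant for stage-2 dephosphorylation).
* Initial fractions: Dirichlet(20, 100, 1, 1, 1, 1, 1, 1) over the eight
  KaiA-free states in the order (C_TP^U, C_DP^U, C_TP^T, C_DP^T, C_TP^S,
  C_DP^S, C_TP^D, C_DP^D) — concentrated on the dephosphorylated ADP-bound
  state, where a dephosphorylated reaction mixture actually sits.

The time-series likelihood is Gaussian with the single global σ;
dephosphorylation records carry weight 4 (the full log-density is
multiplied, normalization included — the weight's purpose is to rebalance
the small dephosphorylation dataset against the 18 phosphorylation
conditions, and scaling the whole density keeps the weighted posterior a
proper tempered product). S is never an observable (percentages sum to
100; S is the conservation-constrained variable; datasets store U, T, D).

The hydrolysis observable — cumulative Pi release plus ADP-bound KaiC at
t = 12 h — is an upper bound, not a measurement, so its log-likelihood is
a half harmonic: zero below the bound, −(x − bound)²/2σ_h² above. The
bound 29.8 KaiC⁻¹ day⁻¹ converts to 29.8 × [KaiC] × 0.5 µM over 12 h
(52.15 µM at 3.5 µM KaiC); σ_h uses the reported uncertainty
5.1 KaiC⁻¹ day⁻¹ the same way — the only uncertainty figure available for
this constraint. It is attached to the [KaiA] ∈ {0.375, 0.75, 1.5} µM
conditions at 100% ATP (the source measurement was near 100% ATP);
the condition list is configurable.

## Sampling and fitting

The sampler is the affine-invariant ensemble ("stretch move") method: to
update walker θ_k, draw partner θ_j from the rest of the ensemble, propose
η = θ_j + z(θ_k − θ_j), and accept with probability
min(1, z^(N−1) exp(Δ ln p)). The stretch density is g(z) ∝ 1/√z on
[1/α, α] by default — the form for which the z^(N−1) factor makes the move
reversible, and the one the standard ensemble samplers implement; a 1/z
variant is kept behind a flag because both forms circulate in the
literature. Default α = 1.1 for the 48-dimensional posterior (acceptance
near 50%); toy problems in the tests use larger α. Walkers are updated
sequentially; the walker count must exceed the dimension (default 224).

Tempering raises only the likelihood: the annealed target is L^β p, with
β = 0.3 … 1.0 in steps of 0.1. The four-step fit heuristic:

1. **Initialize** walkers from the prior; **anneal** up the β ladder
   (20,000 steps per β at full scale).
2. **Select** the best 300 de-duplicated samples ranked by the true
   posterior; pick 10 by stratified rank (the best plus nine spread evenly
   down the ranking — the selection rule among the 300 is otherwise
   unconstrained, and stratification keeps some diversity); locally
   **optimize** each with Powell's derivative-free method.
3. **Reseed** the ensemble around the optima with N(0, 0.001²I) noise
   (which also guarantees distinct walkers for the stretch proposal),
   allocating walkers ∝ posterior^0.6; the best optimized point is kept
   verbatim (elitism). **Sample** 50,000 steps at β = 1.
4. **Terminate** when sampling stops finding maxima more than 1 nat above
   the optimized ones (an explicit operationalization of "no new local
   maxima"; configurable), after an additional 50,000-step run; otherwise
   loop to selection. The last 30,000 steps, thinned by 100, feed
   post-analysis.

The `test` profile cuts every chain length by ≥ 50× for desk-scale runs;
the `paper` profile holds the full constants.

## Evidence and model variants

The marginal likelihood is estimated with a free-energy-perturbation
ladder over tempered targets q_λ = L^λ p: ln Z = −Σ_n ln⟨L^{λ_{n−1}−λ_n}⟩
with each average taken over samples of stage λ_n. Stages run at
λ = 1.00, 0.99, …, 0.01 (2,000 steps each, last 1,000 used, at full
scale); the final segment down to λ = 0 is evaluated with the λ = 0.01
stage's own samples, which completes the telescope exactly. The likelihood
must be a normalized density over data; the prior normalization cancels
stage-wise. Monte Carlo standard errors come from a bootstrap over walkers
(within-walker autocorrelation makes sample-wise errors over-optimistic).
Two cautions established on the conjugate-Gaussian oracle: the exponential
average is biased when adjacent stages overlap poorly, so coarse ladders
(Δλ ≳ 0.1) shade the estimate high, and the bootstrap SE describes
variance, not that bias. Bayes factors are evidence ratios; 3.2 is the
conventional "substantial" threshold.

Reduced variants tie the KaiA (un)binding modifiers: `minus_n` makes them
independent of the nucleotide state (one on/off pair per phosphoform),
`minus_p` independent of the phosphoform, `minus_n_p` leaves a single pair
(the base ka, kb). Each variant keeps the same reaction network and
re-solves the four cycle constraints for the four KaiA-bound
phosphorylation modifiers (ΔkpA,UT, ΔkpA,US, ΔkpA,TD, ΔkpA,SD), so
detailed balance holds exactly in every variant.

## Stimulus–response analysis

"Steady state" is operationalized as the response at a fixed long time
(24 h, matching how such endpoints are measured) with a settledness check
(|d%CP/dt| < 0.1 %/h over the final hour; non-settled points are flagged,
not dropped). ECx is the stimulus reaching x% of the saturation level
above the [KaiA] = 0 baseline, by monotone linear interpolation;
saturation is the response at the top of the grid after a plateau check
(relative slope < 1%/decade). EC10 measures thresholding, EC90 − EC10
switching; a hyperbola [A]/(K+[A]) gives exactly (K/9, 80K/9), so
(EC90−EC10)/EC10 = 80 is the no-ultrasensitivity reference. ECx accuracy
is limited by grid coverage of the plateau; the analysis grids span the
response range and the analytic checks use wide grids with an explicit
zero point.

The phenomenological competition curve is the inhibitor-ultrasensitivity
scheme: free kinase after one-site binding to a stoichiometric inhibitor
(dissociation constant K₂) drives a hyperbolic response of scale K₁, plus
basal offset b. The printed closed form of this curve is typographically
unreliable in the source text, so the implementation evaluates the scheme
itself — the stable root of the binding quadratic fed through the
hyperbola — and is anchored by its exact limits: the K₂ → 0
threshold-hyperbola Pmax (K−I)/(K₁+K−I) H(K−I) + b, the value b at
K = I, and saturation Pmax + b. EC50 is not an explicit parameter and is
found by root bracketing on the fitted curve.

## The oscillator model

The metabolic-compensation scans use a monomer-cycle oscillator in the
classic architecture: phosphoform populations U → T → D → S → U with each
step rate k_XY(A) = k0_XY + kA_XY · A/(K½ + A) in active KaiA (the
standard monomer-model rate constants, h⁻¹, K½ = 0.43 µM), plus two
KaiB-bound states ^BC^S and ^BC^D that carry the delayed negative
feedback. KaiB binds the S phosphoform (fast exchange, kon = koff = 5 h⁻¹);
complexes keep their CII kinetics (KaiB acts through the other domain) and
each complex sequesters 4 KaiA monomers. Solution %ATP scales the four
phosphorylation steps by pct/(pct + 0.1·(100−pct)). The KaiB branch and
its constants are this package's own calibration — chosen for stable
~27 h oscillations at 3.5 µM KaiC / 1.5 µM KaiA over a broad %ATP range —
and are versioned in `PhongParams`, not taken from any published table.

Active KaiA follows from a one-site quasi-equilibrium between total KaiA
and the sequestration capacity with dissociation constant K_D; K_D → 0
recovers the complete-sequestration min rule. The ultrasensitive
phosphorylation threshold replaces the drive A by max(0, A − θ) with
θ = 0.1 · [C^U] · (0.15 + (100 − %ATP)/100) — a stand-in with the two
properties that matter: θ grows with the U-phosphoform pool and with
falling %ATP. θ = 0 reproduces the unpatched trajectories bit for bit
(same code path, exact arithmetic identity).

Classification follows a fixed recipe: simulate 200 h, discard the first
100 h, resample at 0.1 h, find troughs of total phosphorylation
[C^P] = [C^T]+[C^S]+[C^D]+[^BC^S]+[^BC^D] with prominence ≥ 0.01 µM;
"weak" if std([C^P]) < 0.1 µM, "too few troughs" if fewer than 3, "damped"
if the trough values drift (std > 0.001 µM); otherwise the period is the
mean trough-to-trough time. The damped criterion is tight, so the
oscillator ODEs run at rtol 1e−8 / atol 1e−10 to keep numerical trough
jitter well below it.

## Synthetic data

The generator simulates the full design — [KaiA] ∈ {0.375, 0.75, 1.5, 3,
4.5, 6} µM × %ATP ∈ {10, 25, 100} × 8 phosphorylation time points, plus
the 21-point two-stage dephosphorylation series — under a documented
ground truth and adds i.i.d. Gaussian noise (default sd 1 percentage
point) to the U, T, D percentages, clipping to [0, 100] afterwards.
Phosphorylation sampling times default to {0, 1, 2, 4, 8, 12.25, 18, 24} h
(only 12.25 h is anchored externally); dephosphorylation uses 21 even
points on [0, 20] h. The likelihood ignores the clipping; the
approximation only matters for records within a few sd of the rails, and
the recovery experiments use time grids that avoid them.

The ground truth is built around the substrate-competition mechanism: KaiA
captures the ADP-bound U state with a nanomolar-range dissociation
constant (Δka = 10^2.5, Δkb = 10^−2.5 on the measured base rates) while
T/S/D off-rates sit at their dwell-time centres; the KaiA-bound U state
cycles between exchange and hydrolysis (ΔkhA,U = 10^0.5), and KaiA-bound
phosphotransfer commits forward (ΔkpA,UT = 10^1.3, ΔkpA,TD = 10^0.8). This
yields: a phosphorylation plateau of ~95 %CP at 1.5 µM KaiA/100% ATP
within 24 h; full dephosphorylation without KaiA; 12-h ADP production
(~21 µM) under the hydrolysis bound; and a threshold-hyperbolic
stimulus–response at 25% ATP with EC10 ≈ 4× the fitted-hyperbola K/9,
which collapses to ≈ 1.5× when the nucleotide dependence of KaiA binding
is tied out.

What the synthetic experiments do **not** show: the generator's noise is
i.i.d. Gaussian with one global sd — no gel-batch effects, no
densitometry nonlinearity, no time jitter — so passing recovery tests
demonstrates the estimator's correctness under the model's own
assumptions, not robustness to real measurement pathologies. Likewise the
oscillator scans establish the qualitative robustness claims (stable
region containment, micromolar-K_D instability), not any published period
map.

## Numerical choices

* Integrator: LSODA (automatic stiff/non-stiff switching; BDF multistep in
  the stiff regime, with an analytic Jacobian and a numba-compiled RHS),
  rtol 1e−6, atol 1e−9 µM; time I/O in hours, rates in s⁻¹, the 3600
  factor applied once at system assembly. Integration failure maps to
  log-posterior −∞.
* Concentrations in [−atol, 0) are clamped to zero for observable
  computation only, never fed back into the state.
* Detailed-balance closure is exact algebra in log10 space; the test suite
  verifies every cycle's rate-product ratio to 1e−12 on random parameter
  sets, including all tied variants.
* Posterior fits at test scale clamp the non-target coordinates at known
  values (`ReducedPosterior`), which is what makes 10-seed coverage
  experiments affordable; the identifiable quantities checked are the
  hydrolysis rate and the ADP-bound-U dissociation-constant combination
  kb·Δkb/(ka·Δka), whose posteriors the reduced design actually
  constrains. Problem sizes for these experiments (2 conditions, 7 time
  points, 8 walkers × 400 steps) were chosen as the smallest design that
  leaves those quantities identifiable.

## Known limitations

* No hexamer structure or inter-subunit cooperativity; ultrasensitivity
  from hexameric effects is out of model space by construction.
* The evidence ladder at desk scale uses coarser λ steps than the
  full-scale configuration; bias grows with step size (see above), so
  desk-scale Bayes factors are indicative, not precise.
* The oscillator's KaiB branch is a calibrated reconstruction; only the
  qualitative robustness statements are claimed for it.
* The fit heuristic's termination rule ("no better maximum by > 1 nat") is
  a pragmatic stopping criterion, not a convergence diagnostic; full-scale
  inference should still compare independent runs.
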