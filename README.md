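# kaiac

Bayesian kinetic analysis of the KaiA–KaiC subsystem of the cyanobacterial
circadian clock.

The cyanobacterium *Synechococcus elongatus* keeps time with a
protein-only oscillator: KaiC phosphorylates by day (stimulated by KaiA)
and dephosphorylates by night (when KaiB sequesters KaiA). This package
implements, as a tested library plus a set of analysis drivers, a
data-driven kinetic treatment of the daytime half of that clock — how
KaiA concentration and the solution ATP/ADP ratio jointly set the KaiC
phosphorylation level — for computational biologists who want to fit,
interrogate, or extend mass-action clock models.

## What is in the model

Each KaiC subunit's CII domain is tracked by phosphoform
(U, T, S, D), bound nucleotide (ATP/ADP), and KaiA occupancy — 16 states
connected by reversible phosphotransfer (C_TP^X ⇌ C_DP^Y, so ATP-bound
KaiC cannot dephosphorylate and ADP-bound KaiC cannot phosphorylate),
irreversible hydrolysis C_TP^X → C_DP^X + Pi, reversible KaiA binding,
and KaiA-dependent nucleotide exchange at rate
krDP · ΔkTPA,X · (%ATP/100). Every rate is a base rate times a
state-specific multiplicative modifier Δk (38 modifiers; detailed balance
around the four reversible cycles eliminates 4, leaving 34 free), giving
48 free parameters with σ² and initial conditions. Estimation is
Bayesian: log10-normal priors on base rates, ℓ1 (log10-Laplace) shrinkage
on the modifiers, a Gaussian likelihood with one global σ, a half-harmonic
bound on ATP hydrolysis, and an affine-invariant ensemble MCMC
("stretch move", q = min(1, z^(N−1) p(η)/p(θ))) wrapped in an
anneal–select–optimize–sample fit heuristic. Model variants with tied
KaiA kinetics are compared by Bayes factors from a tempered-likelihood
(free-energy-perturbation) evidence ladder. A monomer-cycle oscillator
with finite KaiA-sequestration affinity K_D probes what the resulting
ultrasensitivity does to metabolic compensation of the full clock.

Everything runs on synthetic data generated in-repo by `kaiac.synth`
(the experimental design: 6 [KaiA] × 3 %ATP × 8 time points, a 21-point
dephosphorylation series, a hydrolysis bound), so the whole pipeline is
testable without downloads.

## Worked example

Simulate the reference parameter set and measure the shape of its
stimulus–response curve:

```python
import numpy as np
from kaiac import SimulationCondition, default_truth, observables, simulate
from kaiac.response import shape_measures, steady_state_response

params = default_truth().params

# a standard phosphorylation reaction: 3.5 uM KaiC, 1.5 uM KaiA, 100% ATP
obs = observables(simulate(params, SimulationCondition(), np.linspace(0, 24, 9)))
print(f"%CP at 24 h: {obs.pct['CP'][-1]:.1f}")
print(f"ADP produced over 12 h: {obs.adp_produced_12h:.1f} uM")

# the steady-state response to KaiA at 25% ATP, and its shape metrics
curve = steady_state_response(params, pct_ATP=25.0)
s = shape_measures(curve)
print(f"EC10 = {s['ec10']:.3f} uM, EC90-EC10 = {s['switch']:.3f} uM, "
      f"threshold ratio = {s['ec10'] / s['hyperbola_ec10']:.2f}")
```

prints

```
%CP at 24 h: 95.4
ADP produced over 12 h: 20.5 uM
EC10 = 0.514 uM, EC90-EC10 = 1.524 uM, threshold ratio = 4.15
```

Phosphorylation saturates near 95% with hydrolysis well under the
measured bound (52.1 µM over 12 h at 3.5 µM KaiC). The shape metrics are
the interesting part: a plain hyperbola [A]/(K+[A]) has EC10 = K/9, so a
threshold ratio of 4.15 means the response stays suppressed to more than
4× higher [KaiA] than any hyperbola through the same points — the
threshold-hyperbolic signature of substrate competition, in which the
ADP-bound unphosphorylated state traps KaiA (nanomolar dissociation
constant) until the trap pool is depleted. Tying KaiA kinetics to be
independent of the bound nucleotide
(`kaiac.evidence.nucleotide_tied_from`) collapses the ratio to 1.48.

## The analysis sequence

Numbered drivers under `analysis/` run the pipeline end to end and write
tables under `results/`:

| driver | what it does |
| --- | --- |
| `01_simulate_reference_kinetics.py` | 16-state kinetics of phosphorylation and the two-stage dephosphorylation protocol |
| `02_generate_fitting_dataset.py` | full synthetic fitting dataset (495 records over 19 conditions) |
| `03_fit_and_recover.py` | test-scale posterior sampling; 95% intervals vs the generating truth |
| `04_response_ultrasensitivity.py` | stimulus–response curves and EC metrics, full vs nucleotide-tied model |
| `05_evidence_ladder_demo.py` | evidence ladder vs a closed-form conjugate oracle |
| `06_oscillator_robustness_scan.py` | %ATP × K_D oscillation scans with and without the phosphorylation threshold |

A thin CLI (`kaiac synth|simulate|fit|evidence|response|phong-scan`)
exposes the same stages; every run writes a manifest (seed, config hash)
for reproducibility.

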