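# Methods

## Problem setting

`fireflyfit` estimates the kinetic parameters **x** = {x₁, …, x_M} of a
nonlinear ODE model ds/dt = f(s, x, t, u) from noisy time-series
measurements y of a subset of species (the output map g). Estimation
minimizes the unweighted nonlinear least-squares fitness

    J(x) = Σₙ Σₖ ( y[n, k] − ŷ[n, k; x] )²,

summed over all N sampling times and all K observed species, where ŷ is
the solver prediction at the sampling grid. No normalization by N and no
per-species weighting is applied by default (an optional per-species
weight vector exists for users whose species live on very different
scales). Out-of-bounds candidates are clipped by the optimizer before
evaluation, so J itself is a pure function; a failed integration maps to
J = +∞ and the candidate is discarded by selection.

## The hybrid optimizer

The optimizer hybridizes the Firefly Algorithm (FA) with the evolutionary
operators of Differential Evolution (DE). A population of NP candidate
vectors is initialized uniformly in the search box, x_id = LB_d +
C₁·(UB_d − LB_d). Each iteration then performs:

1. **Firefly pass.** Every candidate i attempts a move toward every
   neighbour j with strictly better fitness:
   x_i ← x_i + β·(x_j − x_i) + α·(C₂ − 0.5), with attraction
   β = β₀·exp(−φ·r_ij²) decaying in the Euclidean distance r_ij.
2. **Partition.** Candidates are ranked by fitness (stable sort, ties by
   original index); the top ⌈potential_fraction·NP⌉ form the *potential*
   set, the remainder the *weak* set.
3. **DE step on the potential set.** Mutation v_i = x_i + C₄·MR·(x_r1 −
   x_r2) with distinct donors from the potential set; binomial crossover
   with rate CR and one forced component (so the offspring differs from
   the parent whenever v_i does); greedy selection — the offspring
   replaces the parent only on strict fitness improvement, so the
   potential set never worsens.
4. **Weak re-seeding.** Weak members are redrawn around the current best
   vector: x_id ← x_min,d + (C₃ − 0.5)·w·(UB_d − LB_d), with re-seeding
   width w (default 0.1 of the box). This is what lets the swarm escape
   suboptimal basins without losing its best solution.

All random draws (C₁–C₄, α's noise, donor and forced-index choices) come
from a single seeded generator in a fixed call order, so runs are exactly
replayable. The global best is tracked outside the population, making the
best-fitness trace non-increasing by construction (elitism). The plain-FA
baseline (`run_fa`) executes only step 1.

Defaults: β₀ = 1, φ = 1, α = 0.2, MR = 0.5, CR = 0.9,
potential_fraction = 0.5, w = 0.1. These are exposed, not asserted — they
are conventional values for the two component algorithms, and the study
the defaults emulate does not pin them. By default the fitness of a moved
firefly is refreshed after each accepted move (`eval_mode="move"`);
`eval_mode="sweep"` refreshes once per firefly per sweep (the canonical
FA schedule) and costs roughly NP fewer ODE solves per iteration — the
heavy paired-seed comparison tests use it.

## Built-in models

**p53–Mdm2 negative feedback loop** (states A = nuclear p53, B = Mdm2,
C = p53–Mdm2 complex, D = Mdm2 mRNA; nine rate constants):

    dA/dt = k₁ − k₂A − k₃AB + k₄C
    dB/dt = k₆D − k₃AB + k₄C + k₇C − k₅B
    dC/dt = k₃AB − k₄C − k₇C
    dD/dt = k₈A − k₉D

k₁ p53 production, k₂ p53 degradation, k₃ complex formation, k₄ complex
diffusion (back-flux), k₅ Mdm2 degradation, k₆ translation, k₇
Mdm2-mediated p53 degradation (the complex consumes its p53 moiety and
releases Mdm2), k₈ p53-driven transcription, k₉ mRNA degradation. The
E2 variant zeroes k₄ and k₉ (no complex diffusion, no mRNA turnover),
which sends mRNA and Mdm2 monotonically away from the feedback
steady state — a structurally detectable perturbation.

The reference ("true") parameter values and initial conditions for this
model are synthetic defaults of this package: k = (1, 0.2, 2, 0.2, 1, 1,
2, 1, 1) in scaled concentration/time units, s₀ = (1, 0.2, 0.1, 0.1),
horizon 30 time units. They were chosen so that (i) the loop shows a
damped transient into its steady state within the horizon and (ii) all
four species span comparable O(1) dynamic ranges, so the unweighted
objective is equally sensitive to every species. All four species are
observed.

**Arginine catabolism** (states A = external arginine, B = ornithine,
C = internal arginine; sixteen rate constants; only B and C observed).
Five Michaelis–Menten-type rates:

    v₁ = k₁A/(k₂ + A + k₇B) − k₁₃C/(k₁₄ + C + k₁₁B)   (net CAT transport)
    v₂ = k₃C/(k₄ + C)                                   (arginase)
    v₃ = k₅C/(k₆ + C)                                   (NO synthase)
    v₄ = k₈B/(k₉ + B)                                   (ornithine decarboxylase)
    v₅ = k₁₅B/(k₁₆ + B + k₁₂C) + k₁₀B                   (ornithine export + leak)

    dA/dt = −v₁,  dB/dt = v₂ − v₄ − v₅,  dC/dt = v₁ − v₂ − v₃

Ornithine competes with arginine for the cationic amino-acid transporter;
that competitive inhibition is the additive k₇B term in the uptake
denominator, written in lumped form so that k₇ = 0 removes the inhibition
exactly (the F2 variant) while leaving the rest of the rate law intact.
The reference parameter set is k = (70, 160.5, 380, 847, 420, 420, 110,
1500, 1000, 0.013, 60, 1.33, 16, 160.5, 380, 847); the F3/F4/F5 variants
override subsets of these constants. Initial concentrations default to
(500, 300, 200) µM with a 5-time-unit horizon, giving a fast catabolic
transient in both observed species.

**Integration.** LSODA (adaptive step, automatic stiff/non-stiff
switching) with rtol = 1e-8, atol = 1e-10 by default. These are tight
enough that fitness differences between nearby candidates exceed solver
noise (verified by a 10×-refinement self-convergence test). The
integrator does not enforce non-negativity; trajectories dipping below
−10·atol trigger a warning, since concentrations cannot be negative.

## Synthetic data

The generator simulates the chosen model at its reference parameters and
adds independent Gaussian noise with per-species standard deviation
σ_k = level × RMS_k, where RMS_k is the root-mean-square of species k's
noiseless trajectory and the default level is 0.25 ("25% white Gaussian
noise"). The noise is homoscedastic within a species — this is what
yields a single real variance σ_k² per species for the identifiability
test. Negative noisy concentrations are kept as drawn; the choice is
recorded in the dataset metadata. Default grid: 100 equally spaced points
over the model's horizon.

Each dataset records two noise summaries: the nominal variance σ_k² of
the generating law, and the *realized* variance — the sample mean square
of the actual noise draws. The identifiability test compares against the
realized value by default, mirroring a protocol in which the "real
variance" is computed from the noisy data itself; with the nominal value
the pass verdict for a perfect fit would be a calibrated 95% event per
species rather than a property of the fit.

What the generator does *not* emulate: correlated or heteroscedastic
noise, missing samples within a series (incompleteness is expressed only
as unobserved species), instrument drift, or non-Gaussian outliers.
Passing tests therefore certify the method under its own stated noise
model, not under arbitrary experimental artifacts.

## Practical-identifiability test

Given a fitted parameter vector, residuals ε̂[n, k] = y − ŷ estimate the
measurement noise. Per species, the variance point ξ_k = (1/N)·Σ ε̂²
(denominator N; an optional N − M correction is available but off by
default) is surrounded by the equal-tails χ² confidence interval for a
Gaussian variance,

    [ N·ξ_k / χ²_{N, 1−δ/2} ,  N·ξ_k / χ²_{N, δ/2} ],  δ = 1 − γ,

with γ = 0.95 by default. The fit is rejected for species k when the real
variance falls outside the interval; a model passes only if every
observed species passes. Monte-Carlo calibration (2000 replicates,
N = 200) confirms the interval covers a known variance with probability
γ to within sampling error. Overfitting shows up as ξ_k far *below*
σ_k²; structural misfit (a knockout that cannot reproduce the dynamics)
as ξ_k far above. Both directions fail the interval check.

## Model selection

Candidates fitted on the same dataset are scored per species with the
Gaussian-noise AIC = N·ln(RS/N) + 2M (RS the per-species residual sum of
squares, M the model's full parameter count). Selection: among candidates
passing the χ² test, the smallest summed AIC wins; if none passes, "no
adequate model" is reported. Candidates are still totally ordered —
passers first, then ascending AIC — so a ranking exists even among
failures. Knockout candidates are scored at their perturbed parameter
vectors (the base fit with the overrides applied) rather than freely
refitted: a knockout with all remaining parameters free can partially
absorb the missing term inside a 25% noise band, which is not the
perturbation the selection question asks about.

## Problem sizes used in the shipped tests

Chosen as the package's own desk-scale study conditions:

* interval calibration: 2000 replicates × N = 200 residuals;
* single-parameter recovery: noiseless 100-point data, NP = 20, up to 200
  iterations with early stop at J ≤ 1e-10, bounds [1, 500] (k₁) and
  [1, 1000] (k₇);
* hybrid-vs-FA ordering: both models, 30-point grids, 25% noise, NP = 20,
  100 iterations, 20 paired seeds, sweep-mode evaluation;
* knockout pattern: 100-point data, base fits with all nonzero parameters
  free in a [0.2×, 5×] box around the reference values, NP = 20, 60
  iterations.

## Numerical choices and edge cases

* Bound violations are resolved by projection (clipping) onto the box —
  the simplest contract, applied identically in every operator.
* Selection ties keep the parent; partition ties keep original order
  (stable sort). Both choices make runs deterministic.
* A degenerate search box (LB = UB) collapses the population to a point;
  the run is still valid and returns that point.
* ξ = 0 (perfect residuals) yields the degenerate interval [0, 0]; RS = 0
  has no finite AIC and is reported as a domain error rather than −∞.
* The early-stop threshold ("acceptable fitness") is disabled by default.

## Known limitations

* The weak-half update re-seeds around the current best with a fixed
  width; it does not adapt the width to the search progress.
* AIC uses the full parameter count M for every species' column; species-
  wise effective parameter counts are not estimated.
* The χ² test requires the real variance; for imported (non-synthetic)
  datasets without noise metadata the report carries intervals but no
  verdict.
* Structural identifiability is assumed, not analyzed; the test detects
  practical non-identifiability only through the variance criterion.
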