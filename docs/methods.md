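# Methods

## Generative models

**Detection task.** On each trial a stimulus is absent (s = 0) or present
(s = μ) with prior p(present) (default 0.5). The observer's measurement is
x ~ Normal(s, σ²); σ is the only quantity attention is allowed to change
(valid/attended: σ_val; invalid/unattended: σ_inv > σ_val). The observer
answers "present" when x > k, with k the *absolute* criterion in measurement
units. The log posterior ratio is affine in x,
LPR(x) = log prior-odds + (μ/σ²)(x − μ/2), so thresholding x is an
equivalent decision rule; the package stores all criteria in measurement
units and derives relative quantities (c = (k − μ/2)/σ, d′ = μ/σ) on
demand, never storing both, so inconsistent (k, c) pairs cannot arise.

**Embedded-category task.** The stimulus orientation is drawn from one of
two zero-mean Gaussians — narrow (category 1, SD σ_narrow) or broad
(category 2, SD σ_broad) — and observed through measurement noise
x ~ Normal(s, σ_m²). The decision rule is the symmetric two-sided
|x| > k → "category 2" (forced by the task's symmetry about 0°; a tie
x = k counts as category 1, a measure-zero convention fixed for
determinism). Marginally x | C ~ Normal(0, v_C) with v_C = σ_C² + σ_m², so
the prior-weighted densities cross at

    k*² = [log(v₂/v₁) + 2·log π] / (1/v₁ − 1/v₂),   π = p(C₁)/p(C₂),

when the bracket is positive. If the prior is extreme enough that the
bracket is non-positive, one response is always optimal; this is *reported*
as a no-interior-boundary condition, never silently clamped. k* is strictly
increasing in σ_m (the variance ratio v₂/v₁ shrinks toward 1 while both
grow), which is exactly the incentive to shift the criterion that a
symmetric-offset discrimination task lacks — there the optimal boundary
bisects the means at every noise level.

## Criterion policies

A policy maps noise level to absolute criterion. The implemented family:

| kind | k(σ) | role |
|---|---|---|
| fixed | k_ref | the "unified criterion" hypothesis (γ = 0) |
| power (γ) | k_ref·(σ/σ_ref)^γ | interpolating family; γ = 0.5 is the square-root observer |
| bayes_optimal | k_ref·(σ/σ_ref) | accuracy-maximizing under d′ matching and equal priors (γ = 1) |
| misbelief_bayes | k_ref·r off-reference | Bayesian observer believing the noise ratio is r, not the true one |

The misbelief policy is the minimal wrong-belief construction: the observer
applies the d′-matched Bayes rule but under a believed noise of
r·σ_ref whenever the true noise departs from σ_ref. r = 1 reduces exactly
to the fixed policy and r = true ratio to the optimal one, so the family
continuously connects the two hypotheses; richer wrong-belief structures
(e.g. about μ or the priors) are out of scope. With unequal priors the
linear-scaling shortcut no longer applies and the per-condition Bayes
criterion `sdt_core.bayes_criterion` should be used directly.

**IARF classification.** The inflation signature constrains a condition
pair only through k_inv < (σ_inv/σ_val)·k_val with k_val > 0. The
classifier uses a boundary tolerance of 1e−9 in criterion-ratio units —
the inequality itself is strict, and the tolerance only absorbs floating-
point error so the γ = 1 policy classifies as "boundary" rather than
flapping between sides. The region map defaults to a 251 × 251 grid over
σ-ratio ∈ [1, 3] × k-ratio ∈ [0, 2.5], wide enough to contain the three
policy lines; σ-ratios below 1 are flagged invalid (inattention is assumed
never to reduce noise).

## Synthetic observers

The simulators are the package's stand-in for the human experiments and
generate data *from the stated generative models and nothing else*: no
lapses, no guessing, no criterion jitter, no sequential effects, no spatial
display or cue-timing structure. d′ matching across attention conditions is
done analytically (μ_c = d′·σ_c) rather than by emulating a psychophysical
contrast staircase, which affects only how the matched state is reached,
not the mathematical claims about it. Consequences for interpretation:
passing tests show that the *analysis pipeline* is correct and that the
degeneracy/identifiability claims hold under the model's own assumptions;
they say nothing about model misspecification in real data (e.g. criterion
noise or lapse rates, which would bias the ML fit).

Orientation wrap-around is ignored; the generator warns if σ_broad or σ_m
exceeds 30°, where the Gaussian-on-a-line approximation becomes dubious.
All randomness derives from one integer seed via numpy `SeedSequence`
child streams (one per condition), so a trial table is bit-reproducible
from its seed.

Default embedded-category parameters (σ_narrow = 0.8°, σ_broad = 2.0°,
σ_m = 0.5°, equal priors) are package choices for a plausible desk-scale
instance of the task — small enough orientations that wrap-around is
irrelevant, a 2.5× category-SD ratio that keeps accuracy away from both
chance and ceiling, and measurement noise of the same order as the narrow
category so the optimal boundary moves appreciably over a σ_m sweep.

## Estimation and fitting

**SDT summaries.** Empirical H and F use the 1/(2N) boundary correction
(0 → 1/(2N), 1 → 1 − 1/(2N), N = trials of that truth class) before the
z-transform; exact-boundary rates reaching the transform uncorrected raise
an error rather than returning ±∞.

**Embedded ML fit.** The fit maximizes the Bernoulli log-likelihood with
kernel P(respond 2 | s) = Φ((s − k)/σ_m) + Φ((−k − s)/σ_m) over per-trial
(s, r) pairs, via L-BFGS-B on (k, log σ_m). The log parameterization keeps
σ_m strictly positive (excluding the degenerate σ_m = 0 boundary); k is
bounded below by 0. Five deterministic starts — built from k₀ = median |s|
among category-1 responses and a data-driven noise scale (0.3 × SD of s,
overridable) — guard against the k ↔ σ_m likelihood ridge. Probabilities
are clipped at 1e−12 inside the likelihood for numerical safety. Standard
errors come from the observed information (central-difference Hessian at
the optimum, delta method for σ_m); bootstrap would be more robust near
the k = 0 bound but costs orders of magnitude more time, and SEs are
reported as NaN when the Hessian is not positive definite. A dataset whose
responses are all identical (as produced by a k = 0 observer, for whom
every |x| > 0) is reported as non-identifiable rather than fitted.

**Degeneracy report.** For a measured (d′, c) the report enumerates
(μ, σ, k) = (d′σ, σ, σ(c + d′/2)) over a σ grid, each row annotated with
its implied (H, F) — identical by construction — and classifies fixed,
square-root and linear criterion ratios for the (min, max) σ pair against
the IARF, exhibiting both fixed and flexible solutions inside the region.

## Problem sizes and numerical checks

Simulation-based tests use 10⁵ trials per condition for detection-rate
convergence (3-standard-error bands via the delta method for ĉ), 2 × 10⁴
trials per ML fit with 20 seeded replicates for recovery (median relative
error thresholds 5% for k, 10% for σ_m), and brute-force oracles at 10⁻³
resolution (expected-accuracy grid) and 10⁻⁶ resolution (density-crossing
grid) for the ideal-observer boundary. Round-trip identities
(rates → summary → parameters) are checked to 1e−9; the family-degeneracy
identity of (H, F) to 1e−12.

## Known limitations

- The misbelief policy is a two-condition construction (reference vs.
  other); it is a step function of σ, not a smooth policy curve.
- Observed-information SEs are asymptotic; they are anti-conservative for
  small samples and unavailable at the k = 0 bound.
- Unequal-variance SDT for the detection task, ROC fitting, confidence
  ratings, lapse/guessing processes, and hierarchical (multi-subject)
  fitting are out of scope.
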