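# Methods

## Model

A tissue microstate is a point in gene-expression (GE) space, reduced to a
single coordinate x₁: its projection on the first principal axis v₁ of the
sample covariance of log-fold expressions ê = log₂(e/e_ref). The normal
(homeostatic) state is an attractor around the origin with r.m.s. radius Rₙ;
the tumor state is a second attractor centered at x̄₁ with radius Rₜ. The
lifetime risk of cancer in a tissue is modelled as the probability that at
least one of its N_sc stem-cell-scale microstates crosses the minimal walk
length R = x̄₁ − Rₙ − Rₜ within t stem-cell generations,
t = t₀ + m_sc·age with t₀ = log₂(N_sc).

Displacements per generation combine two processes:

* small steps δx₁ = D·r with r ~ U(−1, 1), where D = max|v₁ᵢ| is the
  largest single-gene loading of the cancer axis — a Brownian component;
* with probability μ per generation, a Lévy jump whose magnitude follows a
  Pareto law with scale D and tail exponent ν (survival (D/x)^(ν−1), x ≥ D).

Closed forms. The Brownian escape probability is taken from the Gaussian
density p(x) = √(a/π)·exp(−a x²) with a = 2/(D²t), integrated beyond R:
Erfc(√(aR²)). On the log scale this yields the regression predictor
ln(D√t/R) − 2(R/(D√t))² for ln(risk/N_sc). The Lévy escape probability is
proportional to μ·t·(D/R)^(ν−1); at ν = 2 the predictor is ln(D·t/R), and
the absolute risk is N_sc·μ′·(D/R)·t with an effective rate μ′ absorbing
the Pareto normalization. The extra risk score rescales the per-stem-cell
risk by a universal reference rate: ERS = (risk/N_sc)/(a_ref·t),
a_ref = 2×10⁻¹⁴ per generation; 1 < ERS < 6 is the band expected when
replication noise alone drives risk.

### Assumptions

* One dimension suffices: PC1 carries the normal/tumor separation (≈ half
  of the total variance in the colon cohort the geometry derives from).
* R lies deep in the jump-size tail (R/D ~ 10³ in the shipped table; a
  warning fires below R/D = 10).
* At most one large jump matters per microstate (μt ≪ 1), making risk
  linear in both μ and t.
* μ (hence μ′) is common across tissues, so it can sit in the regression
  intercept; tissue-specific μ′ is exactly what ERS quantifies.
* No fitness landscape, drift, immune removal, or age-dependence of m_sc is
  modelled.

## Key parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| age | exposure age | 80 | years (registry risks are cumulative to 80) |
| ν | Pareto tail exponent | 2 | — (expression tails show 1.6–2.0) |
| a_ref | ERS reference rate | 2×10⁻¹⁴ | per generation |
| pseudocount | added before log₂ | 0 | expression units; genes with zero normal expression are excluded instead |
| time convention | t = t₀ + m_sc·age | `with-t0` | `msc-only` (t = m_sc·age) is available but does not reproduce the reference slopes |

The time convention matters: only the t₀-inclusive convention reproduces
the reference regression slopes (0.82 Lévy; 2.1×10⁻⁵ / 1.5×10⁻⁴ Brownian)
on the shipped table, because tissues with slow turnover but many stem
cells (lung: m_sc·80 = 5.6 versus t₀ ≈ 30) are dominated by development
generations. Both conventions are exposed via `time_convention`.

## Numerical choices

* **ln Erfc.** The escape log-probability reaches −1650 for colon (z ≈ 41),
  far below floating-point underflow of Erfc itself. It is computed as
  ln 2 + log_ndtr(−z√2) via SciPy's log-scale normal CDF — one smooth
  formula, accurate to better than 10⁻⁸ relative (checked against a
  well-scaled quadrature oracle on z ∈ [0, 30]) with no asymptotic branch
  switch. The leading asymptotic −z² − ln(√π z) is provided separately for
  reference; it is only ~10⁻⁶-accurate near z = 25.
* **PCA.** Computed by SVD of the column-centered ê (grand-mean centering,
  standard PCA); projections are *uncentered* dot products ê·v₁ so the
  origin stays the normal-cloud center. The two centerings differ little
  for balanced clouds. v₁ is oriented so the mean tumor projection is
  positive; exact eigenvalue ties are broken toward the vector with
  lexicographically largest absolute components. Rₙ is measured about the
  origin, Rₜ about the tumor mean; both are 1-D radii along PC1, matching
  the one-dimensional model.
* **Gaussian-variance convention.** The analytic escape density implies
  variance D²t/4 (a = 2/(D²t)), while the uniform step law gives per-step
  variance D²/3, hence D²t/3 diffusively. The simulator validates against
  its own moment (t·D²/3) and the 4/3 ratio between conventions is asserted
  explicitly in the tests; the regression predictors inherit the analytic
  convention, where the constant is absorbed into the intercept anyway.
* **Simulator.** One generation = one small step, then the jump sub-step,
  then a single absorption check at x₁ ≥ R (0-based generation index).
  Jumps are two-sided by default, so closed-form comparisons carry an
  explicit ½ factor. The Pareto floor equals D, making the jump floor and
  step scale commensurate. Only the tumor side absorbs; there is no
  reflecting barrier at negative x₁. The RNG is numpy's seeded
  default_rng; identical config and seed give identical summaries.
* **OLS.** Unweighted ordinary least squares (scipy.stats.linregress) with
  a two-sided slope t-test, n − 2 degrees of freedom; no weighting by the
  registry dispersion (the `dev` column is an error-bar/plotting aid), no
  multiple-testing correction (one hypothesis per model). A fit needs ≥ 2
  points; a p-value needs ≥ 3. On the shipped 8-tissue table the Lévy fit
  gives Pearson r = 0.71 (r² = 0.51); claims of r ≈ 0.85 for this
  regression could not be reproduced from the table itself and are not
  asserted anywhere.
* **Risk clamping.** The linear Lévy risk estimate is unbounded; values
  above 1 are clamped with a warning rather than rejected.

## Synthetic data

`generate_cohort` plants a two-cloud geometry: in log-fold space, normal
samples are Rₙ·g·u plus isotropic N(0, σ²) noise per gene (default σ = 1),
tumor samples x̄₁·u + Rₜ·g·u plus the same noise, with u a unit direction
and g standardized latent coefficients (zero mean, unit r.m.s. — exact by
construction, so planted radii are not subject to finite-sample drift of
the latent moments). Defaults (500 genes, 50+50 samples, x̄₁ = 150, Rₙ = 12,
Rₜ = 28) emulate a colon-like cohort with well-separated clouds. Expression
is reconstructed as e = e_ref·2^ê with positive references, so the
geometric-mean stage sees strictly positive data; `with_zeros` injects
zeros to exercise the pseudocount/exclusion path, and `heavy_tail_fraction`
switches a gene subset to symmetric Pareto-tailed noise mimicking the
heavy-tailed character of real expression distributions. What the generator
does **not** emulate: count noise, library-size variation, dispersion
structure, batch effects, or gene–gene correlation beyond the planted axis.
Passing recovery tests therefore show the geometry pipeline is correct on
its own terms, not that real cohorts satisfy the model.

`generate_planted_table` draws tissue parameters from ranges spanning the
shipped table (D ∈ [0.044, 0.077], R ∈ [27, 147], N_sc log-uniform in
[6.6×10⁶, 8.7×10⁹], m_sc log-uniform in [0.07, 73]) and generates risks
from the Lévy law with Gaussian scatter on the log scale (default sd 0.5).
The default intercept −28 keeps every planted risk below 1 across the whole
parameter box, so the generative law stays exactly linear; with scatter 0
the fit recovers slope and intercept to 10⁻⁶, and across replicates OLS is
unbiased within Monte-Carlo error.

## Problem sizes

Validation runs use ensembles of 10⁵ walkers over 100–400 generations
(diffusive-variance and rare-jump escape checks, each against a 3-standard-
error band of the closed form) and 300 replicate planted-table fits; these
sizes put the Monte-Carlo error well below the tolerances being checked
while the full suite runs in a few seconds.

## Known limitations

* The regression rests on 8 tissues; the slope's standard error (0.33) is
  accordingly large, and single-tissue exclusions move the Brownian slope
  by an order of magnitude.
* Geometry parameters in the shipped table are taken as given; the
  geometry pipeline is validated on synthetic cohorts only, and raw-cohort
  preprocessing (normalization, batch correction) is out of scope.
* ERS values depend linearly on which risk compilation feeds them;
  scores computed from the shipped table differ from scores computed from
  other published risk inputs.
* The mapping from simulator generations to calendar time is left to the
  caller via m_sc; aging-related decline of m_sc is not modelled.
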