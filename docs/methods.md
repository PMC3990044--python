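# Methods

## Infection models

All models live on a single haploid locus with `K` genotypes per species
and are expressed as a `K×K` infection-probability matrix `α` (rows =
hosts, columns = parasites). MA is the identity pattern, IMA its
complement. GFG uses the nested multi-level convention: host resistance
levels `r_i = 0..K−1`, parasite virulence levels `v_j = 0..K−1`, infection
iff `v_j ≥ r_i`. This convention is chosen because it yields exactly `K`
genotypes per species at one locus, matching the simulation design; the
model registry is extensible (`register_model`) so alternative GFG
geometries or empirical matrices can be dropped in without touching any
other module. Two no-interaction controls are provided: CONST (default,
level `c = 0.5`) and ADDITIVE (`clip(β_i + γ_j, 0, 1)`; its unclamped form
has exactly zero interaction variance under every frequency pair, a
property-tested invariant).

`α` stores probabilities rather than binary outcomes so an assay error
rate can be layered on downstream without changing this module.

### Frequency-weighted decomposition

For frequencies `(p, q)` the decomposition
`α_ij = μ + a_i + b_j + e_ij` with `Σ p_i a_i = Σ q_j b_j = 0` is exact,
and `var_int = Σ p_i q_j e_ij²` is the population-level statistical G×G on
the probability scale. It is the analytic oracle for the ANOVA module and
makes the core phenomenon transparent: `var_int` of a fixed matrix
collapses as any genotype frequency approaches 0 or 1.

## Coevolution recursion

Discrete non-overlapping generations; per generation the order is
selection → mutation → drift (the standard Wright–Fisher-with-selection
scheme). Fitness is mean-field — each individual effectively meets the
entire partner population in proportion to its frequencies — which is the
standard approximation for these models and necessary for 1000-generation
runs at N = 10⁵. Host fitness is `1 − s_h · P(infected)`, parasite fitness
`1 − s_p · P(fails to infect)`; GFG cost exponents enter multiplicatively
as `(1 − τ)^level`. Mutation is symmetric at rate μ (each genotype mutates
to every other with probability `μ/(K−1)`); drift is one multinomial draw
of N per species. Both a stochastic (drift on, default) and a
deterministic mode are provided, since published figures of this kind are
consistent with either at N = 10⁵.

Initial conditions default to uniform frequencies plus a seeded
perturbation of magnitude 0.01, so deterministic runs leave the unstable
symmetric equilibrium; any initial state can be supplied. Frequencies are
clamped at 0 (tolerance 10⁻¹²) and renormalized after deterministic
updates. Identical seed and parameters give bit-identical trajectories.

## Cross-infection experiments

Isolates are sampled with replacement from the current frequency vectors
(for 30 isolates from N = 10⁴–10⁵ the finite-population correction is
< 0.3% and ignored). "Replicated five times" is read as five independent
factorial repeats sharing the same isolates — the replicate is the ANOVA's
within-cell error stratum; resampling isolates per replicate would instead
confound replicate with isolate identity. Surveys run at generations
`0, Δ, 2Δ, …` inclusive, giving 51 experiments for Δ = 20 over 1000
generations.

Each trial is Bernoulli with `π′ = α(1−ε) + (1−α)ε`. The module default is
`ε = 0`; the default *study* configuration uses `ε = 0.05`, a realistic
infection-assay misclassification rate. A nonzero ε matters twice: with
deterministic 0/1 matrices and ε = 0 every replicate of a cell is
identical, so the ANOVA error stratum is exactly zero (degenerate), and
the latent-genotype likelihood is −∞ on any discordant count.

## Variance partitioning

Response = per-cell infection count (0..trials), matching how such
experiments are scored; a per-trial binary response is available but
non-default. Method-of-moments EMS estimates are the primary estimator
(closed form, transparent, testable to 10⁻¹⁰ against a brute-force
sums-of-squares oracle): `σ²_e = MS_E`, `σ²_gxg = (MS_AB − MS_E)/n`,
`σ²_host = (MS_A − MS_AB)/(bn)`, `σ²_par = (MS_B − MS_AB)/(an)`. Negative
solutions are truncated at zero and the raw values retained — truncation
is standard practice and itself part of the detection story. Isolates are
always treated as distinct random levels even when they share a latent
genotype, because the empiricist cannot pool them.

REML is offered as a cross-check, implemented through the balanced crossed
design's stratum likelihood (the four mean squares are independent scaled
chi-squares with scales `σ²_e`, `σ²_e + nσ²_ab`, `σ²_e + nσ²_ab + nbσ²_a`,
`σ²_e + nσ²_ab + naσ²_b`; L-BFGS-B with non-negativity bounds). On
balanced data it reproduces the EMS solutions whenever those are interior,
and it is validated against statsmodels' general crossed
variance-component REML in the tests.

`expected_components` maps the frequency-weighted decomposition of the
ε-adjusted matrix into expected ANOVA components — between-cell components
scale by trials², the error component is the mean binomial variance — and
serves as the infinite-sample oracle: isolate effects are i.i.d. draws of
the decomposition effects, whose row/column centering makes the classical
EMS expectations hold exactly despite shared latent genotypes.

## Likelihood-based inference

The marginal likelihood sums over joint latent genotype assignments; rows
and columns couple, so both the exact likelihood and the exact E-step are
exponential. Choices made here:

* **Exact enumeration** (guard `K^(G+H) ≤ 10⁷`) conditions on the smaller
  margin, making the other margin independent — cost `K^min(G,H)·G·H·K`.
  It is the oracle for all fitting tests.
* **Mean-field EM** for real sizes: per-isolate genotype posteriors on the
  host and parasite margins are updated alternately, then the frequency
  vectors re-estimated from posterior means. Each sweep is coordinate
  ascent on the ELBO, asserted non-decreasing at every iteration.
  Restarts (default 10) initialize the parasite-margin posteriors with
  per-isolate Dirichlet draws — restarting only the frequency vectors is
  not enough, because the first posterior update erases them and can
  collapse all isolates onto one genotype.
* Inside the guard the EM solution is polished by Nelder–Mead on the exact
  likelihood in softmax coordinates and the exact value reported;
  otherwise the ELBO is reported and flagged (`exact=False`). With 25
  trials per pair the posteriors are near-degenerate and the bound is
  tight, which is why ELBO-based AIC ranking recovers the generating
  model.
* **ε** is fixed at 0.01 by default; optionally re-optimized (bounded 1-D
  search) between EM passes, adding one parameter.
* **CONST** needs no latent structure: its single infection probability
  has a closed-form MLE (parameter count 1).
* **K** is chosen by fitting each candidate K and comparing AIC — the
  practical reading of "estimating the number of segregating genotypes"
  without trans-dimensional sampling.
* Convergence: absolute ELBO change < 10⁻⁸, cap 500 iterations;
  non-convergence warns and reports the best value found.
* Nesting: only CONST-within-ADDITIVE is flagged for χ² likelihood-ratio
  tests; MA/IMA/GFG vs each other and vs CONST are non-nested and compared
  by AIC (ties → fewer parameters → input order).

## Study pipeline

Scenario seeds derive from the master seed via `SeedSequence` spawn keys
(scenario index, replicate), recorded in a manifest that references every
output file. The "negligible G×G" threshold for detection-failure
summaries defaults to 5% of the scenario's mean error variance —
scale-free and anchored to the one component that is stable over time; an
absolute threshold can be supplied instead. Plotting is optional and
isolated so headless runs need no graphics stack.

## What the generator does and does not emulate

The synthetic data embody: single-locus haploid genetics, mean-field
encounters, balanced complete factorial sampling, binomial trial noise and
symmetric misclassification. Real cross-infection data additionally carry
dose/environment variation, isolate-level (within-genotype) heterogeneity,
unbalanced and incomplete designs, and non-binary infection phenotypes —
so passing tests demonstrate correctness of the estimators and the
population-genetic mechanism, not robustness to those complications.

Test and acceptance runs use N = 10⁴ rather than 10⁵ with all other
parameters unchanged; the cycling regime is insensitive to this because
selection coefficients of order 0.4–0.7 dominate drift at both sizes.

## Known limitations

* With 0/1 infection matrices the within-cell error variance is bounded by
  `t·ε(1−ε)`, while the interaction component at even frequencies reaches
  `t²(1−2ε)²·var_int(α)`. At realistic assay error rates the error
  component therefore does **not** dominate the interaction component in
  scenarios that hold frequencies near uniform (notably the selection-off
  control); error dominance emerges only as a time-average under strong
  near-fixation cycling, or under graded (non-binary) infection
  probabilities. The corresponding acceptance test is kept strict and
  currently fails for the MA/IMA and selection-off scenarios.
* Mean-field EM is a variational approximation; its ELBO can in principle
  rank models differently from the exact likelihood on weakly informative
  tables (near-monomorphic surveys), where model selection is genuinely
  ill-posed anyway.
* Out of scope by design: multi-locus or diploid genetics, gene flow /
  multi-population designs, longitudinal inference, G×G×E, escalatory
  sweep models, significance testing of variance components.
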