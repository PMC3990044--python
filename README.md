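# gxglink

Simulation and inference toolkit for connecting **functional**
genotype-by-genotype (G×G) interactions — the mechanistic infection
genetics that drive host–parasite coevolution — with **statistical** G×G,
the host×parasite interaction variance component that empiricists estimate
from reciprocal cross-infection experiments.

## The problem

Reciprocal cross-infection studies challenge sampled host isolates against
sampled parasite isolates in a factorial design and partition the variance
in infection outcome into host, parasite, host×parasite and error
components with a two-way random-effects ANOVA. The host×parasite
component ("statistical G×G") is a *population-level* quantity: it depends
not only on the infection matrix but on the current genotype frequencies.
Under negative frequency-dependent selection, genotype frequencies cycle —
often close to fixation — so a population with strong functional G×G can
show negligible statistical G×G at many points in time, and strong
statistical G×G can arise without any coevolutionary selection at all.
`gxglink` makes this disconnect quantitative, and implements a
likelihood-based alternative that infers the functional model itself from
cross-infection data.

## The model

Single locus per species, `K` genotypes each. The **infection matrix**
`α[i, j] ∈ [0, 1]` gives the probability that parasite genotype `j`
infects host genotype `i`:

* **MA** (matching alleles): `α = I` — a parasite infects only the host it
  matches;
* **IMA** (inverse matching alleles): `α = 1 − I` — a molecular match
  triggers defense;
* **GFG** (gene-for-gene, nested): resistance levels `r_i = 0..K−1`,
  virulence levels `v_j = 0..K−1`, infection iff `v_j ≥ r_i`, with
  multiplicative fitness costs `(1 − τ)^level`;
* **CONST** / **ADDITIVE**: no-interaction controls.

Coevolution follows a discrete-generation Wright–Fisher recursion with
mean-field selection

```
w_h[i] = (1 − s_h · Σ_j q_j α_ij) · (1 − τ_h)^r_i
w_p[j] = (1 − s_p · Σ_i p_i (1 − α_ij)) · (1 − τ_p)^v_j
```

followed by symmetric mutation (rate μ) and multinomial drift (population
size N). Defaults mirror the standard simulation study: N = 100,000,
μ = 10⁻⁵, K = 3, strong selection s_h = 0.67 / s_p = 0.69 or moderate
s_h = 0.37 / s_p = 0.39, surveys every 20 generations with 30 isolates per
species, 5 trial exposures per pair, replicated 5 times.

Statistical G×G has an exact analytic counterpart: the frequency-weighted
decomposition `α_ij = μ + a_i + b_j + e_ij` with interaction variance
`σ²_int = Σ_ij p_i q_j e_ij²`, which is what the ANOVA estimates (scaled by
trials²) in the infinite-sample limit.

The **likelihood module** treats each isolate's genotype as latent
(`z_g ~ f`, `z_h ~ g`) and computes

```
L(f, g) = Σ_z Π_g f_{z_g} Π_h g_{z_h} Π_{g,h,r} Binom(y_ghr; t, π′_{z_g z_h}),
π′_ij = α_ij (1 − 2ε) + ε
```

maximized by a mean-field EM over genotype posteriors (exact enumeration on
small tables, used as the test oracle). Candidate models — and the number
of segregating genotypes `K` — are compared by AIC.

## Worked example

```python
import numpy as np
import gxglink as gx

params = gx.SimulationParams(model=gx.build_infection_matrix("MA", 3),
                             N=10_000, generations=1000, seed=42)
traj = gx.run_simulation(params)

design = gx.ExperimentDesign(error_rate=0.05)   # 30×30 isolates, 5×5 trials
tables = gx.longitudinal_survey(traj, design, np.random.default_rng(7))
components = gx.component_timeseries(tables)
print(components[["generation", "sigma2_host", "sigma2_parasite",
                  "sigma2_gxg", "sigma2_error"]].head(6).to_string(index=False))
```

```
 generation  sigma2_host  sigma2_parasite  sigma2_gxg  sigma2_error
          0     0.000000         0.000000    4.828763      0.227778
         20     0.000000         0.111319    4.656155      0.237222
         40     0.543234         0.177337    3.955167      0.234556
         60     0.327816         3.070835    1.742025      0.236556
         80     4.679429         0.051607    0.374315      0.250000
        100     2.759419         0.341129    0.962374      0.235333
```

Statistical G×G is large while all three genotypes segregate (generations
0–40), then collapses as the cycle approaches fixation — by generation 80
the interaction component has fallen by an order of magnitude although the
functional interaction matrix never changed. Over the full 1000
generations, 82% of surveys show negligible G×G (below 5% of the mean
error variance) in this strong-coevolution run.

Model-based inference on a polymorphic survey recovers the functional
model and the genotype frequencies:

```python
res = gx.compare_models(tables[0], [("MA", 3), ("GFG", 3), ("CONST", 3)],
                        epsilon=0.05, seed=0)
print(res.table[["model", "log_likelihood", "n_params", "aic"]].to_string(index=False))
```

```
model  log_likelihood  n_params          aic
   MA    -2783.121131         4  5574.242261
  GFG   -22995.967486         4 45999.934971
CONST   -12955.598549         1 25913.197098
selected model: MA
estimated host frequencies: [0.367 0.3   0.333]   (truth: [0.335 0.328 0.337])
```

On a near-fixation survey the same comparison selects CONST — a single
time point cannot reveal the functional model when the population is
monomorphic, which is precisely the study's point.

A console script exposes the same operations:
`gxglink simulate|survey|anova|infer|study --help`.

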