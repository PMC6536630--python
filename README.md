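# trilevel

Monte-Carlo sample-size study toolkit for **three-level longitudinal
random-effects models** — students (level 2) nested in classrooms
(level 3), each measured repeatedly over a school year (level 1).

Researchers planning a clustered longitudinal study need to know how many
classrooms and how many students per classroom are required before fixed
effects, variance components, confidence intervals and power become
trustworthy. `trilevel` answers this by simulation: it generates a large
synthetic population from published growth-curve estimates, repeatedly
draws class-level samples under a grid of sample-size and missing-data
conditions, refits the model on every sample, and scores the estimates
against the population's known values.

## The model

For measurement *i* of student *j* in classroom *k*, the response
(academic motivation) follows

```
Y_ijk = β0_jk + β1_jk·t_ijk + β2·t²_ijk + β3·Influence_ijk + e_ijk
β0_jk = δ000 + δ010·Gender_jk + δ001·Classtype_k + v0_k + u0_jk
β1_jk = δ100 + δ110·Gender_jk + δ101·Classtype_k + v1_k + u1_jk
```

with independent Gaussian random effects: residuals e ~ N(0, ε²ₑ),
student intercept/slope deviations u0, u1 ~ N(0, τ²_u0), N(0, τ²_u1), and
classroom intercept/slope deviations v0, v1 ~ N(0, σ²_v0), N(0, σ²_v1);
intercept–slope covariances are fixed at zero. `Influence` additionally
moderates `Classtype` (coefficient δ301). Estimation is by REML with
fixed effects profiled out per classroom block; inference uses Wald
intervals with standard-normal quantiles.

Estimation quality is summarised per condition by

* **peb** — parameter estimation bias, `mean((θ̂_k − θ)/θ)`; |peb| > 0.10
  flags a biased parameter,
* **coverage** — share of 95% intervals containing the truth (acceptable
  band 91–98%),
* **power** — share of intervals excluding zero,
* **ICC** — intraclass correlations from the empty model, and approximate
  effect sizes `β/√ε²ₑ` (binary), `2·β·SD/√ε²ₑ` (continuous) and
  `2·√(ICC/(1−ICC))` (random parts).

## Worked example

```python
import trilevel as tl

# 3000 classrooms, 55000 students, 5 occasions at months 0, 1.5, 4, 7, 10
pop = tl.generate_population(seed=tl.population_seed(1, "COM"))
truth = tl.derive_true_values(pop)
print(round(truth.varcomps["resid"], 4), round(truth.icc.rho_level2_a, 3))

cond = tl.Condition(n2=15, n3=15, pattern="COM", replicates=300)
summary = tl.run_condition(pop, truth, cond, master_seed=1)
print(round(summary.fixed["time"]["peb"], 3),
      round(summary.fixed["time"]["power"], 3))
```

prints

```
0.2599 0.445
-0.051 0.79
```

i.e. the refitted population recovers the generating residual variance
0.2622 to sampling precision and a level-2 ICC of about 0.44; with 15
students in each of 15 classrooms the linear time effect shows only
small relative bias (|peb| = 0.05, below the 0.10 threshold) and is
detected in about 79% of replicates — just under the 80% power
convention, matching the finding that this effect needs either more
students per class or more classes.

The same pipeline is scriptable from the shell:

```bash
trilevel generate-population --seed 1 --out pop.csv
trilevel derive-truth --population pop.csv --out truth.json
trilevel run-condition --population pop.csv --truth truth.json \
    --n2 15 --n3 35 --pattern COM --replicates 200 --seed 1 --out cond.json
trilevel run-study --config study.yaml --out results/
```

## Layout

| module | contents |
| --- | --- |
| `trilevel.params` | generating parameters and population structure |
| `trilevel.population` | population generator, fixed-part predictor, CSV I/O |
| `trilevel.design` | condition grid, class sampling, missingness patterns |
| `trilevel.lmm` | three-level REML/ML engine, Wald intervals |
| `trilevel.metrics` | peb, coverage, power, ICC, effect sizes |
| `trilevel.study` | truth derivation, condition runs, study driver |
| `trilevel.cli` | `trilevel` command-line interface |

See `docs/methods.md` for the modelling and numerical details.
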