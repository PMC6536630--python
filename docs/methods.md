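# Methods

## The generating model

The synthetic population mimics a school-year longitudinal study:
classrooms (level 3) contain students (level 2) who report their academic
motivation at five occasions (level 1), at 0, 1.5, 4, 7 and 10 months
after baseline. The response for occasion *i* of student *j* in class *k*
is

    Y_ijk = fixed(t, Influence, Gender, Classtype)
            + (v0_k + u0_jk) + (v1_k + u1_jk)·t_ijk + e_ijk

where the fixed part is a quadratic growth curve with a time-varying
continuous covariate (perceived teacher influence), a student-level binary
covariate (gender, girl = 1), a class-level binary covariate (classtype,
heterogeneous-ability = 1), the cross-level interactions classtype×time
and gender×time, and the moderation influence×classtype. All random
effects are independent zero-mean Gaussians; intercept–slope covariances
are zero by construction.

Default generating values (response units; months for time):

| parameter | value | | parameter | value |
| --- | --- | --- | --- | --- |
| intercept | 3.2032 | | ε²ₑ (residual) | 0.2622 |
| time | 0.0547 | | τ²_u0 (student intercept) | 0.1950 |
| time² | −0.0039 | | τ²_u1 (student slope) | 0.0009 |
| influence | 0.1493 | | σ²_v0 (class intercept) | 0.0041 |
| gender | 0.0072 | | σ²_v1 (class slope) | 0.0002 |
| classtype | 0.2946 | | P(girl) | 0.56 |
| classtype×time | 0.0092 | | P(heterogeneous) | 0.52 |
| gender×time | 0.0056 | | influence mean / SD | 0.42 / 0.36 |
| influence×classtype | −0.1514 | | | |

The default population holds 3000 classrooms — 1000 each with 5, 15 and
35 students — hence 55 000 students and 275 000 observations. The
expected response mean under these values is 3.541 (analytic moment
expansion), and an empty-model decomposition of a generated population
gives intraclass correlations of roughly 0.05 (classes) and 0.44
(students including classes).

Deliberate generator choices where the design was open:

* **Influence is drawn independently per occasion.** Only its marginal
  mean and SD are specified; no within-student autocorrelation is added.
  Real influence reports would be serially correlated, so the level-1
  covariate here is "noisier" than real data in a way that does not
  affect the marginal model.
* **Influence is not truncated** even though it plays the role of a
  bounded score; it is modelled as an unbounded normal.
* **Zero intercept–slope covariance at both levels**, in generation and
  in estimation (the estimation switch for free covariances is not
  implemented; diagonal structure is a structural assumption of this
  package).
* **Time is raw months**, time² its raw square, no centering; the implied
  predictor SDs (≈3.63 for time, ≈37.5 for time²) match this coding.
* Class and student identifiers are consecutive integers assigned in
  generation order, so a seed fully determines every identity.

What passing tests on this generator do *not* show about real data:
balanced designs only (every class in a stratum has the same size, every
student starts with all five occasions), exactly normal random effects,
and missingness that is genuinely MCAR. Conclusions about, say, MNAR
dropout or unbalanced classrooms are out of scope.

## Design conditions and missingness

The study grid crosses students-per-class n2 ∈ {5, 15, 35}, classes
n3 ∈ {15, 35, 55} and four missingness patterns (36 cells, default 1000
replicates each). Classes are drawn uniformly without replacement from
the matching class-size stratum; draws are independent across replicates.

* **COM** — complete data.
* **DrOP2 / DrOP3** — round(0.20·students) students, chosen uniformly per
  sample, lose their last two / three occasions (8% / 12% of rows).
* **MCAR** — by default 20% of all occasion-level records are deleted
  uniformly. The alternative student-level reading (20% of students each
  losing a uniformly chosen non-empty subset of occasions) is available
  via `MissingnessPattern(student_level=True)` /
  `StudyConfig(mcar_student_level=True)`; results under the two readings
  should be reported side by side, never merged. The record-level default
  removes the most data (20% vs. 8–12%), consistent with power dropping
  most under MCAR in this design.

Counts of affected students/records use banker's rounding (ties to even).
A student may lose all rows under MCAR; the engine tolerates one-row and
zero-row students.

## Estimation

The engine fits the three-level Gaussian LMM by REML (ML optional). Per
classroom k the marginal covariance is

    V_k = Z3_k G3 Z3_k' + blockdiag_j(Z2_jk G2 Z2_jk') + σ²ₑ I

with diagonal G3 and G2. Classes are independent, so every likelihood
quantity is accumulated per class; the full-population covariance is never
formed. Classes sharing a per-student occasion structure share one
Cholesky factorisation of V_k/σ²ₑ, which makes the 275 000-row population
fit take seconds per deviance evaluation.

Numerical choices:

* Optimisation over θ_i = sd_i/σₑ ≥ 0 (relative standard deviations);
  fixed effects are profiled out by GLS and σ²ₑ analytically, exactly as
  in the standard profiled REML criterion. The zero boundary is
  reachable; a fit with any sd below 1e-6 × sd(response) is flagged
  *singular* but kept.
* L-BFGS-B from two deterministic starts — a moment-based start from a
  within/between decomposition of OLS residuals, and an all-ones start —
  taking the lower criterion. The second start guards against the rare
  flat-region misconvergence in boundary-heavy problems. If the
  gradient-based optimiser reports failure (typically a line search on a
  flat boundary region), a Nelder–Mead polish runs from the best point;
  the fit counts as converged when the polish cannot improve the
  criterion by more than 1e-3 deviance units.
* Non-convergence is reported (`converged = False`), never raised;
  rank-deficient fixed designs (e.g. a small sample in which every class
  has the same classtype) raise a structured linear-algebra error and are
  excluded by the orchestrator.
* Standard errors come from σ̂²ₑ(X'W⁻¹X)⁻¹ at the optimum; confidence
  intervals are Wald with standard-normal quantiles (not t), matching the
  interval definition the evaluation metrics assume.
* The restricted likelihood includes its full constant, so the criterion
  is directly comparable to lme4's `REMLcrit`; the suite verifies
  agreement with lme4 to 1e-4 relative on 50 datasets and against a dense
  multivariate-normal oracle to 1e-6 on small instances.

## Evaluation metrics

peb is the signed mean relative deviation over converged replicates;
non-converged replicates are dropped and counted (`n_excluded`), and a
condition with more than 20% exclusions carries a quality warning.
Singular-but-converged fits are retained, matching common mixed-model
practice. Coverage is judged against the 91–98% band; power counts
intervals excluding zero.

Effect sizes follow the "coefficient relative to residual spread"
convention: β/√ε²ₑ for binary predictors, 2·β·SD/√ε²ₑ for continuous
ones. Two published-formula ambiguities are resolved in favour of the
values the source tables actually contain: the denominator is the
residual *standard deviation* (dividing by the variance reproduces none
of the published values), and the random-part effect size is
2·√(ICC/(1−ICC)) (the literal 4·ICC/(1−ICC) is available behind the
`literal=True` flag; the default is its square root for every ICC). One
documented rounding discrepancy remains: the quadratic-time entry prints
−0.55 while the formula yields −0.556.

## Orchestration and reproducibility

True values are the *population-fit* estimates (full model for fixed
effects and variance components, empty model for ICCs), not the
generating parameters: sampling bias is measured against what the model
estimates on the full population. With per-pattern regeneration (the
default) each missingness pattern receives its own population and truth;
a shared-population switch exists for variance-reduction experiments.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawn keys. Population streams are keyed by
pattern; replicate streams are keyed by the condition's identity
(n2, n3, pattern) and replicate index, so any subset of conditions can be
recomputed in any order with bit-identical results. Replicates run
serially; per-condition results are cached as JSON so an interrupted
study resumes where it stopped.

## Problem sizes used by the tests and the acceptance script

The full 36 × 1000 study is supported but the shipped checks use reduced
Monte-Carlo sizes chosen to keep tolerances meaningful: 200 replicates
for the 15/35 bias condition and 300 for the 5/15, 15/15 and 35/15
conditions, with the full 3000-class population regenerated and refitted
for truth. At these sizes the Monte-Carlo standard error is ≈0.01 for
fixed-effect peb, ≈2–3 percentage points for power, and ≈0.3 for the
level-3 intercept-variance peb.

## Known limitations

* The level-3 random-intercept variance is tiny (σ²_v0 ≈ 0.004) relative
  to its estimator's sampling noise in small designs (sd ≈ 0.015 at
  n2=5/n3=15). Its relative bias is therefore extremely sensitive to the
  population realisation: across population seeds the 5/15 peb ranges
  roughly from 0.7 to 3.7 around a mean near 1.7. Any single published
  number for this cell is one draw from that distribution; comparisons
  should use wide tolerances or aggregate several populations.
* Only diagonal random-effects covariance structures are fitted.
* No MAR/MNAR mechanisms, no unbalanced class sizes within a stratum, no
  crossed random effects, no non-Gaussian outcomes, and no p-values (the
  evaluation is built on intervals, not tests).
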