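# Methods

## The model

A population of `n` subjects carries a primary disease with prevalence
`d`. Each of `K` binary symptoms occurs independently of the others'
*causes* but with a shared dependence structure: a non-diseased subject
presents a given symptom with baseline incidence `ir`, a diseased
subject with the at-risk incidence

```
p1 = min(ir * rr, 1)
```

where `rr` is the risk ratio. The cap at 1 defines two regimes used as
strata everywhere: *uncapped* (`ir * rr < 1`) and *capped*
(`ir * rr >= 1`), where every diseased subject presents every symptom. A
second, *associated* disease has the same marginal prevalence `d`,
correlates with the primary disease at `rho_dd`, and causes no symptoms;
it probes how much diagnostic accuracy a symptom count has for a disease
that is merely correlated with the symptoms' cause.

For a single symptom the 2x2 table gives closed forms:
sensitivity `= p1`, specificity `= 1 - ir`, and for the binary rule's
three-point ROC, `AUC = (sens + spec)/2 = 0.5 + (p1 - ir)/2`. With
`rr = 1` the symptom is uninformative (`AUC = 0.5`); with `rr < 1` the
AUC is below 0.5 and is reported as such — no orientation flip is
applied anywhere in the package, because the sub-0.5 regime is a result,
not an artifact. In the capped regime sensitivity and NPV are exactly 1
and `AUC = 1 - ir/2`. Note that in the uncapped regime the AUC
*increases* with `ir` when `rr > 1` (net effect `ir (rr - 1) / 2`);
monotone decrease in `ir` holds only for `rr <= 1` and in the capped
regime. Two-symptom rules ("both present" / "at least one present")
reuse the same algebra with joint rates `(ir_both, rr_both)` /
`(ir_one, rr_one)` supplied by the user or estimated empirically;
no analytic bridge from the pairwise symptom correlation to the joint
rates is offered, and rules over three or more symptoms are handled by
simulation only.

## Correlated-binary generation

Symptoms within a disease-status group are exchangeable with pairwise
phi (binary Pearson) correlation `rho_ss`; the two groups are generated
independently with the same `rho_ss` (similar baseline correlations
among diseased and non-diseased is a model assumption). Generation uses
latent-Gaussian thresholding with a one-factor equicorrelated latent
structure: `X_i = sqrt(r) W + sqrt(1 - r) E_i`, symptom present iff
`X_i < Phi^-1(p)`. The latent correlation `r` is solved by `brentq` so
the resulting *phi* correlation equals the target:

```
Phi2(z, z; r) = p^2 + rho * p (1 - p),   z = Phi^-1(p)
```

with the equal-threshold bivariate-normal orthant probability evaluated
in closed form via Owen's T function,
`Phi2(z, z; r) = Phi(z) - 2 T(z, sqrt((1-r)/(1+r)))` (exact; verified
in tests against scipy's numerical bivariate-normal CDF). Solver
tolerance: `xtol = 1e-13` on `r`, giving phi error well below 1e-6.
With equal marginals any phi in `[0, 1)` is attainable (phi runs
continuously from 0 at `r = 0` to 1 as `r -> 1`), so feasibility errors
can only arise from out-of-range inputs; the bracket is still checked
defensively and failures name the attainable bound. The two disease
vectors use the same machinery with `k = 2` at marginal `d`.

The choice of the *phi* scale for the targets is a design decision: it
makes the assumed correlation directly comparable to the observed
(phi-scale) correlations that the meta-models regress on. A
latent-scale (tetrachoric) convention would attenuate the realized
binary correlations nonlinearly in the marginals. This choice matters
for one downstream number: the overall-symptom-correlation meta-model
fits our simulations almost perfectly (adjusted R² ≈ 0.99) because the
observed correlation is nearly linear in the assumed measures under
phi targeting, whereas a latent-scale mechanism would leave more
unexplained curvature.

Reproducibility: each cohort derives three deterministic sub-streams
(diseases, symptoms of the diseased, symptoms of the non-diseased) from
a single root seed; identical measures + seed give bit-identical
cohorts.

## What the generator does and does not emulate

It reproduces the study's idealized cohorts: perfectly measured disease
status and symptoms, homogeneous `ir` and `rr` across symptoms,
exchangeable symptom correlation, at most two diseases, one of which
causes all symptoms. Real data violate all of these: heterogeneous
per-symptom rates, multi-cause symptoms, reporting error,
non-exchangeable correlation structure. Passing tests therefore
validate the method's behaviour under the stated model, not its
performance on real cohorts.

## ROC analysis of symptom counts

Subjects are scored by their symptom count over the first `k` columns
(`k = 1..K`; under exchangeability any nested subset is
distributionally equivalent, and first-`k` is deterministic). Cutpoints
are the half-integers `k - 0.5` for `k = 0..K+1`, so "threshold 5.5"
means "6 or more symptoms", and the bounding cutpoints supply the ROC
endpoints (1,0) and (0,1). AUC is computed as the tie-credited
Mann–Whitney probability over case–control pairs, which equals the
trapezoid area under the empirical ROC exactly (property-tested). The
95% CI is DeLong's structural-components variance with a normal
approximation, computed via midranks and verified against explicit
component enumeration to 1e-10; degenerate inputs give a zero-width
interval. The operating point maximizes the absolute Youden index
`|sens + spec - 1|`, ties broken toward the smallest threshold (the
tie-break is not specified by the study; smallest favours sensitivity).

Across `k`, the extremal AUC is the maximum when `rr >= 1` and the
minimum when `rr < 1` (the `rr = 1` case is assigned to the maximum
branch; all CIs overlap there, so the assignment is inconsequential).
Per-`k` CIs are flagged when they overlap the extremal AUC's CI. Best
operating points are computed for every `k`; the per-record "best set"
reported in the results tables is the one at the extremal `k`.

A practical caveat established during testing: at the worked-example
configuration (`d = 0.05, ir = 0.1, rr = 2, n = 10,000`) the Youden
index gap between cutpoints 5.5 and 6.5 (~0.018) is comparable to its
sampling error at ~500 cases (~0.015), so a single cohort picks 6.5
roughly one seed in eight. `count_rule_operating_point` therefore
estimates the threshold as the modal best cutpoint over replicate
cohorts (default 10, the study's replicate count) and reports mean
sensitivity/specificity at that fixed threshold.

## Experiment grid

The full factorial crosses `rho_dd in {0, 0.3, 0.7}`,
`d, ir in {0.05, 0.1, 0.2, 0.4, 0.8}`, `rr in {0.5, 1, 2, 5, 10, 25}`
and `rho_ss in {0, 0.4, 0.8}`: 1,350 configurations, by default with
10 replicates of 10,000 subjects and 40 symptoms each. Per-record seeds
are sha256 hashes of the configuration + replicate, XORed with the base
seed and reduced below 2^31, so any sub-grid or resumed run reproduces
the full run's records exactly, independent of execution order.
Infeasible or degenerate cells are recorded as failed with a reason,
never dropped; each record also carries a `quality_ok` flag (empirical
prevalence and mean baseline incidence within 4 binomial SEs of the
assumptions, the study's own simulation-quality check).

Scaled-down mode is first class. The acceptance analyses use one
replicate of 5,000 subjects per configuration over the full 1,350-cell
grid (~2 minutes on one CPU); the structural unit tests use smaller
grids still. Coefficients of the analytic-identity meta-models are
insensitive to this scaling because they are identities plus shrinking
Monte-Carlo noise.

## Meta-models

Per-record outcomes are regressed by OLS (statsmodels) on the *assumed*
measures — disease correlation, `d`, `ir`, `rr`, at-risk incidence,
baseline symptom correlation — separately in the uncapped and capped
strata. In the capped stratum the at-risk incidence is constant at 1
and is omitted from the covariate set. The associated-disease model
adds the four disease-correlation interactions. The observable-measures
model regresses per-(record, k) AUCs on the *observed* overall symptom
correlation, observed overall symptom incidence, and `k`, over all risk
ratios and over `rr > 1`; its unit of analysis is one (simulation, k)
pair, the only reading under which the number of symptoms varies within
the fit. Constant or rank-deficient covariates are dropped with a
warning naming them. Raw two-sided t p-values and t-based 95% CIs are
reported without multiple-testing correction, matching the source
tables. One observation per record (replicates are not pooled into
per-configuration means).

Expected structure, all computed by the test suite and acceptance
script on the scaled grid: sensitivity ~ at-risk incidence with
coefficient 1; specificity ~ baseline incidence with coefficient −1;
single-symptom AUC with intercept 0.5 and the (−0.5, +0.5) pair on
baseline and at-risk incidence, all with adjusted R² ≈ 1; the
overall-correlation and associated-disease models fit closely
(≈ 0.96–0.99 here; the published counterparts are 0.89 and 0.96, the
gap being the correlation-scale convention discussed above — for the
extremal-AUC models the published footer values 0.79/0.71 additionally
disagree with the 0.83/0.80 quoted in the accompanying prose, and we
simply report our fitted values); the observable-measures model
explains almost nothing (≈ 0.08 here, ≤ 0.03 published).

## Numerical and degenerate-input choices

* Capped cohorts: the diseased block is written as all-ones directly
  (no latent draw); empirical at-risk incidence is exactly 1.
* Zero-variance symptom columns (possible in tiny cohorts) propagate as
  NaN into correlation summaries and are excluded by `nanmean`.
* Cohorts with zero diseased or zero non-diseased subjects are rejected
  by `summarize_cohort` (risk ratio undefined).
* A rule that never fires (`ir_both = 0`) has undefined PPV, returned
  as NaN; its observed-pattern odds are 0.
* OLS requires `n > p + 1` after covariate drops and excludes rows with
  non-finite values.

## Known limitations

* The correlation-scale convention of the original simulations is
  unverifiable; results that depend on it (overall-correlation model
  fit) match in order but not to the second decimal.
* No per-symptom heterogeneity in `ir`, `rr`, or correlation; no more
  than two diseases; no continuous severity scores; no partial AUC,
  smoothing, or bootstrap CIs.
* The associated disease's marginal prevalence is set equal to `d`
  (unstated in the source design; it enters results only through its
  correlation with the primary disease).
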