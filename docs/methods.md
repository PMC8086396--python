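# Methods

This note records the statistical procedures the package implements, the
choices made where the procedure was genuinely open, the design of the
synthetic-data generator, and the limits of what the test suite shows.

## Scoring model

Part 2 of the CAMDEX-DS informant interview is codified as 54 ordinal items
(levels 0/1/2 = no / slight / great deterioration) in four sections with
7/11/15/21 items, so section maxima are 14/22/30/42 and the total maximum is
108. Subscores are plain sums within sections; the total is the sum of the
subscores. The item *identities* are instrument content and are not
reproduced: the built-in codification table uses placeholder labels with the
correct section structure, and a user table (CSV/JSON with `item_id`,
`section`, `label`) can be loaded in its place. Records missing any item are
rejected by default; an explicit `missing_policy="zero"` scores missing
items as "no deterioration" (no other imputation is offered, since none is
defined for the instrument).

Threshold rules use the strict convention *score > cut-off*. Derived
cut-offs are half-integers (midpoints between observed integer scores), so
the partition is unambiguous; on integer scores "> 6.5" and ">= 7" are the
same rule.

## Group comparison

Kruskal–Wallis H is computed on average ranks with the pooled tie
correction 1 − Σ(t³−t)/(N³−N) (scores are small integers, so ties are
heavy) and referred to χ² with k−1 df; a pooled sample with all values
identical returns H = 0, p = 1 rather than an error. The effect size is
ε² = H/(n−1), clipped to [0, 1]. Dunn's post-hoc z for groups i, j is the
mean-rank difference over √(A(1/nᵢ+1/nⱼ)) with A = N(N+1)/12 −
Σ(t³−t)/(12(N−1)); p-values are two-sided normal, Bonferroni-multiplied by
the number of pairs (6 for four groups) and capped at 1. Demographic
variables (e.g. sex) must be numerically coded by the caller; the pipeline
codes female/male as 1/0.

## Threshold derivation

Candidate cut-offs are the midpoints between consecutive distinct pooled
scores plus sentinels outside the observed range, so the ROC always
includes (sens 1, spec 0) and (sens 0, spec 1). The AUC is computed by the
rank-sum identity (ties half-credited). The cut-off maximising
J = sens + spec − 1 is selected; when several cut-offs tie, the smallest
wins (maximising sensitivity) — the tie rule is exposed
(`tie_break="smallest"|"largest"`) because the choice is conventional.
J is stored in [0, 1] and reported ×100.

Interval estimation follows a two-regime rule: for AUC > 0.90 the Wilson
score interval is applied to the AUC treated as a proportion, with
`effective_n` defaulting to the *full cohort size* rather than the size of
the two compared groups — an unusual choice, but the one that reproduces
the reference intervals for this instrument (every published CI pair at
n = 85 matches to 3 dp; the bound printed as 0.999 for AUC 0.998 is exactly
0.9999, i.e. capped in print just below 1). The default is configurable and
the interval method actually used is recorded per row. For AUC ≤ 0.90 a
DeLong-type asymptotic interval from placement-value variances is used; its
empirical coverage is checked by simulation in the test suite (~95% at
n = 80 per group under a normal shift model).

## Imaging association

The partial Spearman correlation is the standard rank-then-residualise
construction: all variables (including covariates) are converted to average
ranks, the x and y ranks are residualised on the covariate ranks plus an
intercept by least squares, and the Pearson correlation of the residuals is
taken. This equals the precision-matrix partial correlation of the 4×4 rank
correlation matrix (verified in the tests). P-values use a t reference with
n − 2 − k df; an exact Monte-Carlo permutation p is available for small
samples (`method="permutation"`). Intellectual-disability level is coded
ordinally (mild = 1, moderate = 2, severe = 3). The Bonferroni family is
the set of regions supplied for one measure (68 for the default
hemisphere-qualified Desikan–Killiany parcellation); the family size m is
recorded in every output row. Whether the original analysis rank-transformed
covariates before residualising is not documented; ranking them is the
internally consistent choice and is what makes the estimate invariant to
monotone covariate transforms.

Participants without imaging are excluded from this stage only, mirroring
an imaging subcohort design; the overlap count is checked and reported.

## Synthetic-data generator

The generator emulates the study population the pipeline is designed for: a
cohort of 85 adults with Down syndrome in four clinician-labelled groups
(asymptomatic 49, mental-health 15, prodromal 10, dementia 11), with the
prodromal/dementia groups older (truncated-normal ages, means 51/54 vs 38),
only mild/moderate intellectual disability, and an imaging subcohort of 39.

Item responses are drawn independently per item from a group × section
probability triple over {0, 1, 2}. The default triples were calibrated once
against the study conditions the pipeline assumes, in this order of
priority:

1. group mean totals near 1/5/10/30 with strict severity ordering, the
   mental-health group elevated only in Sections C1/C2 (behavioural overlap
   with dementia) and only mildly in Section B;
2. the prodromal-vs-asymptomatic comparison genuinely overlapping, with a
   population Youden index of 0.824 at its optimal cut-off — matching the
   reference operating point for that comparison (Youden ≈ 82) — so that
   cut-off recovery from finite cohorts is meaningful;
3. population-optimal cut-offs near the instrument's published ones.

The frozen defaults give mean totals 1.9/5.6/7.5/30.0 and population
boundaries 4.5 (prodromal vs asymptomatic), 10.5 (dementia vs
asymptomatic) and 5.5 (Section B, dementia vs mental-health). Targets (2)
and (3) trade off against (1): with items independent given the group, the
per-item variance is bounded, so a dementia distribution centred at 30
cannot reach down to an asymptomatic tail near 7 — the dementia-vs-
asymptomatic comparison is therefore near-separated (as it effectively was
in the reference data, AUC 0.998) and its empirical cut-off falls mid-gap
rather than at a stable density crossing. Parameter-recovery checks
consequently use the prodromal comparison.

Because items are independent given the group, the exact pmf of any section
or total score is a convolution of three-point distributions;
`planted_boundary` maximises the population Youden index over half-integer
cut-offs (same tie rule as the empirical derivation) and defines the
generator's "true" cut-off for recovery tests. An optional shared
latent-severity tilt (`latent_severity_sd`) induces within-participant item
correlation via a log-odds reweighting of each triple; it is off by default
because the real item covariance is unknown, and the exact-pmf machinery
refuses to run when it is on.

The imaging generator subsamples 39 participants and sets each region to
baseline + slope × z(total) + Gaussian noise, with positive slopes for
amyloid binding (baseline 0.60, slope 0.60 per SD, noise SD 0.12; values
floored at −0.45, since BP_ND may be slightly negative from measurement
noise) and weak negative slopes for cortical thickness (baseline 2.5 mm,
slope −0.08, noise SD 0.12, floored at 0.2 mm). The default planted amyloid
regions are right medial orbitofrontal and bilateral superior temporal;
planted effects yield partial ρ ≈ 0.83, chosen large enough that the
planted set is recovered as exactly the Bonferroni-surviving, top-|ρ|
regions in ≈ 95% of seeds (effects at the borderline strength reported for
real data, ρ ≈ 0.4–0.6, sit at the survival threshold for n = 39 and m = 68
and cannot be recovered reliably — that borderline character is why only 3
of 34 raw-significant regions survived correction in the reference
analysis). Thickness effects are deliberately weak (partial ρ ≈ −0.3):
reliably negative in sign but rarely surviving Bonferroni, mirroring the
reference thickness findings.

What the generator does *not* emulate: item-level covariance beyond the
optional single latent factor, informant/rater effects, longitudinal
change, spatial correlation between neighbouring cortical regions, and any
dependence of imaging noise on age or disability level. Passing recovery
tests therefore shows the pipeline recovers structure *of this kind*; it
does not validate the instrument on real populations.

## Numerical and edge-case choices

- Youden ties: smallest qualifying cut-off (prefer sensitivity); exposed.
- All-identical pooled data: H = 0, p = 1 returned, not raised.
- Wilson bounds are clamped to contain p̂ and [0, 1] against floating-point
  residue at degenerate p̂.
- Partial correlation refuses constant-after-ranking inputs and
  rank-deficient covariate designs (naming the collinear columns), and
  requires n ≥ k + 3.
- Ages are drawn by rejection from a normal until inside the configured
  range, then rounded to integer years.
- Report rounding: 3 dp for AUC/CI/ρ/ε², 1 dp for Youden×100.

## Problem sizes in the checks

The simulation-based checks run at the study's own scale: cut-off recovery
over 200 generated cohorts of n = 85; imaging-signal recovery over 100
cohorts with 39-participant subcohorts and 68 regions; Kruskal–Wallis null
calibration with 5,000 replicates at group sizes 49/15/10/11 (binomial
3σ acceptance band around the nominal 5%); Dunn's test against a
20,000-draw permutation oracle; family-wise error of the all-noise imaging
analysis over 100 seeds against the upper 99.9% binomial envelope of 5%.

## Known limitations

- The default codification table is structurally faithful but uses
  placeholder item labels; analyses that depend on *which* items moved are
  out of reach until a real table is supplied.
- The Wilson interval applied to an AUC with full-cohort n is a
  reproduction choice, not a recommendation; for AUC ≤ 0.90 the DeLong
  interval is the statistically conventional option and the two regimes can
  disagree near the 0.90 boundary.
- Empirical Youden cut-offs from 10-participant case groups are inherently
  variable (±1 point around the population optimum in ~93–95% of seeds
  under the default generator); cut-offs derived from cohorts of this size
  should be reported with that variability in mind.
- ε² is attached to any Kruskal–Wallis result, including demographic
  contrasts on binary codings, where its interpretation is loose.
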