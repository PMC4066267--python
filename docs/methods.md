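# Methods

`vmlong` implements a longitudinal analysis of vaginal 16S rRNA gene survey
data from pregnant women: community-state typing, per-phylotype differential
abundance between term and preterm deliveries, gestational-age trend
analysis, and Shannon-diversity comparison — together with a synthetic
cohort generator that provides ground truth for validating every stage.

## Data model

The unit of analysis is a taxon-by-sample table of integer read counts
(wide TSV; rows samples, columns phylotypes) plus per-sample metadata
(subject, group `term`/`preterm`, gestational age in weeks, total reads).
Totals are recomputed from the count table at load; a metadata `total_reads`
that disagrees with the row sum is an error, and gestational ages must be
strictly increasing within a subject.  Only phylotypes present (count >= 1)
in at least 25% of samples enter the model-based analyses; the boundary is
inclusive.  Samples with missing metadata are rejected at load rather than
imputed.

## Community state types

A sample's *community state* is its relative-abundance vector p.  Pairwise
dissimilarity uses the Jensen-Shannon divergence

    D_JS(p, q) = [D_KL(p, a) + D_KL(q, a)] / 2,   a = (p + q)/2,

with D_KL in base-2 logarithms, so D_JS is 0 for identical states and
exactly 1 for states with disjoint support (a natural-log version would be
bounded by ln 2 instead).  Terms with p_i = 0 contribute zero; D_KL itself
returns `inf` on support violations rather than a silent large number, and
D_JS is always finite because the mixture a has support wherever p or q
does.  The square root of D_JS (the Jensen-Shannon distance) is a metric
and is exposed as an option.

Community state types (CSTs) come from agglomerative clustering with the
Ward criterion applied to the precomputed JSD matrix (classical Ward via
the Lance-Williams update, treating the dissimilarities as squared-
Euclidean surrogates — `scipy.cluster.hierarchy.linkage(method="ward")` on
the condensed matrix).  Whether to cluster the divergence or its square
root is a genuinely open choice; JSD is the default and the distance is a
config option.  The tree is cut at k = 3 by default, matching the three
types observed in pregnancy cohorts, with k configurable.  Clusters are
named by the dominant indicator taxon of their mean composition —
CST I (*Lactobacillus crispatus*), CST III (*L. iners*) — and a cluster
whose mean total *Lactobacillus* abundance falls below 0.5 is labeled
IV-B (diverse anaerobes: *G. vaginalis*, BVAB1, *A. vaginae*,
*Megasphaera*).  Anything else is labeled `other`.

## Count-model ladder

Differential abundance is assessed one phylotype at a time by regressing
read counts on the covariate of interest with three nested model families:

* **PLME** — Poisson mixed model;
* **NBLME** — negative-binomial mixed model (NB2; size k, Var = mu + mu²/k);
* **ZINBLME** — zero-inflated NB: a point mass at zero with probability pi
  mixed with the NB component.

All three share a natural-log link, an offset log(total reads) — so
coefficients describe *relative* abundance — and a subject-level random
intercept b ~ N(0, sigma_b²) on the count mean.  The random effect never
enters the zero-inflation part, and the zero-inflation component is
intercept-only.

The marginal likelihood integrates b out per subject with **adaptive
Gauss–Hermite quadrature** (default 25 nodes): nodes are centered at the
per-subject posterior mode and scaled by the local curvature, both obtained
by a damped, vectorized Newton search warm-started from the previous
evaluation.  The adaptive likelihood is validated against dense-grid
trapezoid integration (agreement to 1e-6 over seeded instances of all
three families).  `sigma_b < 1e-6` falls back to the closed-form
independent likelihood.

Maximization is quasi-Newton (L-BFGS-B) on an unconstrained scale
(log sigma_b, log k, logit pi), started from a Poisson-GLM fit
(method-of-moments k, excess-zero pi, sigma_b = 0.5) plus jittered
restarts (3 by default; simulation studies use fewer).  Convergence uses a
relative-objective tolerance of 1e-11; solutions with sigma_b or pi at
their bound are flagged `boundary` and the bounded parameter is excluded
from the observed-information matrix.  Standard errors come from the
inverse observed information (central-difference Hessian on the natural
scale); Wald 95% CIs and normal p-values follow.  t-based intervals with
subject degrees of freedom would be slightly wider at this design's size;
Wald-normal is used throughout.

Model choice is by AIC = 2·(parameters) − 2·(log-likelihood) with
parameter counts p+1 / p+2 / p+3 for PLME / NBLME / ZINBLME.  Ties break
toward the smaller family; non-converged families are simply excluded from
the comparison, and a phylotype with no converged family is reported unfit
and dropped from the multiple-testing family.

## Differential abundance and reporting

The group analysis fits the ladder with fixed effects {intercept, group}
(term = 0, preterm = 1).  The selected model's group coefficient beta is
reported as a **signed fold change**: exp(beta) when beta >= 0, and
−exp(−beta) when beta < 0 — i.e. a fold *decrease* is reported as its
magnitude with a minus sign (beta = −0.864 prints as −2.4).  P-values are
Benjamini–Hochberg adjusted across the tested phylotypes
(`statsmodels.stats.multitest`); a phylotype is significant at q < 0.1
with |fold change| > 1.5.

## Gestational-age trends (term group only)

Two complementary analyses on the term-delivery subjects:

1. **Three-interval analysis.**  The 5th–95th percentile range of the
   sampled gestational ages is trisected into equal-width windows; the two
   interior cutpoints define three intervals whose outer windows are
   extended to the observed minimum and maximum so every sample is covered
   (windows are left-closed, right-open; the last is closed).  Cutpoints
   are rounded to 0.1 week for display only.  The ladder is fitted with
   the window as a three-level factor, and the three pairwise contrasts
   (2v1, 3v2, 3v1) are tested by Wald linear combinations, BH-adjusted
   across phylotypes per contrast at FDR 10% with the same
   |fold change| > 1.5 rule as the group comparison.
2. **Continuous analysis.**  NBLME with orthonormal polynomial terms in
   gestational age (QR of the centered Vandermonde matrix, constant column
   removed; XᵀX = I to 1e-10).  The degree (1–7) minimizes AIC; per-term
   Wald p-values are BH-adjusted across phylotypes within each term.

A phylotype's reported **direction** is the interval-analysis call
(up / down from the signs of its significant contrasts) *confirmed* by the
continuous analysis — the linear-term coefficient must be significant with
the same sign, otherwise the phylotype is reported flat.  This mirrors the
two-stage logic of treating the continuous model as confirmation of the
interval findings, and in validation it suppresses most of the spurious
interval calls caused by compositional closure (below) while leaving true
trends untouched.

## Diversity

Shannon Diversity Index, SDI = −Σ p_i ln p_i (natural log; 0 for a
monodominant sample, ln(number of taxa) at the uniform maximum).  The group
comparison log-transforms SDI (monodominant samples are floored at 1e-6
first; configurable) and fits a Gaussian linear mixed model with subject
random intercept and group fixed effect (`statsmodels` MixedLM, REML).
Gestational age is not included by default but can be added.

## Synthetic cohort generator

The generator emulates the design the analysis targets: 72 term + 18
preterm subjects; protocol visits every 4 weeks until 24 weeks of
gestation then every 2 weeks (the first visit at or beyond 24 weeks starts
the 2-week cadence), from a uniform entry age (6.9–16 weeks) until a
group-specific delivery age (term ~N(39.6, 1.3) in [38, 42]; preterm
~N(30.5, 2.5) in [24, 33.9]).  Observed cohorts attend far fewer visits
than their protocols, so each scheduled visit is kept with probability
0.35 (minimum 2), giving ~310–350 samples with a median of 3–4 visits per
subject.

Each subject draws a CST from the mixture (0.186, 0.585, 0.229) over
{I, III, IV-B} and keeps it across visits by default (a per-visit
transition probability is available).  A sample's composition is a
Dirichlet draw (concentration 300) around the CST base profile, adjusted
multiplicatively by per-taxon group effects (default: none — the null) and
log-linear gestational-age slopes (default: +0.08/week for the four
*Lactobacillus* spp., −0.08/week for eleven anaerobes, flat for the other
six analysis taxa and all fillers; slopes anchored at 26 weeks).  The 21
named analysis phylotypes ride on 78 rare filler phylotypes (base weights
1e-6–1e-4) so that exactly the named taxa pass the 25% prevalence filter
at the default scale.

Counts are drawn per taxon from a negative binomial (size k = 8) around
mu = depth · w/Σw, where w is the Dirichlet composition multiplied by
per-subject, per-taxon log-normal intercepts (sigma_b = 0.7) and thinned
by structural-zero dropout (pi = 0.05 per taxon).  Two deliberate choices
here: the subject intercepts and the dropout act *before* normalization,
because sequencing output is a property of the run rather than of the
biology — this keeps the drawn log-normal depth (median 7,548, log-SD
0.42, matching an IQR of roughly 5,400–9,500) as the sample's expected
total; and the per-count NB size is mild because most of the
overdispersion the fitted models absorb is supplied compositionally (CST
membership, Dirichlet noise, subject intercepts), which is where it lives
in real surveys.  Realized total-read medians still sit a few percent
below the drawn median (count noise shrinks medians); validation allows
10%.  Ground truth (per-subject CSTs, per-taxon effects and slopes,
per-sample NB means) is emitted alongside the tables.

### What the generator does and does not emulate

It reproduces the features the statistics depend on: CST-structured
compositions, zero inflation, overdispersion, subject-level correlation,
irregular longitudinal sampling, group-asymmetric follow-up (preterm
subjects stop contributing samples at delivery), and realistic depths.  It
does not model CST transitions over time (off by default), taxonomic
misassignment, chimeras, batch effects, or attendance patterns that depend
on clinical status.  Passing recovery tests on this generator therefore
shows the estimators are correct under the assumed data-generating
process, not that real cohorts satisfy those assumptions.

### A note on confounding

Because compositions renormalize (closure) and preterm subjects deliver
early, the default cohort contains two *genuine* epidemiological artifacts
worth knowing about.  First, with gestational-age trends planted and no
true group effect, the group comparison can pick up spurious
*Lactobacillus* differences purely because preterm subjects lack
late-gestation samples; depending on the seed this confounding may or may
not cross the significance threshold.  Second, a rising dominant taxon
depresses every other taxon's relative abundance within the same CST, so
"flat" taxa acquire small CST-dependent apparent trends; the
interval+continuous confirmation rule exists largely to keep these below
the calling threshold.  Both artifacts afflict real studies of this design
equally; they are properties of relative-abundance data, not bugs in the
generator.

## Validation problem sizes

The test suite validates the pipeline at sizes chosen to exercise the
study's scale while keeping a full run in minutes: likelihood-vs-grid
agreement on 21 seeded instances; NBLME parameter recovery over 100
replicates at 90 subjects with 2–6 visits (group-coefficient bias < 0.05,
CI coverage in [0.90, 0.99]); procedure-level FDR over 40 replicated
30-subject null cohorts with all 21 taxa (empirical FDR within 2
Monte-Carlo SEs of 10%); and trend recovery on one full 72-subject term
cohort with the polynomial degree search capped at 3 (degree 1 carries the
direction information; higher degrees only refine curvature).  The
`analysis/` scripts run the same pipeline at the full default scale.

## Numerical choices and degenerate inputs

Base-2 logs in divergences; natural logs everywhere in the models.  The
linear predictor is clipped at ±35 before exponentiation; quadrature sums
use log-sum-exp.  Zero-total samples, negative counts, duplicate labels,
non-increasing within-subject gestational ages, rank-deficient designs and
degenerate gestational-age spreads are rejected with named errors.
All-zero phylotypes under ZINBLME drive pi to its bound and are flagged
rather than silently reported.  All randomness flows from explicit seeds;
identical config and seed reproduce tables byte-for-byte.

## Known limitations

Wald inference ignores uncertainty in sigma_b, k and pi (anti-conservative
for very small cohorts); the BH family excludes unfit taxa; closure-driven
artifacts are mitigated, not removed, by the confirmation rule; and the
generator's CST profiles are stylized (three types, fixed indicator taxa)
rather than estimated from reference data.
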