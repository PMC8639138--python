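# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Problem setting

Polypharmacy — concurrent use of many medications — is associated with
hospitalisation and mortality, and part of that association plausibly runs
through known pairwise drug–drug interactions (KPDIs). The package
implements the full analysis chain for studying this question in a cohort
of people ageing with and without HIV:

1. build drug-exposure calendars from pharmacy fill records;
2. count interactions within each patient's co-taken drugs against an
   interaction network, and contrast that burden with a random-selection
   null;
3. weight each interacting pair by its bagged association with mortality
   (the KPDI Index) and score patients;
4. fit nested proportional-hazards models of time to first hospitalisation
   to measure how much of the medication-count association demographics,
   physiological frailty and the interaction index each explain.

Because the motivating data (restricted national health-system records) and the
commercial interaction catalogue are both restricted, the package ships a
synthetic-data generator with planted ground truth; all validation is
against that ground truth or against independent oracles.

## Exposure calendars

Fills are merged per (patient, drug) into *exposure episodes* on an
inclusive integer day grid anchored at the observation-window start (the
2009 US fiscal year, Oct 1 2008 – Sep 30 2009, by default). A fill covers
`[fill_day, fill_day + days_supply − 1]`; a refill starting within a
30-day grace window after the running coverage end continues the episode,
and the bridged gap days count as covered — the merged stretch is treated
as consecutive exposure. A drug is *chronic* for a patient when a single
merged episode spans ≥ 90 days and touches the window; days are never
summed across distinct episodes, and episodes may begin before or extend
past the window. Only chronic drugs enter medication counts and (by
default — `chronic_gating`) the co-occurrence matrix, whose entries are
unordered drug pairs sharing at least one covered day inside the window,
with the total shared days summed across disjoint overlap spells.

Conventions chosen where the rules left room: intervals are inclusive at
both ends; the gap rule merges when the uncovered stretch is ≤ 30 days
(so a fill on day 100 after coverage ending day 89 merges); overlap is
measured after clipping episodes to the window. Non-ART medication counts
include only drugs the vocabulary marks `non_art`; excluded items
(supplements, vaccines and similar) are dropped at ingest.

## Random-selection null and enrichment

For each set size k = 2..12, `n_sets` drug sets are drawn uniformly
without replacement from the non-excluded drug universe and the
interaction edges within each set are counted. For a fixed graph with n
nodes and m edges the expected count at size k is exactly
`m·k(k−1)/(n(n−1))` — each specific pair is present in a uniform k-subset
with probability k(k−1)/(n(n−1)) — and the Monte-Carlo means are tested
against that expectation (the configured density generates the graph once;
the realised edge count, not the nominal density, is the correct
reference for sampling from that graph). The default null population is
44 350 sets per size; tests use 20 000, which leaves Monte-Carlo error far
below the tolerances used. Observed per-patient interaction counts are
summarised by group and medication count on the same scale, and ordinary
least squares through the per-count means gives the slope contrast
(observed slope / random slope), the quantitative face of "real-world
prescribing concentrates interacting drugs".

## KPDI Index

**Prevalence filter.** Only interacting pairs co-taken by ≥ 10 patients
are weighted; below that an individual-pair hazard estimate is noise.

**Bagged weights.** For each of `n_bags` (default 1000; 200 in the
simulation experiments) with-replacement resamples of patients — the
patient, not the row, is the resampling unit — and each pair, a Cox model
of all-cause mortality on the pair-exposure indicator plus the frailty
score is fitted on the HIV-negative stratum (weights are estimated in the
largest stratum, free of HIV and ART effects; follow-up Oct 2009 – Mar
2019, censoring at the administrative end). If the exposure coefficient's
two-sided Wald p ≥ 0.05 the resample contributes a hazard ratio of 1
(beta 0). The pair's weight is the mean over *all* bags — the shrunken
mean, under which weak or unstable pairs get low-to-zero weight; averaging
only significant bags is available as a switch (`significant_only_mean`)
because the alternative reading is defensible. The 95% CI is the 2.5/97.5
percentile of the across-bag values. Degenerate resamples (no deaths,
constant exposure, non-convergence) contribute zero and are logged.
Estimation uses lifelines' partial-likelihood fitter throughout; the
package does not re-derive the optimiser.

**Scores.** A patient's index is Σ_j beta_j × overlap_days_j /
window_length over their weighted pairs, on the log-hazard scale; a pair
exposed in several disjoint spells sums its days. Patients with no
weighted pair score 0 and form a separate `no_kpdi` category — they are a
clinically distinct group (very low medication counts), not a fifth of
the distribution.

**Quintiles.** Cutpoints are derived on reference-group (HIV-negative)
patients with ≥ 1 weighted pair so that each quintile holds as close to
one fifth of their deaths as ties allow. Tied scores are never split;
subject to that, the four cutpoints are chosen by an exact dynamic
program minimising the worst quintile's deviation from an even split
(equivalent to exhaustive cutpoint search; above 6000 distinct
death-carrying scores, scores are pre-binned to keep the program
quadratic in a bounded size — at that scale the displacement of the
optimum is far below one death). Cutpoints derived on the reference group
are applied unchanged to both groups.

## Nested hospitalisation models

Hospitalisation is time to *first* admission from Oct 1 2009, censored at
death or Mar 31 2019 — single-event Cox with death-censoring is the only
reading consistent with censoring patients at death. Four nesting levels
are fitted per HIV stratum on the identical risk set: medication count
alone; + demographics (age per 10 years, sex [male reference], race
[White non-Hispanic reference; missing merged into Other]); + frailty
(per 5 points); + interaction-index category (quintile 2 reference, plus
the `no_kpdi` indicator). Count enters per single non-ART drug. Ties use
the Efron approximation (lifelines' default). Constant covariates are
dropped with a warning; a non-converging level is reported and the run
continues. Crude rates are events per 1000 person-years with Poisson-exact
(chi-square inversion) intervals; correlation summaries are plain Pearson
coefficients per stratum and overall.

The proportional-hazards check tests each covariate's interaction with
log follow-up time via the Schoenfeld-residual score test with a log time
transform — the score test for a coefficient of the form b₀ + b₁·log t.
In simulation the test runs slightly conservative at moderate samples
(rejection ≈ 2–4% at nominal 5%, n = 600), which is characteristic of the
score test with binary covariates; it stays within the binomial band used
in validation and has essentially full power against a planted effect
reversal.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults matching the motivating cohort's published summary:

* **Network.** Erdős–Rényi over 200 drugs at density 0.05 by default, or
  a hub variant (designated drugs with a multiplied edge probability,
  motivated by antiretrovirals' outsized interaction degree). Nine drugs
  are flagged as ART classes; six excluded items exist to exercise
  ingest filtering.
* **Cohort.** 10 000 patients by default (a desk-scale stand-in for a
  cohort of tens of thousands), 19.5% HIV-positive; frailty scores
  normal with mean 50 (SD 15) for the HIV group and 33 (11) for
  comparators; non-ART counts negative-binomial with mean 3 (SD 3) and
  4 (3) respectively, floored at one drug for comparators and capped so
  total counts stay ≤ 12; HIV patients always carry a fixed three-drug
  ART backbone.
* **Co-prescription clustering.** Drug sets grow with candidate weight
  exp(γ × edges-to-chosen-set); γ is calibrated per group and set size by
  Monte-Carlo bisection so the mean interaction count is a configured
  multiple (default 5×) of the exact random expectation at the same size.
  Single-neighbour attachment cannot reach 5× at large set sizes on a
  sparse graph, which is why the preference is exponential in the full
  edge count; an unattainable target raises with a diagnostic.
* **Fills.** Each chronic drug gets fills jointly covering ≥ 220 days
  overlapping the window with refill gaps ≤ 30 days (so every intended
  drug survives the chronic rule and all chronic drugs pairwise overlap);
  15% also get a detached earlier episode (gap > 30 days), plus
  non-chronic 30-day decoy fills and occasional excluded-item fills, so
  calendar logic is exercised end to end.
* **Planted effects.** Pair effects occupy dedicated drugs whose edges
  always exist and which are left out of organic selection, so their
  exposure prevalence is exactly the configured mechanism (optionally
  scaled with medication count to create mediation). Outcomes are
  exponential proportional hazards: death and first admission with
  configurable baselines, frailty and per-medication log-hazards, and the
  planted pair effects.
* **Mediated count effect.** When part of the configured total
  per-medication log-hazard on hospitalisation is carried by planted
  pairs, the generator solves for the direct component against the
  *marginal Cox estimand* of the realised cohort: the population
  partial-likelihood score equation (exponential times, death censoring,
  administrative end) is integrated numerically and the direct slope
  iterated until the count-only model's large-sample limit equals the
  configured total. A first-order split misses because risk-set depletion
  attenuates marginal coefficients under unmodelled heterogeneity; the
  score-equation calibration is exact up to quadrature error.

Regeneration from (config, seed) is byte-identical; all stage generators
spawn from one seed sequence.

**What the synthetic cohorts do not emulate:** real prescribing is
condition-driven (therapeutic classes, contraindications), adherence is
imperfect, interactions have heterogeneous severity and direction,
hazards are not exponential, and admission can recur. Passing the
recovery experiments shows the estimators do what they claim under the
model the analysis assumes — not that the model captures any particular
health system.

## Validation scales and numerical choices

The study-scale experiments (in `kpdi.experiments`, also driven by
`scripts/acceptance.py`) use: enrichment at 10 000 patients and 20 000
random sets per size; weight recovery at 5 000 HIV-negative patients, five
planted pairs (+0.5, +0.3, −0.3, two null) at 25% prevalence, 200 bags;
attenuation at 20 000 patients with a planted total count log-hazard of
0.08 partially mediated through three planted pairs, 20 replicates in the
test suite; proportional-hazards calibration over 200 null replicates at
n = 600; quintile optimality at 10 000 patients. These sizes were chosen
to make Monte-Carlo error small relative to each check's tolerance while
keeping the whole suite runnable on a laptop. In the attenuation
experiment the adjustment index is built from the planted (true) pair
weights rather than re-estimated per replicate: weight estimation has its
own dedicated experiment, and re-using truth isolates the nested-model
property being measured.

Other numerics: exponential event times are converted to whole days
(ceiling, minimum one day), which introduces ties handled by Efron's
approximation; candidate weights in clustered set growth cap the exponent
at γ·30 to avoid overflow; bisections run 12 (clustering) or 40 (score
equation) halvings, far below the tolerances that matter.

## Known limitations

* Pair weights are estimated one pair at a time (as in the motivating
  design); correlated exposures therefore share credit, and omitted
  concurrent pairs mildly attenuate each estimate (visible as a bias of a
  few hundredths at strong effect sizes).
* The bagged mean with significance zeroing is a shrinkage estimator: for
  a truly null pair whose full-sample estimate happens to sit near two
  standard errors, the weight can reach ~±0.05–0.08. The validation
  checks its typical, not worst-case, behaviour.
* The pipeline's bagged weighting over a full catalogue of prevalent
  pairs is computationally heavy (pairs × bags Cox fits); desk-scale runs
  use reduced bag counts, and the experiments weight only the planted
  pairs.
* `no_kpdi` patients are excluded from cutpoint derivation but included
  in models via their own indicator; with very few reference deaths
  (< 5) quintile construction refuses to run rather than emit arbitrary
  cutpoints.
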