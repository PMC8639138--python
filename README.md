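# kpdi

Polypharmacy analysis toolkit: drug-exposure calendars, a random-selection
null for pairwise drug-interaction counts, a mortality-weighted
drug-interaction index built by bagged proportional-hazards estimation,
and nested survival models of hospitalisation risk.

## Who this is for

Pharmacoepidemiologists studying whether known pairwise drug interactions
(KPDIs) explain part of the dose–response association between medication
count and adverse outcomes — here framed for cohorts of people ageing with
and without HIV, where antiretroviral therapy both inflates interaction
burden and complicates comparison. The real inputs (pharmacy dispensing
records, a licensed interaction catalogue) are restricted, so the package
includes a first-class synthetic-data generator with planted ground truth;
every method is validated by parameter recovery against that truth or by
independent oracles.

## The model in brief

**Exposure.** Fills merge into episodes per (patient, drug): a fill covers
`[t, t + days_supply − 1]` and a refill starting ≤ 30 days after coverage
ends continues the episode. A drug is *chronic* when one episode spans
≥ 90 consecutive days intersecting the observation year. Chronic drugs
define medication counts and the co-occurrence matrix — unordered pairs
taken ≥ 1 day in common, with overlap durations.

**Interaction burden.** For a drug set *S* on an interaction network
*G = (V, E)*, the KPDI count is `|{{a,b} ⊆ S : {a,b} ∈ E}|`. The null
draws uniform k-subsets; on a fixed graph the expected count is exactly
`m·k(k−1)/(n(n−1))`. Observed counts per patient, stratified by
medication count, are contrasted with the null via OLS slopes of the
per-count means.

**KPDI Index.** For each prevalent interacting pair *j* (≥ 10 exposed
patients), over *B* bootstrap resamples of the HIV-negative stratum, fit
a Cox model of all-cause mortality on the pair-exposure indicator plus
the frailty score and set

    β_j = (1/B) Σ_b β_{jb} · 1{p_{jb} < 0.05}

(the non-significant resample contributes hazard ratio 1). A patient's
index is `Σ_j β_j · d_j / L` — pair weights scaled by the fraction of the
observation year the pair was co-taken — on the log-hazard scale, cut
into quintiles holding ≈ equal numbers of reference-group deaths, with
no-interaction patients as their own category.

**Hospitalisation models.** Time to first admission, censored at death or
the administrative end of follow-up; Cox models per HIV stratum at four
nesting levels (count; + demographics; + frailty per 5 points; + index
quintiles) quantify how much of the count association each block
explains. Crude rates use Poisson-exact intervals; the proportional-
hazards assumption is checked by covariate × log(time) score tests.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

End-to-end run on a synthetic cohort (800 patients, 120 drugs, 5×
co-prescription enrichment, two planted pair effects of +0.5 and −0.3 on
mortality):

```python
from kpdi import GeneratorConfig, RunConfig, run_pipeline

config = RunConfig(
    seed=7,
    synth=GeneratorConfig(
        seed=7, n_patients=800, n_drugs=120, enrichment_target=5.0,
        planted_betas=(0.5, -0.3), planted_prevalence=0.25,
        beta_med_mortality=0.05,
    ),
    sim_n_sets=5000, n_bags=25,
)
report = run_pipeline(config, "out/")
print(report.fits.round(3).to_string(index=False))
```

which prints:

```
       group  slope  intercept  r_squared
hiv_negative  1.332     -3.891      0.933
hiv_positive  1.466     -5.275      0.940
      random  0.319     -0.951      0.956
```

Observed interaction burden grows ~4× faster per added medication than
random selection (1.33 and 1.47 vs 0.32 extra KPDIs per drug), steeper
for the HIV group — the clustered-prescribing signature the generator
plants. The bagged weights recover the planted pairs:

```
drug_a drug_b  beta_mean  ci_low  ci_high  prevalence  n_significant
 D0116  D0117      0.630   0.217    0.887         155             24
 D0118  D0119     -0.051  -0.600    0.151         151              4
```

the harmful pair (+0.5) is found in 24/25 bags; the weak protective pair
shrinks toward zero at this sample size — exactly the intended behaviour
of the significance-gated average. The nested models show the count–
hospitalisation association attenuating once the index enters:

```
       level    hr  ci_low  ci_high
  unadjusted 1.075   1.040    1.112
demographics 1.076   1.040    1.113
    +frailty 1.073   1.037    1.111
 +kpdi_index 1.048   1.001    1.098
```

i.e. per additional non-ART medication, an unadjusted hazard ratio of
1.075 falls to 1.048 after adjusting for the interaction index — the
planted mediation being recovered. A `kpdi` command-line tool exposes the
stages (`kpdi synth`, `kpdi simulate`, `kpdi calendar`, `kpdi run`).

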