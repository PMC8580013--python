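# microstab

Longitudinal vaginal-microbiome stability analysis for two-cohort
postmenopausal studies (gynecologic-cancer patients vs. healthy controls,
four timepoints over one year), driven by a synthetic-cohort generator so
the entire pipeline runs at desk scale without any sequence download.

Women treated for gynecologic cancer experience vaginal symptoms that
track the state of their vaginal microbiome. In healthy women the
community is typically *Lactobacillus*-dominated, acidic and temporally
stable; cancer therapy perturbs it. `microstab` quantifies that
perturbation per subject with three Bray-Curtis statistics —

* **overall stability** `ABC = mean{ BC(x_s, x_t) : s < t }` over all
  pairs of a subject's timepoints,
* **resistance** `BC(x_T0, x_T1)` (short-term shift across treatment),
* **resilience** `BC(x_T0, x_T3)` (one-year departure from baseline),

each categorized high/intermediate/low on 0–0.5 / 0.5–0.75 / 0.75–1 —
and surrounds them with the full supporting pipeline: blank-anchored QC
(Good's coverage, low-yield exclusion, contaminant reporting),
cumulative-sum-scaling normalization, four alpha-diversity metrics
(Chao1, Shannon, Pielou, Faith PD), Ward-linkage community-state typing
on Bray-Curtis distances, CTCAE/PRO-CTCAE/FSFI symptom dichotomization
with persistence scoring, and an association layer (Fisher exact,
rank tests, sequential PERMANOVA, forward-AIC GLM with analysis-of-
deviance partitioning).

## Worked example

```bash
microstab run --seed 1 --out run1/
```

runs simulate → qc → normalize → diversity → cst → stability → symptoms →
associate on a default synthetic cohort (25 cancer / 27 healthy subjects,
4 timepoints, median depth 35,200 reads, 8 contaminated blanks) and
prints:

```
microstab pipeline report
==============================
version 0.1.0  seed 1  stages 8

[simulate] n_samples=208, n_blanks=8, n_subjects=52, seed=1
[qc] threshold=3055.0, n_in=208, n_out=208, n_excluded=0, mean_coverage=0.9999640664314058
[normalize] quantile=0.5, n_samples=208
[diversity] metrics=['observed_richness', 'chao1', 'shannon', 'pielou', 'faith_pd'], beta_metric=braycurtis
[cst] k=7, method=ward-BC
[stability] n_subjects=52, kw_cohort_p=1.8828765791857449e-07
[symptoms] n_subjects=52, scheme=methods
[associate] permanova_cohort_p=0.195, n_perm=999, glm_mode=full

Community types:
       n  pct_of_total
CT
CT-A  49          23.6
CT-B  41          19.7
...

Median overall stability (ABC) by cohort:
cohort
cancer     0.726363
healthy    0.127493
```

Reading it: the QC threshold is the largest blank yield (3,055 reads
here), below which samples would be discarded; coverage ~99.996% means
essentially every genus present was observed. Ward clustering at k = 7
recovers the seven planted community types (the per-sample labels and a
per-type summary — counts, shares, cohort enrichment Fisher p — are in
`run1/ct_summary.tsv`). The cancer cohort's median ABC of 0.73 vs 0.13
for healthy subjects reflects the planted community turnover (switch
probability 0.6 vs 0.2 per interval), and the Kruskal-Wallis p ≈ 2e-7
detects it. Every stage also writes TSV outputs and a `manifest.json`
recording parameters and seeds; reruns with the same seed are
byte-identical.

Each stage is equally usable on its own, from Python
(`microstab.stability.stability_table`, `microstab.associations.permanova`,
…) or the CLI (`microstab simulate|qc|diversity|cst|stability|symptoms`).

## Layout

```
src/microstab/
  simulate.py      synthetic-cohort generator (the study conditions)
  tables.py        count/metadata/symptom table I/O and alignment
  qc.py            coverage, low-yield exclusion, contaminant screen
  diversity.py     CSS normalization, alpha/beta diversity
  community.py     Ward community-state typing and characterization
  stability.py     per-subject ABC/resistance/resilience
  symptoms.py      CTCAE/PRO-CTCAE/FSFI encoding, persistence, prevalence
  associations.py  Fisher, rank tests, PERMANOVA, forward-AIC GLM, screen
  pipeline.py      end-to-end orchestration, manifest, report
  cli.py           `microstab` command group
docs/methods.md    model, parameter and design documentation
```
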