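# Methods

## The analysis

`microstab` models a two-cohort longitudinal vaginal-microbiome study:
gynecologic-cancer patients (treated with radiation between baseline and
the first follow-up) and healthy postmenopausal controls, each sampled at
four timepoints T0–T3 over one year. The scientific questions the pipeline
addresses are (i) how vaginal communities partition into community-state
types (CTs), (ii) how much each woman's community composition moves over
the year, and (iii) which clinical, behavioral and symptom variables
associate with that movement.

### Quality screening

Per-sample coverage uses Good's estimator `C = 1 − f1/N` (`f1` = genera
seen once, `N` = total reads); a Chao-corrected variant is available.
Samples are excluded when their total yield falls below the largest yield
among sequencing blanks (fallback cutoff 3,200 reads; comparison strict,
so a sample at exactly the cutoff is retained). Genera found in blanks are
reported with their blank- and sample-prevalence but never subtracted:
the exclusion of blank-like low-yield datasets is the decontamination
step, matching how negative controls are commonly handled in
amplicon studies of low-biomass sites.

### Normalization and diversity

Counts are depth-normalized by cumulative-sum scaling (CSS): each sample's
scaling factor `s_j` is the sum of its positive counts at or below the
p-th quantile of those counts (p = 0.5 by default, ties included), and
normalized values are `y_ij / s_j × 1000`. The fixed-quantile form is the
default; CSS damps the influence of dominant taxa (e.g. a 95%
*Lactobacillus* community) on the scaling factor relative to total-sum
scaling.

Alpha diversity is computed on raw integer counts, because Chao1's
bias-corrected estimator `S_obs + f1(f1−1)/(2(f2+1))` needs exact
singleton/doubleton counts: observed richness, Chao1, Shannon entropy in
nats, Pielou evenness `H/ln S_obs` (undefined below two taxa → NaN), and
Faith's PD (total branch length of the minimal rooted subtree spanning the
observed genera; computed by path-union so star trees are legal). No
rarefaction is applied anywhere. Beta diversity — Bray-Curtis
`1 − 2Σmin/(Σx+Σy)` or presence/absence Jaccard — is computed on relative
abundances of the CSS-normalized table. Bray-Curtis is treated as a
dissimilarity: symmetry and [0,1] range are asserted, the triangle
inequality is not.

### Community-state typing

Genera are first filtered to those reaching 0.1% relative abundance in at
least one sample. Ward-linkage clustering runs directly on the Bray-Curtis
dissimilarities in the `hclust ward.D` convention: the Lance-Williams Ward
update applied to the dissimilarities as given. (SciPy's `ward` implements
the squared-dissimilarity scheme, so the implementation feeds it
`sqrt(d)` and squares the merge heights — the two recursions coincide
exactly under that transform.) A `ward.D2` switch is exposed. The tree is
cut at a requested `k` (default 7) or at the `k ∈ [2,10]` maximizing mean
silhouette width (ties to the smallest k). Clusters are renamed CT-A,
CT-B, … in decreasing size order so the most prevalent type is always
CT-A. A Spearman-distance (1 − ρ, range [0,2]) complete-linkage clustering
serves as a robustness check, compared by adjusted Rand index. CT
summaries report counts, one-decimal shares of all typed samples, per-CT
cohort splits with Fisher exact enrichment (CT vs rest × cancer vs
healthy), mean-abundance-ranked dominant genera, and the fraction of
members with >95% *Lactobacillus*.

### Stability metrics

For each subject with ≥2 timepoints, on relative abundances:

* **overall stability (ABC)** — mean Bray-Curtis over all unordered pairs
  of the subject's timepoints (a consecutive-pairs option exists), with
  the maximum pairwise value kept alongside;
* **resistance** — BC(T0, T1), the short-term shift across the treatment
  window;
* **resilience** — BC(T0, T3), the one-year departure from baseline.

ABC tolerates missing timepoints (any available pairs); resistance and
resilience strictly require their anchors and are reported missing
otherwise, flagged through `n_timepoints`. Values are categorized high /
intermediate / low stability on [0, 0.5) / [0.5, 0.75) / [0.75, 1]; the
boundary points, which the three printed ranges share, are assigned
upward (0.5 → intermediate, 0.75 → low).

### Symptom encoding

Clinician CTCAE grades (0–3) and patient-reported PRO-CTCAE grades (0–4)
dichotomize at grade ≥ 1 (grade 3 maps to present by monotone extension).
FSFI domain scores (0–6, higher = better function) mark a symptom present
below 4.2; a composite below 26 flags sexual dysfunction; both boundaries
are strict. pH ≥ 5 is "high" (the instrument defines only "<5" and ">5";
the boundary goes to high, overridable). Presence over the four
assessments collapses to never / occasional (exactly 1) / frequent (2–3) /
constant (all 4); a coarser variant (occasional = 1–2, persistent = 3–4)
is selectable as `scheme="figure"`. Behavioral booleans use the same
categories. Cohort prevalences are compared per symptom and timepoint with
two-proportion z-tests, Bonferroni-adjusted; presence flags are
correlated pairwise by the phi coefficient (NaN for constant flags).

### Association layer

* **Fisher exact** (scipy) — validated exhaustively against a brute-force
  hypergeometric enumeration on all 2×2 tables with row margins ≤ 15.
* **PERMANOVA**, sequential (Type I) multi-factor: the distance matrix is
  Gower-centered (`G = −½ J d² J`), term sums of squares are differences
  of `tr(H_i G)` along the accumulated design, pseudo-F uses the residual
  mean square, and p-values are `(1 + #{F* ≥ F}) / (1 + n_perm)` over
  seeded permutations of sample identity (999 by default). The
  single-factor pseudo-F matches scikit-bio's PERMANOVA to machine
  precision; the sequential decomposition sums exactly to the total.
* **Forward-AIC GLM with deviance partitioning**: greedy forward entry of
  candidate covariates by AIC (Gaussian identity link by default — the
  responses are BC values in [0,1]); `mode="stop"` halts when no candidate
  improves AIC, `mode="full"` enters every candidate in greedy order (the
  reported stepwise tables include non-improving terms, so `full` is the
  pipeline default). The entered order is then scored by sequential
  analysis of deviance: per-term deviance drop, `Pr(>Chi)` from a
  chi-square on the drop scaled by the full-model dispersion estimate, and
  percent of null deviance explained, with the residual percentage closing
  the budget to 100%.
* A univariate per-genus symptom screen (Spearman for ordinal grades,
  rank-sum for binary flags, Benjamini-Hochberg across genera) stands in
  for multivariate per-taxon modelling, which is out of scope.

## The synthetic cohort

The generator plants exactly the structure the analysis assumes, so every
downstream stage is testable at desk scale without sequence data.

* **Community templates.** Seven CT templates over a 24-genus panel
  mirror the qualitative type descriptions: CT-A 95% *Lactobacillus*;
  CT-B *Gardnerella* 45% + *Atopobium* 30% without *Prevotella*; CT-C
  *Streptococcus* 50%; CT-D *Bifidobacterium* 30%; CT-E twelve diffuse
  anaerobes with no dominant taxon; CT-F *Prevotella* with
  *Atopobium*/*Sneathia*/*Veillonella*/*Gardnerella*; CT-G *Prevotella*
  with *Porphyromonas*/*Peptoniphilus*/*Fusobacterium*/*Anaerococcus*.
  Each template carries a 0.2% floor on every panel genus so Dirichlet
  concentrations stay positive. Only the types' qualitative characters are
  published; the exact vectors are this package's design choice.
* **Sampling model.** Per sample, proportions ~ Dirichlet(120 × template)
  and counts ~ Multinomial(depth); depth is lognormal with median 35,200
  reads and log-sd 0.35 (only the median is published; the lognormal and
  its spread are a modelling choice). Concentration 120 keeps within-type
  scatter well below between-type distances — real vaginal profiles are
  noisier, so clustering recovery here is an upper bound on field
  performance.
* **Turnover.** Each subject's CT follows a uniform-restart Markov chain:
  switch probability per interval 0.6 (cancer) vs 0.2 (healthy), new type
  uniform over the remaining six. These probabilities are calibrated only
  to produce the published ordering of cohort stability (cancer less
  stable), not its magnitudes, which depend on unpublished effect sizes.
* **Symptoms.** Dryness (clinician and patient instruments) is Bernoulli
  with logit `−3.2 − 1.1 log10(Lactobacillus + 1e−6)`; pH is
  `4.3 + 2.2 (1 − Lactobacillus) + N(0, 0.35)` clipped to the 4.0–7.7
  strip range, so low-*Lactobacillus* samples cross pH 5 far more often.
  Other symptoms use cohort-specific baseline prevalences shaped like the
  published baseline pattern (e.g. dryness more common in healthy women at
  baseline, pain/bleeding/vaginismus more common in cancer). FSFI domains
  are Gaussian around 5.0 shifted down by 1.5 (1 − *Lactobacillus*),
  clipped to 0–6.
* **Blanks and tree.** Eight blanks draw 100–3,199 reads over the four
  classic reagent contaminants (*Escherichia*, *Stenotrophomonas*,
  *Ralstonia*, *Corynebacterium*), which never appear in real samples.
  The genus tree for Faith PD is a Kingman coalescent over all genera with
  branch lengths rescaled to unit mean, seeded.
* **Determinism.** One integer seed drives a single `numpy` Generator (and
  a derived seed for the tree), so regeneration is bit-for-bit identical.

What the generator does **not** emulate: read-level error/chimera
processes, taxonomic misassignment, compositional zero-inflation beyond
the multinomial, within-visit technical replicates, subject dropout, and
realistic covariance between behaviors and the microbiome (behaviors are
independent draws). Passing tests therefore demonstrate correctness of
the statistical machinery under the planted model, not field performance
on sequenced cohorts.

## Numerical choices and degenerate inputs

* Kruskal-Wallis on all-identical values returns H = 0, p = 1 instead of
  an error; Wilcoxon on all-zero differences raises (degenerate test);
  the exact Wilcoxon null is used for n ≤ 25 without ties or zeros.
* CSS quantile ties are included in `s_j` (`≤` comparison); a zero scaling
  factor raises.
* Ward merge ties break toward the lowest-index pair (SciPy's nearest-
  neighbor chain order), making labels deterministic given input order,
  and label identity is invariant to sample order up to renaming.
* Silhouette-based `k` selection skips degenerate cuts and errors when no
  cut yields two clusters.
* Missing persistence assessments (<4) apply the count thresholds to the
  available series; callers see `n_assessments`.
* Seeds: the pipeline seed feeds the generator, the PERMANOVA permutation
  stream, and the tree (seed + 1).

## Problem sizes

The default study is 52 subjects × 4 timepoints = 208 samples plus 8
blanks. The repeated-cohort checks use 200 regenerated cohorts for the
Kruskal-Wallis detection rate and 200 null simulations at n = 40 samples /
999 permutations for PERMANOVA calibration; the acceptance script runs
100 cohorts for the detection rate and the same 200-run calibration.
These sizes give Monte-Carlo standard errors of ~1.5 percentage points on
the reported rates.
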