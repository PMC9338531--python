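# Methods

`concordmap` implements a proteotranscriptomic analysis of a three-arm
cohort design — normal tissue, benign inflammation, and tumor — together
with a synthetic-cohort generator that plants known signal for every stage,
so each statistical claim the pipeline makes can be exercised against
ground truth.

## Per-sample protein–mRNA concordance

The central statistic is the per-sample Spearman correlation ρ between a
sample's protein and mRNA abundances over the shared gene set ("global
protein–mRNA concordance"). Because protein and transcript detection differ
between disease arms, the pair universe is built **per scope**: tumor pairs
and control pairs are the genes observed in at least `detect_frac` (default
0.8, mirroring the 20% missingness rule) of that scope's samples in both
layers, so the two scopes may legitimately count different numbers of
pairs. Each sample's ρ uses its pairwise-complete values; samples with
fewer than `min_pairs` (default 100) complete pairs are excluded and
flagged, guarding ρ's stability.

Downstream associations follow the field's conventions: Mann–Whitney U for
comparing correlation statistics between groups (exact null for
min(n) ≤ 8 without ties, tie-corrected normal approximation otherwise),
Pearson's r for continuous covariates (e.g. a proliferation-marker
abundance), and for survival a median split of the tumor samples
(ties at the median deterministically to the low group, ⌈n/2⌉ vs ⌊n/2⌋)
feeding Kaplan–Meier / log-rank plus a univariate Cox fit on the
continuous ρ. All tests are two-sided.

## Differential expression and concordance classes

Per-layer two-group tests use a moderated t: per-gene pooled variances are
shrunk toward a scaled-F prior fitted by method-of-moments on log variances
(the standard empirical-Bayes squeeze for small-n expression studies; the
implementation is cross-checked against Bioconductor limma's `eBayes` in
the test suite to 1e-6 on p-values). Normalization before testing is
per-sample median centering on the log2 scale. Fold-change gates follow the
usual conventions for these data: |log2FC| > log2(1.5) for mRNA and
> log2(1.2) for protein, with two-sided p < 0.05; the raw p (not the BH q,
reported alongside) drives the up/down/ns status. Cross-layer classes:
CO-UP / CO-DOWN when both layers call the same direction, DISCORDANT when
both are significant with opposite signs, NONE otherwise.

## Trend patterns and the five-class signature

Each protein's trajectory across normal → inflammation → tumor is
classified by two pairwise Welch t-tests (steps N→I and I→T); a step is
up/down only when p < 0.05 **and** |log2Δ| exceeds the proteome fold-change
gate, otherwise flat — giving the 3×3 = nine trend patterns.
Independently, high-variability genes (top 50% MAD on the log matrix by
default) are z-scored per gene and clustered by k-means (k = 4 by default,
elbow curve exported); each cluster's trajectory is summarized by the
least-squares slope of per-sample median z against arm index, segmented per
adjacent arm pair.

The merge rule assigns a five-class label only when pattern and cluster
trend agree in direction:

* MIMIC-UP — (up, flat) steps with a significant overall N→T rise, in an
  up-trending cluster (inflammation-mimicking dysregulation);
* SPECIFIC-UP — (flat, up) in an up cluster (tumor-specific);
* VAGUE-UP — (up, up), or (flat, flat) steps whose overall N→T contrast is
  nonetheless significantly up, in an up cluster;
* MIMIC-DOWN / SPECIFIC-DOWN mirror the first two in a down cluster;
* everything else (including (up, down)-type reversals) is NONE.

The five-class vocabulary is deliberately asymmetric (there is no
VAGUE-DOWN), so sign-negation maps MIMIC↔MIMIC and SPECIFIC↔SPECIFIC
across directions but sends would-be vague-down genes to NONE. The exact
step taxonomy and merge rule are this package's definitions; published
variants of this analysis do not pin them down precisely.

## Gene-set machinery

* **ORA** — hypergeometric upper-tail test of a hit list inside a universe,
  BH across a GMT collection.
* **Preranked enrichment** — weighted Kolmogorov–Smirnov running sum
  (weight exponent 1); NES and nominal p from seeded gene-label
  permutations, conditioning on the sign of the observed ES; FDR across a
  collection by BH of nominal p. Gene-label (not phenotype) permutation is
  the appropriate null here because the inputs are ranked lists.
* **Per-sample scores** — the ssGSEA formulation (rank-weighted ECDF
  difference, exponent α = 0.25), linearly rescaled per set across samples
  to [−1, 1]. This stands in for GSVA proper: the scores are used only for
  correlation and ranking, which are rank-stable, and the ssGSEA form is
  invariant to sample-wise monotone transforms — the property that
  licenses correlating them with ρ in the first place.

## Splicing landscape

Events of the five canonical types (A3, A5, MX, RI, SE) arrive as
per-sample inclusion levels (PSI ∈ [0, 1]), either parsed from
rMATS-dialect junction tables or simulated. Aberrant events are called by
a per-event two-sided Mann–Whitney test of tumor vs control PSI, with BH
applied **once across all tested events of all five types jointly**; an
event passes iff |ΔPSI| > 0.05 (strictly) and adjusted p < 0.01. The
read-count likelihood machinery of splicing callers is intentionally out of
scope — the package consumes inclusion levels. Events with fewer than
three observed values in either arm are skipped with a reason and excluded
from the BH family.

Passing events are screened for progression association by univariate Cox
regression (Efron ties) on the inclusion level over tumor samples;
significance defaults to raw p < 0.05 with BH adjustment available by
flag. Regulator ranking correlates each annotated splicing factor's protein
abundance with each passing event's PSI across tumor samples (Pearson);
per factor the summary is the count of strong correlations (|r| > 0.6)
with mean |r| as tiebreak, ranked both against all passing events and
against the progression-significant subset; factors appearing in both
top-20 lists form the recurrent set.

## Biomarker funnel

Four nested stages on the protein layer, tumor vs control:

1. differential expression at the proteome thresholds;
2. per-protein univariate logistic regression (Wald p < 0.05). The fit is
   a hand-written Newton/IRLS with step halving; (quasi-)complete
   separation — detected scale-invariantly as a per-SD log-odds effect
   above 5, where the Wald statistic is Hauck–Donner-degenerate — triggers
   a Firth bias-reduced refit so perfectly discriminating proteins are not
   silently lost;
3. the intersection of 1–2 enters repeated cross-validated L1 logistic
   regression: `n_iterations` (default 200) independent stratified 10-fold
   splits each choose λ by the 1-SE rule on validation deviance over a
   20-point geometric grid from λ_max down to 0.05 λ_max; the full-data
   support at the chosen λ is recorded, and proteins selected in at least
   `freq_min` (default 0.5) of iterations survive. The path solver is an
   accelerated proximal-gradient (FISTA) method with warm starts, exact
   zeros by soft-thresholding and a KKT-residual stopping rule, verified
   against liblinear in the tests;
4. bidirectional stepwise logistic refinement under **BIC**. BIC rather
   than AIC is a considered choice: with AIC's fixed penalty of 2 a pure
   noise covariate survives whenever its in-sample deviance gain exceeds
   2 — probability ≈ 0.16 at any sample size — so a handful of screened
   noise covariates would routinely survive; the log(n) penalty drives
   that probability to zero as cohorts grow. AIC remains available by
   flag.

Final markers are benchmarked by rank-based AUC (abundance as score)
against user-named reference markers.

A structural caveat documented here because the synthetic experiments
expose it: all four stages run on the same samples, so the few background
proteins that survive stages 1–2 by chance are winner's-curse-informative
for the later stages; when the true marker leaves one or two ambiguous
samples, a screened "patch" protein can genuinely improve both in-sample
and cross-validated deviance and no within-sample criterion can reject it.
This is a real limitation of same-cohort funnel designs, not of this
implementation; split-sample or external validation is the remedy.

## The synthetic-cohort generator

The generator is first-class, tested code: it produces a cohort with the
statistical structure every stage assumes, plus a ground-truth record.

**Rank coupling.** For each sample with planted concordance ρ the latent
Gaussian-copula correlation is r = 2 sin(πρ/6) — the exact inversion of
the copula's Spearman formula ρ = (6/π) asin(r/2). mRNA log2(FPKM+1)
values are gene baseline (N(5, 2²)) plus arm shifts plus N(0, 0.5) noise,
floored at 0; protein z-scores are r·z(mRNA within-sample normal scores) +
√(1−r²)·noise, scaled by 0.30 log2 units. The realized per-sample
Spearman converges to the planted value as the gene count grows (verified
at 5000 genes to 0.03). Planted per-sample ρ is the arm target (defaults
0.16 / 0.23 / 0.36 for normal / inflammation / tumor, emulating the
subgroup medians this cohort design reports) plus N(0, 0.05) jitter.

The protein scale 0.30 emulates TMT-style ratio-compressed within-group
variability (median per-protein log2 SD of roughly 0.2–0.35 in labelled
proteomics) and was fixed by a power-design pass so that the planted
effect sizes (1 log2 trends at n = 10/arm, a 1.5 log2 marker at
n = 30/group) sit in the recovery regime the pipeline's documented
operating characteristics assume.

One structural consequence of the copula worth knowing: when arms differ
in target ρ, genes at the extremes of the mRNA-baseline ranking acquire
small arm-dependent protein mean shifts (the coupling coefficient
multiplies each gene's expected normal score). This is faithful to what
"higher concordance" mechanically means, but it also means the non-planted
background is not pure noise between arms; experiments that require a pure
noise background (e.g. marker-discovery specificity) should set a uniform
`target_rho`.

**Planted structure.**

* *Trends*: 25 genes per each of the nine (step1, step2) patterns, with
  cumulative ±1 log2 arm shifts applied to **both** layers (concordant
  planting).
* *Marker*: one protein shifted +1.5 log2 in tumors only.
* *Proliferation proxy*: one protein whose tumor-arm values correlate 0.5
  with the planted ρ (controls uncoupled).
* *Splice events*: 120 per type; a 25% fraction is aberrant with
  |ΔPSI| = 0.2 planted between tumor and control means. Inclusion levels
  are simulated on the logit scale — baseline logit(U(0.2, 0.8)), tumor
  shift chosen so the PSI-scale delta is ±0.2 within bounds, N(0, 0.3)
  logit noise — and squashed back to (0,1), respecting PSI bounds while
  keeping effects linear where planted.
* *Regulator coupling*: the first annotated splicing factor drives 30
  aberrant events at logit-scale correlation 0.8 across tumor samples
  (loading c·σ with residual σ√(1−c²), leaving total variance unchanged);
  random sign per event.
* *Survival*: exponential baseline (rate 1/24 per month), independent
  uniform censoring with the upper bound solved so the censoring fraction
  matches `censor_rate` (default 0.15) at the baseline hazard. The
  distant-recurrence endpoint's log-hazard is `hazard_rho` (default 2)
  per **SD** of planted concordance; the progression endpoint's log-hazard
  sums `event_hazard_beta` (default 1.5) per SD of each hazard event's
  PSI, with the hazard events (default 3) nested inside the
  regulator-coupled set so regulator and progression rankings are linked,
  as the motivating biology suggests. Standardized covariates are used
  because raw ρ spans only ~0.05 units — "per unit ρ" hazards would be
  either astronomically large or undetectable.
* *Missingness*: MCAR on the protein layer only (default 10%); no MNAR
  mechanism is modelled.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: batch effects and sample-processing structure,
gene–gene co-expression (background genes are independent given the
copula), MNAR missingness typical of low-abundance proteomics, count-level
sequencing noise, clinical covariates genuinely coupled to outcome
(LDH/IPI/stage are generated independent of everything), and paired
designs.

## Numerical choices

* Spearman p: exact permutation for n ≤ 9, t approximation otherwise;
  constant vectors flagged rather than NaN-propagated.
* Welch t with both variances zero: p = 1 when means agree, 0 otherwise.
* Cox: lifelines, Efron ties; constant covariates and monotone-likelihood
  fits are flagged, not reported as numbers.
* Logistic Newton: tolerance 1e-8, max 100 iterations, step halving keeps
  the deviance monotone.
* FISTA path: Lipschitz constant ‖X‖²/(4n), gradient restarts, KKT
  residual < 1e-7 (1e-4 inside CV, where only the loss curve matters).
* k-means: Lloyd, best of 10 seeded restarts.
* Ties at the concordance median go to the low group; BH is step-up with
  the usual monotonicity enforcement.
* Low-abundance defaults: drop transcripts with median FPKM < 1; drop
  proteins in the lowest decile of median abundance; both configurable and
  off by default in the synthetic pipeline (planted genes should not be
  silently removed).
* KNN imputation: k = 10 sample-neighbors, nan-Euclidean distance on the
  log2 scale, after dropping features missing in > 20% of samples.

## Problem sizes

The shipped test suite and the acceptance script run entirely on synthetic
cohorts at the default sizes above (13/18/40 samples, 3000 genes, 600
events) or smaller stage-specific cohorts (e.g. 200-gene cohorts for the
per-event Cox recovery study, a 1000-protein noise background for marker
discovery), chosen so each study retains the power its operating
characteristic requires.
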