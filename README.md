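# concordmap

Proteotranscriptomic analysis toolkit for three-arm cohort designs —
normal tissue vs benign inflammation vs tumor — built around four
questions that matter when matched protein and mRNA profiles exist for the
same patients:

1. **Is protein–mRNA concordance itself a disease characteristic?**
   For each sample, the global concordance is the Spearman correlation
   ρ between its protein and mRNA abundances over the shared gene set.
   The package computes per-sample ρ with scope-specific pair universes,
   compares it between arms and clinical subgroups (Mann–Whitney U),
   correlates it with covariates such as proliferation-marker abundance
   (Pearson r), and tests its prognostic value by median-split
   Kaplan–Meier / log-rank and univariate Cox regression over five
   survival endpoints (PFS, OS, RFS, LRFS, DRFS).
2. **Which dysregulation is tumor-specific rather than
   inflammation-mimicking?** Per-protein trend patterns across
   normal → inflammation → tumor (two Welch-t steps, 3×3 = nine patterns)
   merge with k-means clustering of high-MAD proteins into a five-class
   signature: MIMIC-UP, VAGUE-UP, SPECIFIC-UP, MIMIC-DOWN, SPECIFIC-DOWN.
3. **What does the aberrant splicing landscape look like, and who
   regulates it?** From per-sample inclusion levels (PSI) of A3/A5/MX/RI/SE
   events (rMATS-dialect tables are read directly), aberrant events are
   called at |ΔPSI| > 0.05 and BH-adjusted p < 0.01, summarized per type
   and per gene, screened for progression association by univariate Cox,
   and candidate splicing factors are ranked by how many events their
   protein abundance strongly tracks (|r| > 0.6) — with the recurrent set
   across the all-event and progression-event rankings highlighted.
4. **Can a single diagnostic protein be funnelled out of the proteome?**
   A four-stage funnel: differential expression ∩ univariate logistic
   screen → repeated cross-validated lasso (selection frequencies over
   200 re-splits) → BIC-stepwise logistic refinement → ROC/AUC benchmark
   against reference markers.

Differential expression uses a limma-style moderated t (empirical-Bayes
variance squeeze, cross-checked against Bioconductor limma in the tests)
with layer thresholds |log2FC| > log2(1.5) (mRNA) and > log2(1.2)
(protein), and cross-layer CO-UP / CO-DOWN / DISCORDANT classification.
Gene-set machinery (hypergeometric ORA, preranked permutation GSEA,
per-sample ssGSEA scores) supports the enrichment and correlation steps.

Because the statistics only matter if they can be validated, the package
ships a first-class synthetic-cohort generator
(`concordmap.cohort_synth`): per-sample concordance is controlled exactly
through a Gaussian copula (r = 2 sin(πρ/6)), trends, splice events,
regulator coupling, survival hazards and one diagnostic marker are planted
with known ground truth, and every analysis stage is tested by parameter
recovery against that truth. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a default cohort (13 normal / 18 inflammation / 40 tumor samples,
3000 genes, 600 splice events) and run the concordance and splicing
stages:

```python
import concordmap as cm
from concordmap import concordance, splicing_landscape, pipeline

cohort, events, truth = cm.simulate_cohort(cm.SynthConfig(seed=1))
cohort = pipeline.prepare_cohort(cohort)          # filter + KNN-impute

prof_t = concordance.compute_concordance(cohort, "tumor")
prof_c = concordance.compute_concordance(cohort, "control")
print(round(prof_t["rho"].median(), 3), round(prof_c["rho"].median(), 3))
# 0.385 0.215   <- tumor vs control median concordance (targets 0.36 / ~0.21)

surv = concordance.concordance_survival(prof_t, cohort.meta, "DRFS")
print(f"{surv.logrank.p_value:.2e}")
# 7.97e-08      <- high-concordance tumors recur at distance sooner

calls = splicing_landscape.call_aase(events)
summary = splicing_landscape.landscape_summary(calls)
print(summary.n_aase, summary.n_genes)
# 150 145       <- aberrant events called and genes they affect
```

The numbers printed above are what this exact snippet produces: the
recovered concordance medians bracket the planted arm targets, the planted
concordance–hazard coupling shows up in the log-rank test, and the caller
finds the 150 planted aberrant events.

The same stages are available from the shell, each deterministic for a
fixed seed and byte-identical on rerun:

```bash
concordmap simulate --seed 1 --out cohort/
concordmap de --dir cohort/ --layer protein --out de.tsv
concordmap concordance --dir cohort/ --endpoint DRFS --out-prefix conc
concordmap signature --dir cohort/ --k 4 --seed 1 --out-prefix sig
concordmap splicing call --dir cohort/ --out calls.tsv
concordmap splicing sf-rank --dir cohort/ --out-prefix sf
concordmap funnel --dir cohort/ --iterations 200 --seed 1 --out funnel.json
```

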