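# glstrat

Glycolysis-activity scoring and lncRNA-based stratification of expression
cohorts.

Tumors that rely on aerobic glycolysis tend to behave more aggressively, and
long noncoding RNAs (lncRNAs) are increasingly implicated in wiring that
metabolic program to other oncogenic signaling. `glstrat` implements, as a
tested and reusable pipeline, the full analysis needed to study that linkage
in a bulk RNA-Seq cohort:

- per-sample **glycolytic activity** as the ssGSEA score of a glycolysis gene
  set over within-sample expression ranks;
- **selection of glycolysis-associated lncRNAs** by Pearson correlation with
  that score (|r| > 0.3, Benjamini–Hochberg FDR < 0.05);
- **patient stratification** by feature-resampled consensus clustering with
  PAM (k-medoids), with the cluster count guided by the consensus-CDF
  delta-area curve, and clusters canonically ordered by median glycolysis
  score;
- **cluster characterization**: Kaplan–Meier/log-rank survival comparison,
  Kruskal–Wallis with Dunn's post hoc on scores, Fisher's exact mutation
  enrichment, preranked GSEA (permutation NES/FDR) on differential
  expression, aREA-style transcription-factor activity with an ANOVA
  effect-size screen, and immune-infiltration scoring with Euclidean/Ward
  grouping;
- **lncRNA–glycolysis–gene linkage** via the first-order partial correlation
  r_xy·z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²)),
  with a Kolmogorov–Smirnov comparison of raw vs adjusted correlation
  distributions and a covariate-adjusted (CNV + methylation) regression;
- a transferable **genomic classifier** (quantile normalization onto a stored
  reference + lasso-penalized multinomial logistic regression with 10-fold
  cross-validated lambda) that carries cluster labels to external data;
- a **synthetic cohort generator** with planted ground truth (clusters,
  correlated lncRNAs, survival hazards, enriched mutations, active TFs) so
  every stage has a parameter-recovery test.

It is aimed at computational biologists who want the statistical machinery of
this kind of pan-cancer lncRNA analysis as an inspectable, seedable library
rather than a collection of one-off scripts. See `docs/methods.md` for the
models, assumptions, and numerical choices.

## Worked example

```python
import glstrat as gl

# a synthetic cohort with three planted clusters and 40 planted lncRNAs
bundle = gl.generate_cohort(gl.CohortConfig(seed=1))

cfg = gl.PipelineConfig(seed=1, n_iter=200, gsea_nperm=2000, n_lambdas=30)
res = gl.run_pipeline(bundle, cfg)

print("suggested k:", res.suggested_k)
print("cluster sizes:", res.cluster_labels.value_counts().sort_index().to_dict())
print("log-rank: chi2=%.2f p=%.2e" % (res.logrank[0], res.logrank[2]))
print("selected lncRNAs:", len(res.selected_lncrnas))
mediator = res.linkage["LNC0000"]
print("mediator KS p:", mediator["ks_p"])
```

prints

```
suggested k: 3
cluster sizes: {1: 50, 2: 50, 3: 50}
log-rank: chi2=18.02 p=1.22e-04
selected lncRNAs: 40
mediator KS p: 4.525672866094418e-23
```

The delta-area rule recovers the three planted clusters exactly; cluster 3 is
the highest-glycolysis group and has the worst survival (the log-rank test
rejects strongly); exactly the 40 planted lncRNAs pass the |r| > 0.3 /
FDR < 0.05 screen; and conditioning on the planted
mediator lncRNA collapses the gene–score correlation distribution toward
zero, which the KS test flags decisively.

The same workflow is scriptable from the shell:

```bash
glstrat simulate --seed 1 --outdir cohort/
glstrat score --counts cohort/counts.tsv --gmt cohort/gene_sets.gmt --out score.tsv
glstrat associate --score score.tsv --counts cohort/counts.tsv --out assoc.tsv
glstrat run --indir cohort/ --seed 1 --outdir run/
glstrat report --run-dir run/
```

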