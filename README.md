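# shutoffseq

Decomposition of excitotoxicity-driven "shut-off" of synaptic
activity-induced gene expression from bulk RNA-seq count matrices.

## The problem

Synaptic NMDA-receptor signaling drives a protective, activity-dependent
gene program in neurons; extrasynaptic NMDA-receptor (esNMDAR) signaling —
a hallmark of excitotoxicity in neurodegenerative disease — disrupts it.
When an excitotoxic insult interrupts action-potential (AP) firing, the
resulting loss of gene induction has two components:

* a **passive** component, from the cessation of AP firing itself, and
* an **active** component, from toxic esNMDAR signaling on top of silencing.

The experimental design that separates them uses cultured neurons in nine
conditions: untreated; bicuculline (Bic)-induced AP firing for 0.5, 1, or
2 h; a short protocol (SP, 1 h total) and a long protocol (LP, 2 h total) in
which firing is interrupted midway by TTX (passive), TTX+NMDA (passive +
active), or — LP only — TBOA (glutamate spillover, a milder excitotoxicity
model); five replicates each.

`shutoffseq` implements the complete analysis of such an experiment:

1. **Differential expression** — median-of-ratios size factors, per-gene NB
   dispersions, Wald tests for 16 pair-wise contrasts, empirical-Bayes
   shrinkage of log2 fold changes (L2FC), Benjamini–Hochberg FDR, merged
   into one wide per-gene table over the union of analysis-ready genes.
2. **Activity classes** — a per-gene ANOVA screen over the Bic time course
   plus rule-based categorization: *early* genes (expression maximum at 1 h,
   assayed with SP), *late* genes (maximum at 2 h, LP), *transient* genes
   (0.5 h only, excluded), mirrored for repressed genes.
3. **Shut-off decomposition** — per gene, calls of passive (TTX vs Bic),
   active (TTX+NMDA vs TTX), total (TTX+NMDA vs Bic) and TBOA (TBOA vs Bic)
   shut-off at FDR < 0.05, with percent metrics
   `pct = 100·(2^L2FC − 1)`, a top-N ranking by total shut-off %, and
   overlap/partition summaries.
4. **Concordance** — the gene-wise similarity statistic
   `s = a·b / √(a² + b²)` between two effect L2FCs, and pairwise Pearson
   correlations between the passive / spillover / total / active effect
   vectors.
5. **Exploratory views** — condition-wise L2FC matrix with an informative-
   gene SD filter and Euclidean/complete-linkage clustering, PCA of
   variance-stabilized counts, and seed-fixed exact t-SNE of candidate genes.
6. **Enrichment** — generic hypergeometric overrepresentation of shut-off
   gene sets over user-supplied GMT files against the expressed-gene
   background.
7. **Synthetic data** — a truth-labeled generator that emulates the whole
   design (log-normal baselines, NB overdispersion, library-size factors,
   archetype kinetics, multiplicative intervention effects), so the entire
   pipeline is testable without any download, and recovered calls can be
   scored against ground truth.

## Worked example

```python
import shutoffseq as ss

exp = ss.ShutoffExperiment.simulate(ss.default_config(n_genes=2000, seed=7))
res = exp.fit()
print(res.summary())
```

```text
Excitotoxic shut-off decomposition
==================================
genes: 2000   samples: 45   contrasts: 16

Activity classes (Bic time course):
  early.induced       105
  late.induced        301
  early.repressed     106
  late.repressed      132
  transient            89
  unresponsive       1267

candidate genes (ANOVA FDR < 0.01, classified, complete L2FC): 526

Shut-off decomposition of evaluable induced genes:
  evaluable: 644
  passive only: 99   active only: 142   both: 39
  boosted: 15   resistant: 349   boosted by both: 0

Effect-vector Pearson correlations (late-induced candidates):
  r(passive, active)    = -0.432
  r(total, active)      = +0.698
  r(spillover, active)  = +0.778
  r(spillover, total)   = +0.781

Strongest total shut-off (top 5):
  g01975       late   shut-off   -79.8%  passive   -42.0%  active   -59.6%
  g01547       early  shut-off   -79.6%  passive   -54.0%  active   -44.4%
  g01863       early  shut-off   -76.7%  passive   -39.4%  active   -50.4%
  g01714       late   shut-off   -76.5%  passive   -45.5%  active   -51.3%
  g01920       late   shut-off   -76.4%  passive   -46.4%  active   -46.5%
```

Reading the output: of 2000 simulated genes, 301 classify as late-induced
(rising from 1 h to 2 h of AP firing) and go to the long protocol. Among the
644 evaluable induced genes, active shut-off (142 active-only + 39 both)
outweighs passive-only shut-off (99), no gene is boosted by both
interventions, and the passive and active effect vectors are anticorrelated
(r = −0.43): genes strongly silenced by AP-firing cessation tend to be the
ones boosted, not suppressed, by the additional NMDA signal, and vice versa.
The top-ranked gene's induction is reduced 79.8% by the TTX+NMDA
intervention relative to Bic-only firing.

Real data enter through TSV files — a gene × sample integer count matrix and
a design sheet (`sample_id, protocol, treatment, time_h, replicate`):

```python
exp = ss.ShutoffExperiment.from_tsv("counts.tsv", "design.tsv")
res = exp.fit()
res.ranking(20)            # top shut-off genes
res.effect_correlations()  # passive/active/spillover/total structure
res.tsne()                 # seed-fixed embedding of candidate genes
```

Everything is also available from the shell:

```bash
shutoffseq simulate --n-genes 5000 --seed 1 --outdir sim
shutoffseq run --counts sim/counts.tsv --design sim/design.tsv --outdir out
shutoffseq validate --merged out/merged_gene_table.tsv --reference theirs.tsv
```

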