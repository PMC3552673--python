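# cdtox

Dose-response transcriptomics of cadmium-exposed human proximal tubule (HPT)
cells, re-implemented as a tested, reusable pipeline with a synthetic-study
generator so every stage can be exercised and validated without any array
download.

The underlying study design is small and sharp: HPT cells profiled on
expression arrays after a 1-day Cd²⁺ exposure at 0/9/27/45 μM and a 13-day
exposure at 0/4.5/9/27 μM — one array per condition, eight samples in all.
The pipeline implements the analyses that design supports:

1. **Present-call filtering** — the analysis universe is the probes detected
   Present (MAS5-style P/A/M calls) in at least one sample.
2. **Per-gene dose regression** — OLS of expression on concentration within
   one exposure block; for gene *g*, `y_g = α + β·dose + ε`, with the
   two-sided t test on `β` (n−2 df), strict-cutoff selection, P-value
   histograms and Benjamini–Hochberg q values.
3. **Hypergeometric gene-set enrichment** — for a set with `n` genes in a
   universe of `M` of which `K` are regression-significant and `r` fall in
   the set, the P value is the strictly-greater tail
   `P(X > r) = Σ_{k=r+1} C(K,k)·C(M−K,n−k)/C(M,n)`, computed in the log
   domain (stable at M ≈ 30,000).
4. **Cross-timepoint overlap significance** — the same tail applied to the
   overlap of the 1-day and 13-day significant lists.
5. **Variance-filtered clustering** — grand-mean centering, per-gene SD
   filter, Pearson dissimilarity (d = 1 − r) and Ward linkage over the
   pooled 8 samples, with heat-map and Newick export.
6. **Mutual-information network modules** — plug-in MI (bits) on
   equal-frequency bins over the high-variability genes; modules are gene
   sets with high intra-pair MI and low MI to everything else, found by
   average-linkage clustering of the 1 − NMI distance and scored by
   separation = intra − extra, calibrated against a permutation null.

## Worked example

Generate a synthetic two-block study (2,000 genes, 2% induced and 2%
repressed per block, half the responders shared between blocks, one planted
8-gene module) and run the full analysis:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_dose_regression.py
python analysis/03_enrichment_overlap.py
python analysis/04_cluster_heatmap.py
python analysis/05_network_modules.py
```

Selected output from seed 1:

```
block1: 2000 present probes; 148 with P < 0.05 (0 pass BH q < 0.05)
  positive @ P<0.01: 18 selected; sensitivity 0.20, FPR 0.0051
block1: K=147 significant genes of M=1905
  top set 'shared_responders': n=39, r=32, P=1.18e-32
k=2 cluster 1: ['d1_27uM', 'd1_45uM', 'd13_27uM'] (doses [27.0, 45.0, 27.0])
top module: 8 genes, intra 1.561 bits, extra 0.685 bits, separation 0.876 bits
Jaccard with the planted module: 1.00
permutation null (n=100): 95th percentile separation 0.517 bits -> top module exceeds it
```

Reading this: with n = 4 arrays per block the per-gene t test has 2 residual
df, so only ~7% of genes clear P < 0.05 and none survive FDR control — yet
the *set-level* signals are unambiguous: the planted shared-responder set
enriches at P ≈ 1e-32, the high-dose samples (≥ 27 μM from both timepoints)
form their own Ward cluster, and the planted 8-gene module is recovered
exactly, with a separation well beyond the permutation null.

The same stages are available as subcommands of the `cdtox` CLI
(`simulate`, `regress`, `enrich`, `overlap`, `cluster`, `network`,
`run-all`) for use on real MAS5-style exports (signal TSV, calls TSV,
design CSV, annotation TSV, GMT gene sets).

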