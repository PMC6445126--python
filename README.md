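# sfcomod — splicing-factor co-regulation modules in tumor cohorts

`sfcomod` is an analysis pipeline for a question from tumor transcriptomics:
do the ~244 splicing factors (SFs) of the spliceosome act as one block, or
do subsets of them form co-regulated programs with clinical consequences?
The pipeline discovers anti-correlated SF co-expression modules in bulk
expression cohorts, validates them across cohorts, and links them to
phenotype, survival, isoform switching, pathway context and promoter
motifs.  It is written for computational biologists who want each stage as
a reusable, tested library function, and it ships a synthetic-cohort
generator with planted ground truth so the whole analysis runs and is
scored without any external download.

## The analysis

1. **Correlation clustering.**  All-pairs Pearson correlation `PC(g, g')`
   of the panel across tumors; genes are clustered on their correlation
   profiles (Euclidean distance, complete linkage).  The number of clusters
   k ∈ 2..6 is chosen by a clValid-style stability test (APN: average
   proportion of non-overlap under single-sample removal), guarded so the
   chosen clustering represents the panel's two coherent, mutually
   anti-correlated main groups.
2. **Consensus modules.**  Clusters found independently in two cohorts are
   matched by maximal Jaccard and intersected.  The two anti-correlated
   consensus modules are labeled by outcome: per-patient module score
   (mean log2 expression), median split, log-rank test; the module whose
   high group fares worse (O/E hazard ratio > 1) is the **Enhancer**
   module, the other the **Suppressor** module.
3. **Paired differential expression.**  Matched tissue pairs give
   per-patient log2 fold changes; paired t-tests with Benjamini–Hochberg
   correction across the panel.
4. **Phenotype and survival.**  Median-normalized module scores compared
   across grade, mitotic score, ER status and subtype (t-test / ANOVA);
   Kaplan–Meier curves and log-rank statistics for median-split cohorts.
5. **Isoform switching.**  Genes whose isoforms anti-correlate across
   tumors (min pair PC ≤ −0.3) are selected; their isoforms cluster into
   two groups by correlation to the module genes, and genes with isoforms
   in both groups tie SF switching to isoform-usage switching.
6. **Enrichment.**  Genome ranking by mean PC to each module; top-500
   hypergeometric over-representation and preranked GSEA (running-sum ES,
   permutation NES/FDR).
7. **Motif enrichment.**  Pscan-style PWM scanning of the −50..+450 TSS
   window (best hit, both strands, min-max normalized) with a z-test of
   the module's mean score against the promoter universe.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic design (two 300-tumor cohorts, 244-gene panel with planted 61-gene
suppressor and 24-gene enhancer modules, 114 matched pairs):

```bash
cd analysis
python 01_simulate_cohorts.py
python 03_discover_modules.py
python 05_survival_analysis.py
```

prints (abridged):

```
discovery cohort: 1444 genes x 300 tumors, 114 matched normal/tumor pairs
validation cohort: 1435 genes (235 of 244 panel genes retained)

stability selection: APN per k = {2: 0.1527, 3: 0.2069, 4: 0.2029, 5: 0.1262, 6: 0.1191}, chosen k = 6
consensus modules: {'module_1 (Enhancer)': 23, 'module_2 (Suppressor)': 57, ...}
adjusted Rand index vs planted modules: 0.929

Enhancer  : high-vs-low HR = 2.35 (worse outcome when high), log-rank chi2 = 34.85, p = 3.56e-09
Suppressor: high-vs-low HR = 0.39 (better outcome when high), log-rank chi2 = 42.27, p = 7.96e-11
```

Read: stability picks k = 6; after cross-cohort intersection the two
anti-correlated consensus modules recover the planted 24-gene enhancer and
61-gene suppressor sets (a few genes lost to the 9 panel genes absent from
the validation cohort), and the survival stage orients them correctly —
high enhancer-module expression more than doubles the event hazard.
Scripts 02, 04, 06, 07, 08 run the paired-DE, clinical, isoform,
enrichment and motif stages the same way; each writes its tables under
`results/`.

The same pipeline is scriptable end-to-end from a YAML config:

```bash
comod-sf run --config run.yaml --outdir results/run
comod-sf simulate --seed 7 --outdir results/sim     # cohort tables only
```

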