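# enhancerscan

Tools for discovering and classifying sites of extragenic RNA polymerase II
transcription from ChIP-seq tag data. A substantial fraction of Pol II
signal in mammalian genomes falls outside annotated genes; much of it marks
transcribed *enhancers* (broad, low Pol II peaks over
H3K4me1-high/H3K4me3-low chromatin) rather than promoters of unannotated
RNA genes (sharp Pol II and H3K4me3 peaks, CpG-island-rich). `enhancerscan`
implements the full annotation pipeline for stimulus-response ChIP-seq
designs (e.g. endotoxin-stimulated macrophages) and a seeded synthetic-genome
generator for validating every stage against planted ground truth.

The pipeline:

1. **Curation** — remove Pol II peaks overlapping gene bodies, peaks within
   10 kb of a gene's 3′ end, and peaks whose signal is continuous with an
   upstream transcribed gene (read-through), leaving high-confidence
   extragenic sites.
2. **Regulation classes** — label each peak constitutive, inducible or
   repressed with a conditional exact binomial test: given
   n = k_ut + k_stim tags, k_stim ~ Binomial(n, N_stim/(N_ut+N_stim)) under
   no change (N = library size), combined with a tags-per-million fold-change
   threshold.
3. **Chromatin-signature classification** — summarize H3K4me1/H3K4me3 in 50
   bins of 100 bp over a ±2.5 kb summit-centered window (unit-sum per mark),
   train a linear support-vector machine on unambiguous p300 peaks (enhancer
   exemplars) versus annotated TSSs, and call each peak enhancer, promoter,
   or *unpredictable* when its decision score falls inside a calibrated
   rejection band.
4. **Clustering** — merge peaks within 2 kb, discard clusters overlapping
   protein-coding genes, and carry majority class/regulation labels.
5. **Association statistics** — CpG-island and PU.1 overlap against
   length-matched random nulls with +1-smoothed empirical p-values,
   p = (1 + #{null ≥ obs}) / (1 + n_random); assignment of enhancers to
   coding genes within 20 kb and exact binomial gene-class enrichment;
   nearest Ser5-P Pol II peak distances; intra-region CAGE cluster spacing;
   RNA-seq support versus Pol II occupancy.
6. **Conservation** — per-base conservation profiles around summits and
   empirical significance of each class against random extragenic region
   sets (threshold p < 0.01).
7. **Motif enrichment** — Clover-style PWM statistics: per-window likelihood
   ratios ∏ p_PWM(b)/p_bg(b) scanned on both strands, geometric-mean group
   scores, randomization p-values against two background sequence pools,
   and per-region match probabilities from composition-preserving shuffles.

## Worked example

Generate the default toy genome (2 chromosomes × 5 Mb, 60 genes, 120
enhancers, 40 promoter-type ncRNA elements) and run everything:

```sh
enhancerscan run-all --simulate --seed 1 --out reports/
```

Selected lines from the printed summary:

```
classifier_holdout_accuracy     1.0
fraction_clusters_enhancer      0.6875
fraction_clusters_promoter      0.25
cpg_fraction_promoter           0.35
cpg_fraction_enhancer           0.0091
pu1_fraction_enhancer           0.8636
pu1_fraction_promoter           0.675
truth_class_accuracy            1.0
truth_regulation_accuracy       0.9313
truth_unpredictable_fraction    0.0625
```

Reading these numbers: the signature SVM separates planted enhancer and
promoter chromatin perfectly on held-out exemplars; ~69 % of the final Pol II
clusters carry an enhancer signature; CpG islands sit under 35 % of promoter
clusters versus 0.9 % of enhancer clusters (the planted promoter bias);
PU.1 binding (±500 bp) covers 86 % of enhancers and 68 % of promoters; and
against the generator's truth table the pipeline recovers every planted
element, calls 93 % of regulation labels correctly, and abstains on 6 % of
them. Per-stage BED/TSV reports (curated peaks, predictions, clusters,
overlap statistics, conservation, motif enrichment) are written alongside
the summary, and `run_log.json` records the config, seed and versions.

The same stages are available as library calls (`enhancerscan.peaks`,
`.signatures`, `.associations`, `.conservation`, `.motifs`) and as stage
subcommands (`annotate`, `classify`, `associate`, `conserve`, `motifs`)
operating on a data directory with a `manifest.json`.

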