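# Methods

This note documents the models, estimators, defaults and design choices
behind `enhancerscan`, and what the synthetic validation does and does not
demonstrate.

## Coordinate and tag conventions

All internal coordinates are 0-based half-open (BED convention); the gene
table readers convert other dialects on input, so every off-by-one decision
is made exactly once. ChIP-seq tags are reduced to their 5′ positions
(read start on +, end−1 on −) because tag counting is directional-read
based. Duplicate tags are kept; `TagTrack.deduplicated()` collapses them
when a library is suspected of PCR duplication. A chromosome absent from a
track counts as zero signal rather than raising — sparse synthetic genomes
and chromosome-subset analyses are normal inputs.

## Extragenic curation

Three rejection rules, applied in order: (a) any overlap with a gene body;
(b) any overlap with the strand-aware 10 kb window downstream of a gene's
3′ end (`flank3_bp`), which absorbs Pol II tracking past termination
sites; (c) read-through — continuous Pol II coverage between the peak and
the 3′ end of the nearest upstream transcribed gene. "Continuous" is
operationalized as no zero-tag window of `continuity_gap_bp` (default
500 bp) in the intervening gap; the cutoff mimics the visual
discontinuity a curator would demand, and is configurable because no
principled value exists. A gene counts as transcribed when its body holds
at least `transcribed_min_tags` pooled Pol II tags (default 1).

Peak summits are the midpoint of the leftmost plateau of maximal
sliding-window (50 bp) tag counts. Windowed counts are piecewise constant,
so the maximum is almost always a plateau; taking its midpoint maps a
single tag pile to the pile itself while remaining deterministic.

Peak calling itself is out of scope — the pipeline expects external peak
calls — but a minimal sliding-window Poisson caller (500 bp windows,
50 bp steps, global background rate, p < 1e-5, minimum merged width
200 bp) is provided so the synthetic pipeline is self-contained. It is not
a general-purpose caller: no local background correction, no duplicate
handling, no strand cross-correlation.

## Regulation classes

For a peak with k_ut and k_stim tags and library sizes N_ut, N_stim, the
no-change null is k_stim ~ Binomial(k_ut + k_stim, N_stim/(N_ut + N_stim)),
tested two-sided (exact). A peak is inducible when the tags-per-million
fold change (pseudocount of one tag) is ≥ `fold_min` (default 2) with
p ≤ `p_max` (default 1e-3); repressed symmetric; otherwise constitutive.
The labels are anti-symmetric under swapping conditions by construction.
The thresholds are declared configuration: they make the three-class split
reproducible but are not claimed to match any particular published split.

## Chromatin-signature classifier

Each summit is profiled as two 50-bin vectors (H3K4me1, H3K4me3; 100 bp
bins over ±2.5 kb), converted to tags-per-million and rescaled to unit sum
per mark. The signature is the *pattern* of the two marks — sharp central
me3 at TSSs versus broad, often bimodal me1 at enhancers — so amplitude is
deliberately removed; this also makes predictions invariant to library
size. A mark with zero window signal stays all-zero and is flagged; a
profile with both marks silent is never classified.

Training exemplars: "informative" p300 peaks (≥ 2.5 kb from any annotated
TSS, so the profile window cannot touch promoter chromatin) as the
enhancer class, and an equal number of uniformly sampled annotated TSSs as
the promoter class. The classifier is a linear soft-margin SVM (C = 1) on
the 100 concatenated bins; the linear kernel keeps training deterministic
and the me1/me3 weight pattern interpretable. Five-fold stratified CV
accuracies are stored as model metadata.

Abstention: the rejection band is the 5th percentile of |decision score|
over correctly classified training profiles. Scores inside (−band, +band)
are called "unpredictable". This operationalizes a non-predictive third
class numerically; about 5 % of clean profiles are expected to abstain by
construction, and noisy real signatures abstain more.

## Association statistics

Empirical overlap p-values use +1 smoothing (Phipson–Smyth):
p = (1 + #{null ≥ obs}) / (1 + n_random), with the mirrored tail for
depletion; both tails are reported along with the direction of the
observed deviation. Null sets re-place length-matched intervals uniformly
on the same chromosomes, rejection-sampled out of gene bodies when the
query set is extragenic. Note two consequences of this estimator: the
smallest attainable p is 1/(n_random + 1), so `n_random` must exceed
1/α for a strict p < α verdict to be reachable; and a statistic with
large tie mass (heavily discrete overlap fractions from few query
intervals) makes the p-values conservative rather than uniform.

PU.1 overlap uses the same machinery with features extended ±500 bp.
Gene assignment takes the nearest protein-coding gene at boundary distance
< 20 kb, with ties broken by TSS distance then gene id (deterministic and
permutation-stable). Gene-class enrichment compares assigned-gene
regulation labels against the class frequencies among Pol II-positive
genes (≥ `polii_positive_min_tags` tags in TSS ± 500 bp, default 5) with
two-sided exact binomial tails, reported raw plus a Benjamini–Hochberg
column; the choice of a binomial rather than hypergeometric model treats
assignments as independent draws, adequate at the scales involved.

## Conservation

Profiles are position-wise means over summit-centered windows; missing
bases (track gaps) are excluded from means, never zeroed, and the count of
contributing regions per position is reported. Group significance compares
the mean per-base score over all region bases with length-matched random
sets restricted to extragenic space (verdict at p < 0.01). Random sets are
matched on length and extragenic location only — GC matching is omitted as
the minimal faithful matching; this is recorded in the output metadata.

## Motif statistics

PWMs come from JASPAR count matrices with a per-cell pseudocount of 0.01
(avoids log 0 while barely perturbing informative positions). The window
statistic is the likelihood ratio against the background base composition;
N bases contribute a factor of 1. A sequence scores the arithmetic mean of
window ratios over both strands (reverse-complement invariant), and a
group scores the mean log sequence score — a deterministic, Clover-style
simplification of subset-averaged enrichment scores, chosen so every value
is reproducible by direct enumeration. Enrichment p-values redraw
length-matched fragment sets from a background pool (per-pool window
scores are precomputed once and fragment scores read off a cumulative sum,
which is exact). Per-region match probabilities compare the observed
sequence score with mononucleotide-shuffled versions of the same sequence
(dinucleotide shuffling available behind a flag).

A PWM exactly equal to the background scores every window 1.0; all null
draws then tie the observed statistic and the smoothed estimators return
their conservative extremes (enrichment p = 1, match probability
1/(n+1)). Uninformative-but-not-identical PWMs behave as expected
(p ≈ uniform).

## Synthetic data: what it emulates

The generator plants, from one seeded RNG: genes (8–20 kb, ≥ 30 kb apart)
with uniform gene-body Pol II plus a TSS-proximal component; enhancers
(1.5–3 kb) with broad Gaussian Pol II at one quarter of the element width
and mean 60 tags; promoter-type ncRNA elements with 1.5× sharper, higher
Pol II; H3K4me1 bimodal at ±1 kb (s.d. 400 bp) with me3 at 15 % of me1 for
enhancers, versus sharp me3 (s.d. 300 bp) flanked by me1 at ±800 bp for
promoters and gene TSSs; condition fold changes of 4 for inducible and
repressed elements (20/32/48 % constitutive/inducible/repressed, matching
the relative sizes of the three regulation classes reported for this
biology); p300 at 80 % of enhancers; PU.1 at 85 % of enhancers and 70 % of
promoters; Ser5-P tags and RNA-seq tags scaled to element activity; tight
CAGE clusters at promoters versus dispersed ones at enhancers; CpG islands
at 72 % of gene TSSs, 25 % of ncRNA promoters and 0.5 % of enhancers;
conservation elevated to 0.55 over a 0.08 background at planted elements;
and three instances of an NF-kB-like motif (consensus GGGACTTTCC) sampled
into each inducible enhancer, alongside ten random decoy PWMs. Elements
whose nearest gene lies within 20 kb copy its regulation label with
probability 0.9, planting the enhancer/gene co-regulation structure.

What it does *not* emulate: mappability artifacts, duplicate reads, copy
number, local background variation, nucleosome phasing, GC bias in either
tags or conservation, overlapping or nested genes, and realistic motif
co-occurrence. Passing the synthetic recovery tests therefore shows the
pipeline's logic is correct under its own model assumptions — not that the
thresholds are optimal for any real ChIP-seq library.

Default sizes (2 chromosomes × 5 Mb, 60 genes, 160 elements) were chosen
so the complete pipeline, including 1000-replicate nulls, finishes in
about 90 seconds on one CPU; the calibration tests use smaller null counts
(99–199 replicates) where only uniformity, not resolution, is at stake.

## Known limitations

* The classifier is strictly two-class-plus-abstention; poised/latent
  enhancer subtypes and multi-mark signatures are out of scope.
* Cluster-level labels are majority votes with fixed tie-breaks
  (constitutive / unpredictable), which discards within-cluster
  heterogeneity.
* Empirical nulls place intervals uniformly per chromosome; no matching on
  GC, repeat content or distance-to-gene beyond the extragenic exclusion.
* The fallback peak caller is intentionally minimal (see above).
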