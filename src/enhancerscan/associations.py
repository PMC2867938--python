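"""Overlap, distance and enrichment statistics for classified Pol II clusters.

Covers CpG-island association with matched random nulls, assignment of
transcribed enhancers to neighbouring coding genes, gene-class enrichment
(do inducible enhancers sit next to inducible genes?), nearest Ser5-P peak
distances, intra-region CAGE cluster spacing, RNA-seq support versus
Pol II occupancy, and PU.1 overlap (as overlap with +-500 bp slop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    TagTrack,
    count_tags,
    nearest_distance,
    sample_random_intervals,
)


@dataclass
class OverlapResult:
    """Observed vs expected overlap fraction with an empirical p-value.

    ``empirical_p`` carries +1 smoothing, (1 + #null >= observed) /
    (1 + n_random) for enrichment and the mirrored tail for depletion;
    the reported value follows the observed direction.
    """

    n_query: int
    n_overlapping: int
    expected_fraction: float
    empirical_p: float
    p_enrichment: float
    p_depletion: float
    direction: str

    def __post_init__(self) -> None:
        if not 0 <= self.n_overlapping <= self.n_query:
            raise ValueError("n_overlapping must lie in [0, n_query]")

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_query if self.n_query else 0.0


def overlap_fraction_with_null(
    query: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    n_random: int = 1000,
    slop: int = 0,
    seed: int = 0,
    exclude: Sequence[GenomicInterval] | None = None,
) -> OverlapResult:
    """Fraction of query intervals hitting >= 1 feature, with a random null.

    Features are extended symmetrically by ``slop`` before testing.  The
    null re-places length-matched intervals uniformly on the same
    chromosomes, avoiding ``exclude`` (gene bodies, for extragenic query
    sets).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    slopped = [f.expanded(slop) for f in features]
    index = IntervalIndex(slopped)
    exclude_index = IntervalIndex(exclude) if exclude else None

    observed = sum(1 for q in query if index.overlaps_interval(q))
    obs_frac = observed / len(query) if query else 0.0

    # group the template by chromosome once so each null replicate is a
    # single vectorized draw + searchsorted per chromosome
    by_chrom: dict[str, np.ndarray] = {}
    for i, q in enumerate(query):
        by_chrom.setdefault(q.chrom, []).append(i)  # type: ignore[union-attr]
    lengths = np.asarray([len(q) for q in query], dtype=np.int64)
    null_fracs = np.empty(n_random)
    for i in range(n_random):
        if exclude_index is None:
            hits = 0
            for chrom, idx in by_chrom.items():
                idx_arr = np.asarray(idx)
                lens = lengths[idx_arr]
                hi = np.maximum(1, chrom_sizes[chrom] - lens)
                starts = rng.integers(0, hi)
                hits += int(index.overlaps_many(chrom, starts, starts + lens).sum())
            null_fracs[i] = hits / len(query)
        else:
            placed = sample_random_intervals(rng, query, chrom_sizes, exclude_index)
            null_fracs[i] = sum(
                1 for q in placed if index.overlaps_interval(q)
            ) / len(placed)
    p_enrich = (1 + int(np.sum(null_fracs >= obs_frac))) / (1 + n_random)
    p_deplete = (1 + int(np.sum(null_fracs <= obs_frac))) / (1 + n_random)
    expected = float(null_fracs.mean())
    direction = "enrichment" if obs_frac >= expected else "depletion"
    return OverlapResult(
        n_query=len(query),
        n_overlapping=observed,
        expected_fraction=expected,
        empirical_p=p_enrich if direction == "enrichment" else p_deplete,
        p_enrichment=p_enrich,
        p_depletion=p_deplete,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Gene assignment and gene-class enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAssignment:
    cluster_id: str
    gene_id: str | None
    distance: int | None  # boundary distance, bp; None when unassigned


def assign_to_genes(
    clusters: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    max_dist: int = 20_000,
) -> list[GeneAssignment]:
    """Assign each cluster to its nearest coding gene if closer than max_dist.

    Distance is the boundary gap (0 on overlap).  Ties go to the gene with
    the nearer TSS, then to the lexicographically smaller gene_id, so the
    assignment is deterministic and stable under input permutation.
    """
    out: list[GeneAssignment] = []
    for cluster_id, iv in clusters:
        best: tuple[int, int, str] | None = None  # (distance, tss_dist, gene_id)
        for g in genes:
            giv = g.interval
            if giv.chrom != iv.chrom:
                continue
            if giv.overlaps(iv):
                d = 0
            elif giv.start >= iv.end:
                d = giv.start - iv.end
            else:
                d = iv.start - giv.end
            if d >= max_dist:
                continue
            mid = iv.midpoint
            tss_d = abs(mid - g.tss)
            key = (d, tss_d, g.gene_id)
            if best is None or key < best:
                best = key
        if best is None:
            out.append(GeneAssignment(cluster_id, None, None))
        else:
            out.append(GeneAssignment(cluster_id, best[2], best[0]))
    return out


@dataclass
class GeneClassEnrichment:
    """Observed vs expected gene-class fractions with exact binomial p.

    Expected fractions are the class frequencies among all Pol II-positive
    genes; p-values are two-sided exact binomial tails, reported raw with
    a Benjamini-Hochberg column for transparency.
    """

    classes: list[str]
    observed_fraction: dict[str, float]
    expected_fraction: dict[str, float]
    p_value: dict[str, float]
    p_bh: dict[str, float]
    direction: dict[str, str]
    n_assigned: int

    def __post_init__(self) -> None:
        for fracs in (self.observed_fraction, self.expected_fraction):
            if abs(sum(fracs.values()) - 1.0) > 1e-9:
                raise ValueError("class fractions must sum to 1")


def gene_class_enrichment(
    assigned_gene_classes: Sequence[str],
    polII_positive_gene_classes: Sequence[str],
    classes: Sequence[str] = ("constitutive", "inducible", "repressed"),
) -> GeneClassEnrichment:
    """Per-class over/under-representation of assigned genes.

    ``assigned_gene_classes``: regulation label of the gene each cluster
    was assigned to.  ``polII_positive_gene_classes``: labels of the full
    Pol II-positive gene universe, which defines the expected fractions.
    """
    if not assigned_gene_classes:
        raise ValueError("empty assignment set")
    if not polII_positive_gene_classes:
        raise ValueError("Pol II-positive gene set must be non-empty")
    n = len(assigned_gene_classes)
    n_univ = len(polII_positive_gene_classes)
    observed: dict[str, float] = {}
    expected: dict[str, float] = {}
    pvals: dict[str, float] = {}
    direction: dict[str, str] = {}
    for cls in classes:
        k = sum(1 for c in assigned_gene_classes if c == cls)
        q = sum(1 for c in polII_positive_gene_classes if c == cls) / n_univ
        observed[cls] = k / n
        expected[cls] = q
        if q in (0.0, 1.0):
            pvals[cls] = 1.0 if observed[cls] == q else 0.0
        else:
            pvals[cls] = float(stats.binomtest(k, n, q, alternative="two-sided").pvalue)
        if observed[cls] > q:
            direction[cls] = "over"
        elif observed[cls] < q:
            direction[cls] = "under"
        else:
            direction[cls] = "n.s."
    raw = np.asarray([pvals[c] for c in classes])
    bh = _benjamini_hochberg(raw)
    return GeneClassEnrichment(
        classes=list(classes),
        observed_fraction=observed,
        expected_fraction=expected,
        p_value=pvals,
        p_bh={c: float(v) for c, v in zip(classes, bh)},
        direction=direction,
        n_assigned=n,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# Distances and transcriptional support
# ---------------------------------------------------------------------------

@dataclass
class DistanceSummary:
    distances: list[int]
    n_none: int

    @property
    def median(self) -> float | None:
        return float(np.median(self.distances)) if self.distances else None

    @property
    def quartiles(self) -> tuple[float, float] | None:
        if not self.distances:
            return None
        q1, q3 = np.percentile(self.distances, [25, 75])
        return float(q1), float(q3)


def distance_to_nearest_distribution(
    clusters: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
) -> DistanceSummary:
    """Per-cluster distance to the closest peak; chromosome misses counted."""
    if not clusters or not peaks:
        raise ValueError("both interval sets must be non-empty")
    distances: list[int] = []
    n_none = 0
    for c in clusters:
        d = nearest_distance(c, peaks)
        if d is None:
            n_none += 1
        else:
            distances.append(d)
    return DistanceSummary(distances, n_none)


def median_intra_region_cage_distance(
    region: GenomicInterval,
    cage_clusters: Sequence[GenomicInterval],
) -> float | str:
    """Median spacing of CAGE cluster midpoints inside one region.

    Collects the CAGE clusters overlapping the region; with >= 2 of them,
    returns the median of consecutive midpoint-to-midpoint distances,
    otherwise "single" (one cluster) or "none".  Tight spacing indicates a
    focused TSS; broad spacing indicates dispersed initiation, as at
    transcribed enhancers.
    """
    mids = sorted(
        c.midpoint for c in cage_clusters if c.overlaps(region)
    )
    if not mids:
        return "none"
    if len(mids) == 1:
        return "single"
    return float(np.median(np.diff(mids)))


@dataclass
class SupportComparison:
    supported: list[bool]
    polII_cpm: list[float]

    @property
    def median_supported(self) -> float | None:
        vals = [c for s, c in zip(self.supported, self.polII_cpm) if s]
        return float(np.median(vals)) if vals else None

    @property
    def median_unsupported(self) -> float | None:
        vals = [c for s, c in zip(self.supported, self.polII_cpm) if not s]
        return float(np.median(vals)) if vals else None

    @property
    def log10_ratio(self) -> float | None:
        ms, mu = self.median_supported, self.median_unsupported
        if ms is None or mu is None or ms <= 0 or mu <= 0:
            return None
        return float(np.log10(ms / mu))


def tag_support_comparison(
    clusters: Sequence[GenomicInterval],
    rnaseq: TagTrack,
    polII: TagTrack,
) -> SupportComparison:
    """RNA-seq support flag per cluster and Pol II occupancy by group.

    A cluster is supported when >= 1 RNA-seq tag falls inside it; the
    comparison reports per-group median Pol II tags-per-million and their
    log10 ratio.
    """
    if rnaseq.library_size == 0 or polII.library_size == 0:
        raise ValueError("tracks must be non-empty")
    lib = polII.library_size
    supported: list[bool] = []
    cpm: list[float] = []
    for c in clusters:
        supported.append(count_tags(rnaseq, c) >= 1)
        cpm.append(count_tags(polII, c) / lib * 1e6)
    return SupportComparison(supported, cpm)
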