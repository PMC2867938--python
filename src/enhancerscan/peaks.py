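"""Curation of extragenic Pol II peaks and their regulation classes.

The workflow mirrors the annotation strategy for extragenic transcription
sites: start from Pol II peak calls, remove everything overlapping gene
bodies or the 10 kb window downstream of a gene's 3' end, drop peaks whose
signal is continuous with an upstream transcribed gene (read-through), then
classify each surviving peak as constitutive / inducible / repressed from
its per-condition tag counts, and finally cluster peaks and discard
clusters overlapping protein-coding genes.
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
    group_into_clusters,
)

REGULATION_CLASSES = ("constitutive", "inducible", "repressed")
SIGNATURE_CLASSES = ("enhancer", "promoter", "unpredictable", "unassigned")


@dataclass
class PolIIPeak:
    """An extragenic Pol II site with summit, tag counts and regulation."""

    interval: GenomicInterval
    summit: int
    tags_ut: int = 0
    tags_lps: int = 0
    regulation: str | None = None
    regulation_p: float | None = None
    signature_class: str = "unassigned"
    peak_id: str | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")
        if self.tags_ut < 0 or self.tags_lps < 0:
            raise ValueError("tag counts must be >= 0")
        if self.regulation is not None and self.regulation not in REGULATION_CLASSES:
            raise ValueError(f"unknown regulation label {self.regulation!r}")
        if self.signature_class not in SIGNATURE_CLASSES:
            raise ValueError(f"unknown signature class {self.signature_class!r}")


@dataclass
class PeakCluster:
    """Merged Pol II peaks with majority class/regulation labels."""

    interval: GenomicInterval
    member_peaks: list[PolIIPeak]
    signature_class: str = "unassigned"
    regulation: str | None = None
    assigned_gene: str | None = None
    assigned_gene_distance: int | None = None
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.member_peaks:
            raise ValueError("cluster must have at least one member peak")
        self.member_peaks.sort(key=lambda p: p.interval.start)
        span_start = min(p.interval.start for p in self.member_peaks)
        span_end = max(p.interval.end for p in self.member_peaks)
        if (self.interval.start, self.interval.end) != (span_start, span_end):
            raise ValueError("cluster interval must equal the span of its members")

    @property
    def summit(self) -> int:
        """Summit of the strongest member (pooled tags), leftmost on ties."""
        best = max(
            self.member_peaks,
            key=lambda p: (p.tags_ut + p.tags_lps, -p.interval.start),
        )
        return best.summit


# ---------------------------------------------------------------------------
# Summit detection
# ---------------------------------------------------------------------------

def find_summit(
    track: TagTrack, interval: GenomicInterval, smooth_bp: int = 50
) -> int:
    """Position maximizing the tag count in a sliding window of smooth_bp.

    The window at base p covers [p - smooth_bp//2, p - smooth_bp//2 +
    smooth_bp).  The maximal windowed count typically forms a plateau of
    tied bases; the summit is the midpoint of the leftmost such plateau
    (so a single tag pile maps to the pile itself), and an interval with
    no signal returns its midpoint.
    """
    if smooth_bp < 1:
        raise ValueError("smooth_bp must be >= 1")
    pos = track.chrom_positions(interval.chrom)
    if count_tags(track, interval) == 0:
        return interval.midpoint
    candidates = np.arange(interval.start, interval.end, dtype=np.int64)
    lo = candidates - smooth_bp // 2
    hi = lo + smooth_bp
    counts = np.searchsorted(pos, hi, side="left") - np.searchsorted(
        pos, lo, side="left"
    )
    best = int(np.max(counts))
    i = int(np.argmax(counts))
    j = i
    while j + 1 < counts.size and counts[j + 1] == best:
        j += 1
    return int((candidates[i] + candidates[j]) // 2)


# ---------------------------------------------------------------------------
# Extragenic filtering
# ---------------------------------------------------------------------------

def _flank3_interval(gene: GeneModel, flank3_bp: int) -> GenomicInterval | None:
    """Strand-aware window covering [tes, tes + flank3_bp] downstream."""
    if flank3_bp <= 0:
        return None
    iv = gene.interval
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.end - 1, iv.end + flank3_bp)
    return GenomicInterval(iv.chrom, max(0, iv.start - flank3_bp), iv.start + 1)


def _has_continuous_coverage(
    track: TagTrack, chrom: str, start: int, end: int, gap_bp: int
) -> bool:
    """True when no window of gap_bp within [start, end) lacks tags."""
    if end - start < gap_bp:
        return True
    pos = track.chrom_positions(chrom)
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    inside = pos[lo:hi]
    bounds = np.concatenate(([start - 1], inside, [end]))
    return int(np.max(np.diff(bounds))) < gap_bp


def filter_extragenic(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    polII: TagTrack | None = None,
    flank3_bp: int = 10_000,
    continuity_gap_bp: int = 500,
    transcribed_min_tags: int = 1,
) -> tuple[list[GenomicInterval], list[tuple[GenomicInterval, str]]]:
    """Retain peaks with no gene-body / 3' flank overlap or read-through.

    Three rejection rules:
      (a) overlap of >= 1 bp with any gene body;
      (b) overlap with the strand-aware [tes, tes + flank3_bp] window;
      (c) continuous Pol II coverage (no zero-tag window of
          continuity_gap_bp) between the peak and the 3' end of the
          nearest upstream transcribed gene — read-through signal.

    Returns (retained peaks, rejection log of (peak, rule)).
    """
    body_index = IntervalIndex([g.interval for g in genes])
    flanks = [f for g in genes if (f := _flank3_interval(g, flank3_bp))]
    flank_index = IntervalIndex(flanks)

    transcribed: list[GeneModel] = []
    if polII is not None:
        for g in genes:
            if count_tags(polII, g.interval) >= transcribed_min_tags:
                transcribed.append(g)

    retained: list[GenomicInterval] = []
    rejected: list[tuple[GenomicInterval, str]] = []
    for peak in peaks:
        if body_index.overlaps_interval(peak):
            rejected.append((peak, "gene_body_overlap"))
            continue
        if flank_index.overlaps_interval(peak):
            rejected.append((peak, "3prime_flank"))
            continue
        if polII is not None and _is_readthrough(
            peak, transcribed, polII, continuity_gap_bp
        ):
            rejected.append((peak, "upstream_continuity"))
            continue
        retained.append(peak)
    return retained, rejected


def _is_readthrough(
    peak: GenomicInterval,
    transcribed: Sequence[GeneModel],
    polII: TagTrack,
    continuity_gap_bp: int,
) -> bool:
    best_gap: tuple[int, int, int] | None = None  # (gap_len, start, end)
    for g in transcribed:
        iv = g.interval
        if iv.chrom != peak.chrom:
            continue
        if iv.strand == "+" and iv.end <= peak.start:
            gap = (peak.start - iv.end, iv.end, peak.start)
        elif iv.strand == "-" and iv.start >= peak.end:
            gap = (iv.start - peak.end, peak.end, iv.start)
        else:
            continue
        if best_gap is None or gap[0] < best_gap[0]:
            best_gap = gap
    if best_gap is None:
        return False
    _, start, end = best_gap
    return _has_continuous_coverage(polII, peak.chrom, start, end, continuity_gap_bp)


# ---------------------------------------------------------------------------
# Regulation classes
# ---------------------------------------------------------------------------

def classify_regulation(
    tags_ut: int,
    tags_lps: int,
    libsize_ut: int,
    libsize_lps: int,
    fold_min: float = 2.0,
    p_max: float = 1e-3,
) -> tuple[str, float]:
    """Constitutive / inducible / repressed call for one peak.

    The test is a conditional exact binomial on (tags_ut, tags_lps): given
    n = tags_ut + tags_lps, the stimulated count is Binomial(n, q) with
    q = libsize_lps / (libsize_ut + libsize_lps) under no change.  The
    fold is computed on tags-per-million with a pseudocount of 1 tag.
    """
    if libsize_ut <= 0 or libsize_lps <= 0:
        raise ValueError("library sizes must be > 0")
    n = tags_ut + tags_lps
    q = libsize_lps / (libsize_ut + libsize_lps)
    if n == 0:
        return "constitutive", 1.0
    p = stats.binomtest(tags_lps, n, q, alternative="two-sided").pvalue
    cpm_ut = (tags_ut + 1) / libsize_ut * 1e6
    cpm_lps = (tags_lps + 1) / libsize_lps * 1e6
    fold = cpm_lps / cpm_ut
    if fold >= fold_min and p <= p_max:
        return "inducible", float(p)
    if 1.0 / fold >= fold_min and p <= p_max:
        return "repressed", float(p)
    return "constitutive", float(p)


def annotate_peaks(
    intervals: Sequence[GenomicInterval],
    track_ut: TagTrack,
    track_lps: TagTrack,
    fold_min: float = 2.0,
    p_max: float = 1e-3,
    smooth_bp: int = 50,
) -> list[PolIIPeak]:
    """Build PolIIPeak records (summit, counts, regulation) for intervals.

    The summit is located on the pooled untreated+stimulated signal.
    """
    pooled = TagTrack(
        {
            c: np.sort(
                np.concatenate(
                    [track_ut.chrom_positions(c), track_lps.chrom_positions(c)]
                )
            )
            for c in set(track_ut.positions) | set(track_lps.positions)
        }
    )
    lib_ut, lib_lps = track_ut.library_size, track_lps.library_size
    out: list[PolIIPeak] = []
    for i, iv in enumerate(intervals):
        tags_ut = count_tags(track_ut, iv)
        tags_lps = count_tags(track_lps, iv)
        label, p = classify_regulation(
            tags_ut, tags_lps, lib_ut, lib_lps, fold_min, p_max
        )
        out.append(
            PolIIPeak(
                interval=iv,
                summit=find_summit(pooled, iv, smooth_bp),
                tags_ut=tags_ut,
                tags_lps=tags_lps,
                regulation=label,
                regulation_p=p,
                peak_id=iv.name or f"peak_{i:05d}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _majority(labels: Sequence[str], tie_value: str) -> str:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == best)
    return winners[0] if len(winners) == 1 else tie_value


def cluster_and_filter(
    peaks: Sequence[PolIIPeak],
    ensembl_genes: Sequence[GeneModel],
    cluster_gap_bp: int = 2000,
) -> list[PeakCluster]:
    """Merge peaks into clusters and drop those with protein-coding overlap.

    Cluster regulation is the majority member label (tie -> constitutive);
    cluster signature class is the majority member class (tie ->
    unpredictable).
    """
    coding_index = IntervalIndex(
        [g.interval for g in ensembl_genes if g.is_protein_coding]
    )
    grouped = group_into_clusters([p.interval for p in peaks], cluster_gap_bp)
    by_key: dict[tuple[str, int, int], list[PolIIPeak]] = {}
    for p in peaks:
        key = (p.interval.chrom, p.interval.start, p.interval.end)
        by_key.setdefault(key, []).append(p)
    clusters: list[PeakCluster] = []
    n = 0
    for chrom in sorted(grouped):
        for members_iv in grouped[chrom]:
            members = [
                by_key[(iv.chrom, iv.start, iv.end)].pop() for iv in members_iv
            ]
            span = GenomicInterval(
                chrom,
                min(p.interval.start for p in members),
                max(p.interval.end for p in members),
            )
            if coding_index.overlaps_interval(span):
                continue
            regs = [p.regulation for p in members if p.regulation is not None]
            cluster = PeakCluster(
                interval=span,
                member_peaks=members,
                signature_class=_majority(
                    [p.signature_class for p in members], "unpredictable"
                ),
                regulation=_majority(regs, "constitutive") if regs else None,
                cluster_id=f"cluster_{n:05d}",
            )
            clusters.append(cluster)
            n += 1
    return clusters


# ---------------------------------------------------------------------------
# Fallback peak caller (synthetic pipeline entry point)
# ---------------------------------------------------------------------------

def call_peaks(
    track: TagTrack,
    chrom_sizes: Mapping[str, int],
    window_bp: int = 500,
    step_bp: int = 50,
    p_threshold: float = 1e-5,
    min_width: int = 200,
) -> list[GenomicInterval]:
    """Minimal sliding-window Poisson peak caller vs a global background.

    Windows of window_bp sliding by step_bp are tested against a Poisson
    background with rate library_size * window_bp / genome_size; windows
    with p < p_threshold are merged (gap <= step_bp) and merged spans
    shorter than min_width are dropped.  This is a deliberately simple
    entry point for synthetic data; real studies should supply external
    peak calls.
    """
    genome_size = sum(chrom_sizes.values())
    lam = track.library_size * window_bp / genome_size
    peaks: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        pos = track.chrom_positions(chrom)
        if pos.size == 0:
            continue
        starts = np.arange(0, max(1, size - window_bp + 1), step_bp, dtype=np.int64)
        counts = np.searchsorted(pos, starts + window_bp, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        pvals = stats.poisson.sf(counts - 1, lam)
        sig = pvals < p_threshold
        if not np.any(sig):
            continue
        windows = [
            GenomicInterval(chrom, int(s), int(s) + window_bp)
            for s in starts[sig]
        ]
        merged = group_into_clusters(windows, max_gap=0)[chrom]
        for members in merged:
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            if end - start >= min_width:
                peaks.append(GenomicInterval(chrom, start, min(end, size)))
    return peaks
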