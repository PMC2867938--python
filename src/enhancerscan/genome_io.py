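"""Readers/writers for genomic file formats and the interval/tag-track engine.

All coordinates are 0-based half-open (BED convention) throughout the
package.  Gene-table dialects are converted to this convention on read.
ChIP-seq tags are reduced to their 5' position: the ``start`` of the read
for + strand tags and ``end - 1`` for - strand tags, since tag counting is
directional-read based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

BASES = "ACGT"


class ParseError(ValueError):
    """Raised when a text input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expanded(self, slop: int, chrom_size: int | None = None) -> "GenomicInterval":
        """Symmetric extension by ``slop`` bp, clipped to [0, chrom_size)."""
        start = max(0, self.start - slop)
        end = self.end + slop
        if chrom_size is not None:
            end = min(end, chrom_size)
        return replace(self, start=start, end=end)


@dataclass
class TagTrack:
    """Sorted 5' tag positions per chromosome plus the library size.

    ``positions`` maps chromosome name to a sorted int64 array of tag 5'
    coordinates.  Duplicate tags are kept by default (whether the original
    study collapsed duplicates is unstated; collapsing is the caller's
    choice via :meth:`deduplicated`).
    """

    positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.positions[chrom] = arr

    @property
    def library_size(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))

    def deduplicated(self) -> "TagTrack":
        return TagTrack({c: np.unique(p) for c, p in self.positions.items()})


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES derived from its interval."""

    gene_id: str
    interval: GenomicInterval
    is_protein_coding: bool

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


@dataclass
class ConservationTrack:
    """Per-base conservation scores in [0, 1]; NaN marks missing bases."""

    scores: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.scores.items():
            arr = np.asarray(arr, dtype=np.float32)
            defined = arr[~np.isnan(arr)]
            if defined.size and (defined.min() < 0 or defined.max() > 1):
                raise ValueError(f"{chrom}: conservation scores must lie in [0, 1]")
            self.scores[chrom] = arr

    def region_scores(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); out-of-track bases are NaN."""
        out = np.full(end - start, np.nan, dtype=np.float32)
        arr = self.scores.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


@dataclass(frozen=True)
class PWM:
    """Position weight matrix (per-position base probabilities over ACGT)."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) probabilities
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("matrix must have shape (L, 4)")
        if mat.shape[0] < 4:
            raise ValueError("matrix length must be >= 4")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1 +- 1e-9")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
    ) -> "PWM":
        """Convert a count matrix to probabilities with a per-cell pseudocount."""
        counts = np.asarray(counts, dtype=float)
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=1, keepdims=True)
        if background is None:
            background = np.full(4, 0.25)
        return cls(motif_id, probs, pseudocount, np.asarray(background, float))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.pseudocount,
            self.background[::-1].copy(),
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path, min_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into a list of intervals, in file order.

    ``track``/``browser``/``#`` lines are skipped.  Malformed coordinates
    raise :class:`ParseError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < min_columns:
            raise ParseError(
                f"{path}:{lineno}: expected >= {min_columns} columns, got {len(fields)}"
            )
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = fields[3] if len(fields) > 3 else None
        score: float | None = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, strand, name, score)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    header: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


_GENE_DIALECTS = ("simple_tsv", "ucsc_known", "ensembl")


def read_gene_table(path: str | Path, dialect: str = "simple_tsv") -> list[GeneModel]:
    """Read a gene table; strand-aware TSS/TES are derived on access.

    Dialects: ``simple_tsv`` (id, chrom, start, end, strand, is_protein_coding;
    0-based half-open), ``ucsc_known`` (name, chrom, strand, txStart, txEnd;
    0-based half-open, all protein-coding unless a 6th column says otherwise)
    and ``ensembl`` (gene_id, chrom, start, end, strand, biotype; 1-based
    inclusive, converted on read).
    """
    if dialect not in _GENE_DIALECTS:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if dialect == "simple_tsv":
            gid, chrom, start, end, strand, coding = fields[:6]
            start_i, end_i = int(start), int(end)
            is_coding = coding not in ("0", "false", "False")
        elif dialect == "ucsc_known":
            gid, chrom, strand, start, end = fields[:5]
            start_i, end_i = int(start), int(end)
            is_coding = fields[5] not in ("0", "false") if len(fields) > 5 else True
        else:  # ensembl: 1-based inclusive
            gid, chrom, start, end, strand, biotype = fields[:6]
            start_i, end_i = int(start) - 1, int(end)
            is_coding = biotype == "protein_coding"
        if gid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        try:
            genes.append(
                GeneModel(gid, GenomicInterval(chrom, start_i, end_i, strand), is_coding)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_tag_track(path: str | Path) -> TagTrack:
    """Read a BED6 tag file into a :class:`TagTrack` of 5' positions."""
    by_chrom: dict[str, list[int]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: tag lines must be BED6")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end ({end}) must be > start ({start})")
        strand = fields[5]
        five_prime = start if strand != "-" else end - 1
        by_chrom.setdefault(chrom, []).append(five_prime)
    return TagTrack(
        {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}
    )


def write_tag_track(track: TagTrack, path: str | Path, tag_len: int = 36) -> None:
    """Write a tag track back to BED6 (all tags emitted on the + strand)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            for p in track.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + tag_len}\ttag\t0\t+\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int]
) -> ConservationTrack:
    """Expand a bedGraph into dense per-base score arrays (NaN = no data)."""
    arrays = {
        chrom: np.full(size, np.nan, dtype=np.float32)
        for chrom, size in chrom_sizes.items()
    }
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in arrays:
            continue
        arrays[chrom][start : min(end, chrom_sizes[chrom])] = value
    return ConservationTrack(arrays)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_jaspar(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Parse JASPAR plain-text count matrices into probability PWMs.

    Parsing is delegated to Bio.motifs; counts are converted to
    probabilities with a small per-cell pseudocount to avoid log(0).
    """
    from Bio import motifs as bio_motifs

    pwms: list[PWM] = []
    with open(path) as fh:
        for record in bio_motifs.parse(fh, "jaspar"):
            counts = np.column_stack(
                [np.asarray(record.counts[b], dtype=float) for b in BASES]
            )
            motif_id = record.matrix_id or record.name
            pwms.append(PWM.from_counts(motif_id, counts, pseudocount))
    return pwms


def write_jaspar(
    motifs: Sequence[tuple[str, np.ndarray]], path: str | Path
) -> None:
    """Write count matrices in JASPAR plain-text format."""
    with open(path, "w") as fh:
        for motif_id, counts in motifs:
            fh.write(f">{motif_id} {motif_id}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{int(c):6d}" for c in counts[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Interval / tag arithmetic
# ---------------------------------------------------------------------------

def count_tags(track: TagTrack, interval: GenomicInterval) -> int:
    """Number of tag 5' positions p with start <= p < end (binary search).

    A chromosome absent from the track counts as zero signal (sparse
    synthetic genomes), with a debug note rather than an error.
    """
    pos = track.positions.get(interval.chrom)
    if pos is None:
        log.debug("chromosome %s absent from track; count 0", interval.chrom)
        return 0
    lo = np.searchsorted(pos, interval.start, side="left")
    hi = np.searchsorted(pos, interval.end, side="left")
    return int(hi - lo)


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose boundary gap is <= max_gap, per chromosome.

    Output is sorted by (chrom, start); the base-pair union is preserved
    and the merge is idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for group in group_into_clusters(intervals, max_gap).values():
        for members in group:
            merged.append(
                GenomicInterval(
                    members[0].chrom,
                    min(m.start for m in members),
                    max(m.end for m in members),
                )
            )
    merged.sort(key=lambda iv: (iv.chrom, iv.start))
    return merged


def group_into_clusters(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> dict[str, list[list[GenomicInterval]]]:
    """Partition intervals into per-chromosome clusters at gap <= max_gap.

    Each cluster is the list of member intervals sorted by start; this is
    the membership-preserving core behind :func:`merge_intervals`.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: dict[str, list[list[GenomicInterval]]] = {}
    for chrom, ivs in sorted(by_chrom.items()):
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
        clusters: list[list[GenomicInterval]] = []
        current = [ivs[0]]
        current_end = ivs[0].end
        for iv in ivs[1:]:
            if iv.start - current_end <= max_gap:
                current.append(iv)
                current_end = max(current_end, iv.end)
            else:
                clusters.append(current)
                current = [iv]
                current_end = iv.end
        clusters.append(current)
        out[chrom] = clusters
    return out


def nearest_distance(
    query: GenomicInterval, subjects: Sequence[GenomicInterval]
) -> int | None:
    """Boundary-gap distance to the nearest subject (0 if any overlaps).

    Returns None when no subject lies on the query's chromosome.
    """
    best: int | None = None
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        if s.overlaps(query):
            return 0
        gap = s.start - query.end if s.start >= query.end else query.start - s.end
        if best is None or gap < best:
            best = gap
    return best


class IntervalIndex:
    """Sorted, merged interval set per chromosome for O(log n) overlap tests."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals, max_gap=0):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
        for chrom in list(self._starts):
            self._starts[chrom] = np.asarray(self._starts[chrom], dtype=np.int64)
            self._ends[chrom] = np.asarray(self._ends[chrom], dtype=np.int64)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start

    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        return self.overlaps(iv.chrom, iv.start, iv.end)

    def overlaps_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized overlap test for many intervals on one chromosome."""
        f_starts = self._starts.get(chrom)
        if f_starts is None:
            return np.zeros(len(starts), dtype=bool)
        f_ends = self._ends[chrom]
        i = np.searchsorted(f_starts, ends, side="left")
        hit = i > 0
        hit[hit] = f_ends[i[hit] - 1] > starts[hit]
        return hit


def sample_random_intervals(
    rng: np.random.Generator,
    template: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    exclude: IntervalIndex | None = None,
    max_tries: int = 200,
) -> list[GenomicInterval]:
    """Length-matched random intervals, uniform on each template's chromosome.

    Placements overlapping ``exclude`` are rejection-sampled; after
    ``max_tries`` failures the last draw is kept so the routine always
    returns one interval per template.
    """
    out: list[GenomicInterval] = []
    for iv in template:
        size = chrom_sizes[iv.chrom]
        length = len(iv)
        hi = max(1, size - length)
        start = 0
        for _ in range(max_tries):
            start = int(rng.integers(0, hi))
            if exclude is None or not exclude.overlaps(iv.chrom, start, start + length):
                break
        out.append(GenomicInterval(iv.chrom, start, start + length))
    return out
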