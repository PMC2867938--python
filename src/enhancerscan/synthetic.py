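"""Seeded generator of a toy genome with the structure the pipeline assumes.

The generator emulates the statistical structure of stimulated-macrophage
ChIP-seq around extragenic transcription sites: sharp, high Pol II peaks
and H3K4me3 at TSSs versus broad, low Pol II and bimodal H3K4me1 at
enhancers; condition-dependent fold changes for inducible and repressed
elements; CpG islands biased to promoters; elevated conservation at
functional elements; p300/PU.1 binding mostly at enhancers; tight CAGE
clusters at promoters versus dispersed ones at enhancers; RNA-seq tags
proportional to Pol II signal; and inflammatory-TF motif instances
planted in inducible enhancers.  Everything is drawn from one seeded
generator, so the same spec and seed produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import BASES, GenomicInterval, write_jaspar

REGULATION_CLASSES = ("constitutive", "inducible", "repressed")

# Count matrix of the planted inflammatory motif (NF-kB-like consensus
# GGGACTTTCC), 100 observations per column.
PLANTED_MOTIF_ID = "SYN_NFKB"
_PLANTED_CONSENSUS = "GGGACTTTCC"


@dataclass(frozen=True)
class SyntheticSpec:
    """All tunables of the toy genome, with the default study conditions."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 60
    n_enhancers: int = 120
    n_promoter_ncrna: int = 40
    # regulation fractions (constitutive, inducible, repressed)
    frac_constitutive: float = 0.20
    frac_inducible: float = 0.32
    frac_repressed: float = 0.48
    polII_mean_tags: float = 60.0
    gene_body_tags_per_kb: float = 15.0
    gene_tss_mean_tags: float = 50.0
    me1_mean_tags: float = 300.0
    me3_mean_tags: float = 300.0
    inducible_fold: float = 4.0
    cpg_at_promoter_prob: float = 0.25
    cpg_at_gene_tss_prob: float = 0.72
    cpg_at_enhancer_prob: float = 0.005
    conservation_background: float = 0.08
    conservation_functional: float = 0.55
    noise_tags_per_kb: float = 0.1
    p300_fraction: float = 0.8
    pu1_enhancer_fraction: float = 0.85
    pu1_promoter_fraction: float = 0.70
    ser5_mean_tags: float = 30.0
    rnaseq_per_polII_tag: float = 0.5
    motifs_per_inducible_enhancer: int = 3
    n_decoy_motifs: int = 10
    seed: int = 1

    def validate(self) -> None:
        fracs = self.frac_constitutive + self.frac_inducible + self.frac_repressed
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError("regulation fractions must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_enhancers", "n_promoter_ncrna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inducible_fold < 1:
            raise ValueError("inducible_fold must be >= 1")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class TruthElement:
    element_id: str
    interval: GenomicInterval
    element_class: str  # enhancer | promoter
    regulation: str
    has_cpg: bool
    conserved: bool
    n_planted_motifs: int


@dataclass
class SyntheticTruth:
    elements: list[TruthElement]
    gene_regulation: dict[str, str]

    def by_class(self, element_class: str) -> list[TruthElement]:
        return [e for e in self.elements if e.element_class == element_class]


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def _place_intervals(
    rng: np.random.Generator,
    n: int,
    lengths: Sequence[int],
    chrom_sizes: dict[str, int],
    occupied: dict[str, list[tuple[int, int]]],
    clearance: int,
    max_tries: int = 2000,
) -> list[GenomicInterval]:
    """Place n non-overlapping intervals >= clearance bp from occupied ones."""
    chroms = sorted(chrom_sizes)
    out: list[GenomicInterval] = []
    for i in range(n):
        length = int(lengths[i])
        placed = False
        for _ in range(max_tries):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            size = chrom_sizes[chrom]
            if size - length - clearance <= clearance:
                continue
            start = int(rng.integers(clearance, size - length - clearance))
            end = start + length
            clear = all(
                end + clearance <= s or start - clearance >= e
                for s, e in occupied.get(chrom, [])
            )
            if clear:
                occupied.setdefault(chrom, []).append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                "could not place all elements; genome too crowded for spec"
            )
    return out


def _sample_regulation(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    r = rng.random()
    if r < spec.frac_constitutive:
        return "constitutive"
    if r < spec.frac_constitutive + spec.frac_inducible:
        return "inducible"
    return "repressed"


def _activity_scales(regulation: str, fold: float) -> tuple[float, float]:
    """(untreated, stimulated) activity multipliers for one element."""
    if regulation == "inducible":
        return 1.0 / fold, 1.0
    if regulation == "repressed":
        return 1.0, 1.0 / fold
    return 1.0, 1.0


class _TagCollector:
    """Accumulates tag 5' positions per chromosome for one track."""

    def __init__(self, chrom_sizes: dict[str, int]):
        self.chrom_sizes = chrom_sizes
        self.tags: dict[str, list[np.ndarray]] = {c: [] for c in chrom_sizes}

    def add(self, chrom: str, positions: np.ndarray) -> None:
        size = self.chrom_sizes[chrom]
        pos = np.clip(np.asarray(positions, dtype=np.int64), 0, size - 1)
        if pos.size:
            self.tags[chrom].append(pos)

    def write_bed(self, path: Path, tag_len: int = 36) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.tags):
                parts = self.tags[chrom]
                if not parts:
                    continue
                pos = np.sort(np.concatenate(parts))
                size = self.chrom_sizes[chrom]
                for p in pos:
                    end = min(int(p) + tag_len, size)
                    fh.write(f"{chrom}\t{p}\t{end}\ttag\t0\t+\n")


def _normal_tags(
    rng: np.random.Generator, mean_count: float, center: float, sd: float
) -> np.ndarray:
    n = rng.poisson(mean_count)
    return np.round(rng.normal(center, sd, size=n)).astype(np.int64)


def _uniform_tags(
    rng: np.random.Generator, mean_count: float, start: int, end: int
) -> np.ndarray:
    n = rng.poisson(mean_count)
    return rng.integers(start, end, size=n)


def planted_motif_counts() -> np.ndarray:
    counts = np.full((len(_PLANTED_CONSENSUS), 4), 5.0)
    for i, base in enumerate(_PLANTED_CONSENSUS):
        counts[i, BASES.index(base)] = 85.0
    return counts


def _decoy_motif_counts(rng: np.random.Generator, length: int = 10) -> np.ndarray:
    counts = np.full((length, 4), 5.0)
    for i in range(length):
        counts[i, int(rng.integers(0, 4))] = 85.0
    return counts


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write all input files for the pipeline; return (manifest, truth).

    The manifest maps file roles (polII_ut, me1, gene_table, ...) to file
    names inside ``out_dir``.  Every truth element is recoverable from the
    emitted files alone.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    chrom_sizes = spec.chrom_sizes
    fold = spec.inducible_fold

    # --- layout: genes first, then extragenic elements -------------------
    occupied: dict[str, list[tuple[int, int]]] = {}
    gene_lengths = rng.integers(8_000, 20_000, size=spec.n_genes)
    gene_ivs = _place_intervals(
        rng, spec.n_genes, gene_lengths, chrom_sizes, occupied, clearance=30_000
    )
    genes: list[tuple[str, GenomicInterval, str, bool]] = []
    for i, iv in enumerate(gene_ivs):
        strand = "+" if rng.random() < 0.5 else "-"
        coding = i >= 5  # a handful of non-coding genes for the Ensembl filter
        regulation = _sample_regulation(rng, spec)
        genes.append(
            (f"gene_{i:03d}", GenomicInterval(iv.chrom, iv.start, iv.end, strand),
             regulation, coding)
        )

    # elements need >= 12 kb clearance from genes (outside the 10 kb 3'
    # flank) and >= 6 kb from each other so every element is its own cluster
    element_occupied = {
        c: [(s - 6_000, e + 6_000) for s, e in ivs] for c, ivs in occupied.items()
    }
    enh_lengths = rng.integers(1_500, 3_000, size=spec.n_enhancers)
    enh_ivs = _place_intervals(
        rng, spec.n_enhancers, enh_lengths, chrom_sizes, element_occupied,
        clearance=6_000,
    )
    prom_lengths = np.full(spec.n_promoter_ncrna, 1_000)
    prom_ivs = _place_intervals(
        rng, spec.n_promoter_ncrna, prom_lengths, chrom_sizes, element_occupied,
        clearance=6_000,
    )

    # regulation: copy the nearest gene's label when it lies within 20 kb
    # (so inducible enhancers sit next to inducible genes), else sample
    def element_regulation(iv: GenomicInterval) -> str:
        best: tuple[int, str] | None = None
        for _, giv, reg, _ in genes:
            if giv.chrom != iv.chrom:
                continue
            if giv.start >= iv.end:
                d = giv.start - iv.end
            elif iv.start >= giv.end:
                d = iv.start - giv.end
            else:
                d = 0
            if best is None or d < best[0]:
                best = (d, reg)
        if best is not None and best[0] < 20_000 and rng.random() < 0.9:
            return best[1]
        return _sample_regulation(rng, spec)

    elements: list[TruthElement] = []
    for i, iv in enumerate(enh_ivs):
        reg = element_regulation(iv)
        n_motifs = spec.motifs_per_inducible_enhancer if reg == "inducible" else 0
        elements.append(
            TruthElement(
                f"enh_{i:03d}", iv, "enhancer", reg,
                has_cpg=bool(rng.random() < spec.cpg_at_enhancer_prob),
                conserved=True, n_planted_motifs=n_motifs,
            )
        )
    for i, iv in enumerate(prom_ivs):
        reg = element_regulation(iv)
        elements.append(
            TruthElement(
                f"prom_{i:03d}", iv, "promoter", reg,
                has_cpg=bool(rng.random() < spec.cpg_at_promoter_prob),
                conserved=True, n_planted_motifs=0,
            )
        )

    # --- tag tracks ------------------------------------------------------
    polII_ut = _TagCollector(chrom_sizes)
    polII_lps = _TagCollector(chrom_sizes)
    me1 = _TagCollector(chrom_sizes)
    me3 = _TagCollector(chrom_sizes)
    ser5 = _TagCollector(chrom_sizes)
    rnaseq = _TagCollector(chrom_sizes)

    for gid, giv, reg, _ in genes:
        s_ut, s_lps = _activity_scales(reg, fold)
        tss = giv.start if giv.strand == "+" else giv.end - 1
        len_kb = len(giv) / 1000.0
        for collector, scale in ((polII_ut, s_ut), (polII_lps, s_lps)):
            collector.add(
                giv.chrom,
                _uniform_tags(rng, spec.gene_body_tags_per_kb * len_kb * scale,
                              giv.start, giv.end),
            )
            collector.add(
                giv.chrom, _normal_tags(rng, spec.gene_tss_mean_tags * scale, tss, 150)
            )
        # TSS chromatin signature: sharp me3, flanking me1
        me3.add(giv.chrom, _normal_tags(rng, spec.me3_mean_tags, tss, 300))
        side = np.where(
            rng.random(rng.poisson(0.8 * spec.me1_mean_tags)) < 0.5, -800, 800
        )
        me1.add(giv.chrom, tss + side + np.round(
            rng.normal(0, 300, size=side.size)).astype(np.int64))
        mean_act = (s_ut + s_lps) / 2.0
        ser5.add(giv.chrom, _uniform_tags(rng, spec.ser5_mean_tags * mean_act * 2,
                                          giv.start, giv.end))
        rnaseq.add(
            giv.chrom,
            _uniform_tags(
                rng,
                spec.rnaseq_per_polII_tag * spec.gene_body_tags_per_kb * len_kb * s_ut,
                giv.start, giv.end,
            ),
        )

    for el in elements:
        iv = el.interval
        s_ut, s_lps = _activity_scales(el.regulation, fold)
        center = iv.midpoint
        if el.element_class == "enhancer":
            sd = len(iv) / 4.0
            for collector, scale in ((polII_ut, s_ut), (polII_lps, s_lps)):
                collector.add(
                    iv.chrom,
                    _normal_tags(rng, spec.polII_mean_tags * scale, center, sd),
                )
            # enhancer signature: broad bimodal me1, me3 <= 20% of me1
            n_me1 = rng.poisson(spec.me1_mean_tags)
            side = np.where(rng.random(n_me1) < 0.5, -1000, 1000)
            me1.add(iv.chrom, center + side + np.round(
                rng.normal(0, 400, size=n_me1)).astype(np.int64))
            me3.add(iv.chrom, _normal_tags(
                rng, 0.15 * spec.me1_mean_tags, center, 800))
            n_cage = 2 + rng.poisson(1)
            cage_mids = rng.integers(iv.start - 500, iv.end + 500, size=n_cage)
        else:
            for collector, scale in ((polII_ut, s_ut), (polII_lps, s_lps)):
                collector.add(
                    iv.chrom,
                    _normal_tags(rng, 1.5 * spec.polII_mean_tags * scale, center, 100),
                )
            me3.add(iv.chrom, _normal_tags(rng, spec.me3_mean_tags, center, 300))
            n_me1 = rng.poisson(0.8 * spec.me1_mean_tags)
            side = np.where(rng.random(n_me1) < 0.5, -800, 800)
            me1.add(iv.chrom, center + side + np.round(
                rng.normal(0, 300, size=n_me1)).astype(np.int64))
            n_cage = 1 + rng.poisson(1)
            cage_mids = center + np.round(
                rng.normal(0, 100, size=n_cage)).astype(np.int64)
        el_cage = cage_mids  # stored below when writing CAGE
        el.__dict__["_cage_mids"] = el_cage
        mean_act = (s_ut + s_lps) / 2.0
        ser5.add(iv.chrom, _uniform_tags(rng, spec.ser5_mean_tags * mean_act,
                                         iv.start, iv.end))
        rnaseq.add(
            iv.chrom,
            _uniform_tags(
                rng, spec.rnaseq_per_polII_tag * spec.polII_mean_tags * s_ut,
                iv.start, iv.end,
            ),
        )

    # uniform background noise
    for collector in (polII_ut, polII_lps, me1, me3, ser5, rnaseq):
        for chrom, size in sorted(chrom_sizes.items()):
            collector.add(
                chrom,
                _uniform_tags(rng, spec.noise_tags_per_kb * size / 1000.0, 0, size),
            )

    # --- point-feature BEDs ----------------------------------------------
    p300: list[GenomicInterval] = []
    pu1: list[GenomicInterval] = []
    cage: list[GenomicInterval] = []
    cpg: list[GenomicInterval] = []
    for el in elements:
        iv = el.interval
        center = iv.midpoint
        if el.element_class == "enhancer":
            if rng.random() < spec.p300_fraction:
                p300.append(GenomicInterval(iv.chrom, center - 250, center + 250,
                                            name=el.element_id))
            if rng.random() < spec.pu1_enhancer_fraction:
                pu1.append(GenomicInterval(iv.chrom, center - 150, center + 150,
                                           name=el.element_id))
        else:
            if rng.random() < spec.pu1_promoter_fraction:
                pu1.append(GenomicInterval(iv.chrom, center - 150, center + 150,
                                           name=el.element_id))
        for mid in el.__dict__["_cage_mids"]:
            cage.append(
                GenomicInterval(iv.chrom, max(0, int(mid) - 15), int(mid) + 15,
                                name=f"cage_{el.element_id}")
            )
        if el.has_cpg:
            cpg.append(GenomicInterval(iv.chrom, center - 300, center + 300,
                                       name=f"cpg_{el.element_id}"))
    for gid, giv, _, _ in genes:
        tss = giv.start if giv.strand == "+" else giv.end - 1
        if rng.random() < spec.cpg_at_gene_tss_prob:
            cpg.append(GenomicInterval(giv.chrom, max(0, tss - 300), tss + 300,
                                       name=f"cpg_{gid}"))
        for k in range(1 + int(rng.poisson(0.5))):
            mid = tss + int(np.round(rng.normal(0, 80)))
            cage.append(GenomicInterval(giv.chrom, max(0, mid - 15), mid + 15,
                                        name=f"cage_{gid}"))
    # a few background CpG islands so overlap nulls are non-degenerate
    chroms = sorted(chrom_sizes)
    for k in range(15):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - 600))
        cpg.append(GenomicInterval(chrom, start, start + 600, name=f"cpg_bg_{k:02d}"))

    # --- conservation ----------------------------------------------------
    cons_lines: list[str] = []
    step_bg, step_el = 200, 50
    for chrom in chroms:
        size = chrom_sizes[chrom]
        n_steps = size // step_bg
        values = np.clip(
            rng.normal(spec.conservation_background, 0.03, size=n_steps), 0.0, 1.0
        )
        starts = np.arange(n_steps) * step_bg
        overrides: list[tuple[int, int, np.ndarray]] = []
        for el in elements:
            if el.interval.chrom != chrom:
                continue
            s, e = el.interval.start, el.interval.end
            n_el = (e - s) // step_el + 1
            overrides.append(
                (s, e, np.clip(
                    rng.normal(spec.conservation_functional, 0.05, size=n_el),
                    0.0, 1.0,
                ))
            )
        # write background, punching out element spans
        override_spans = sorted((s, e, v) for s, e, v in overrides)
        oi = 0
        for start, value in zip(starts, values):
            end = min(start + step_bg, size)
            inside = any(s < end and start < e for s, e, _ in override_spans)
            if not inside:
                cons_lines.append(f"{chrom}\t{start}\t{end}\t{value:.4f}")
        for s, e, vals in override_spans:
            for j, v in enumerate(vals):
                seg_start = s + j * step_el
                seg_end = min(seg_start + step_el, e)
                if seg_start >= seg_end:
                    break
                cons_lines.append(f"{chrom}\t{seg_start}\t{seg_end}\t{v:.4f}")

    # --- sequence and motifs ---------------------------------------------
    planted_counts = planted_motif_counts()
    planted_probs = (planted_counts + 0.01) / (planted_counts + 0.01).sum(
        axis=1, keepdims=True
    )
    motif_library: list[tuple[str, np.ndarray]] = [
        (PLANTED_MOTIF_ID, planted_counts)
    ]
    for k in range(spec.n_decoy_motifs):
        motif_library.append((f"DECOY_{k:02d}", _decoy_motif_counts(rng)))

    sequences: dict[str, np.ndarray] = {}
    for chrom in chroms:
        sequences[chrom] = rng.integers(0, 4, size=chrom_sizes[chrom], dtype=np.int8)
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    L = planted_probs.shape[0]
    for el in elements:
        if el.n_planted_motifs == 0:
            continue
        iv = el.interval
        offsets = rng.integers(iv.start, iv.end - L, size=el.n_planted_motifs)
        for off in offsets:
            inst = np.array(
                [rng.choice(4, p=planted_probs[j]) for j in range(L)], dtype=np.int8
            )
            sequences[iv.chrom][int(off) : int(off) + L] = inst

    # --- write everything --------------------------------------------------
    manifest: dict[str, str] = {}

    def _path(role: str, name: str) -> Path:
        manifest[role] = name
        return out / name

    with open(_path("gene_table", "genes.tsv"), "w") as fh:
        fh.write("# id\tchrom\tstart\tend\tstrand\tis_protein_coding\n")
        for gid, giv, _, coding in genes:
            fh.write(
                f"{gid}\t{giv.chrom}\t{giv.start}\t{giv.end}\t{giv.strand}\t"
                f"{int(coding)}\n"
            )
    with open(_path("chrom_sizes", "chrom_sizes.tsv"), "w") as fh:
        for chrom in chroms:
            fh.write(f"{chrom}\t{chrom_sizes[chrom]}\n")

    polII_ut.write_bed(_path("polII_ut", "polII_ut.bed"))
    polII_lps.write_bed(_path("polII_lps", "polII_lps.bed"))
    me1.write_bed(_path("me1", "h3k4me1.bed"))
    me3.write_bed(_path("me3", "h3k4me3.bed"))
    ser5.write_bed(_path("ser5", "ser5_polII.bed"))
    rnaseq.write_bed(_path("rnaseq", "rnaseq_nuclear.bed"))

    def _write_bed(role: str, name: str, intervals: list[GenomicInterval]) -> None:
        with open(_path(role, name), "w") as fh:
            for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t.\n"
                )

    _write_bed("p300", "p300_peaks.bed", p300)
    _write_bed("pu1", "pu1_peaks.bed", pu1)
    _write_bed("cage", "cage_clusters.bed", cage)
    _write_bed("cpg", "cpg_islands.bed", cpg)

    with open(_path("conservation", "conservation.bedgraph"), "w") as fh:
        fh.write("\n".join(cons_lines) + "\n")

    with open(_path("genome_fasta", "genome.fa"), "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            seq_bytes = base_arr[sequences[chrom]].tobytes().decode()
            for i in range(0, len(seq_bytes), 80):
                fh.write(seq_bytes[i : i + 80] + "\n")

    # background pools: one whole chromosome and the 5 kb upstream of TSSs
    bg_chrom = chroms[-1]
    with open(_path("bg_chromosome", "background_chromosome.fa"), "w") as fh:
        fh.write(f">{bg_chrom}\n")
        seq_bytes = base_arr[sequences[bg_chrom]].tobytes().decode()
        for i in range(0, len(seq_bytes), 80):
            fh.write(seq_bytes[i : i + 80] + "\n")
    with open(_path("bg_upstream", "background_upstream5k.fa"), "w") as fh:
        for gid, giv, _, _ in genes:
            if giv.strand == "+":
                s, e = max(0, giv.start - 5_000), giv.start
            else:
                s, e = giv.end, min(chrom_sizes[giv.chrom], giv.end + 5_000)
            if e - s < 100:
                continue
            fh.write(f">up5k_{gid}\n")
            seq_bytes = base_arr[sequences[giv.chrom][s:e]].tobytes().decode()
            for i in range(0, len(seq_bytes), 80):
                fh.write(seq_bytes[i : i + 80] + "\n")

    write_jaspar(motif_library, _path("motifs_jaspar", "motifs.jaspar"))

    with open(_path("truth", "truth.tsv"), "w") as fh:
        fh.write(
            "# element_id\tchrom\tstart\tend\tclass\tregulation\thas_cpg\t"
            "conserved\tn_planted_motifs\n"
        )
        for el in elements:
            iv = el.interval
            fh.write(
                f"{el.element_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{el.element_class}\t{el.regulation}\t{int(el.has_cpg)}\t"
                f"{int(el.conserved)}\t{el.n_planted_motifs}\n"
            )
    with open(_path("truth_genes", "truth_genes.tsv"), "w") as fh:
        fh.write("# gene_id\tregulation\n")
        for gid, _, reg, _ in genes:
            fh.write(f"{gid}\t{reg}\n")

    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"roles": manifest, "spec": asdict(spec)}, fh, indent=1, sort_keys=True
        )
        fh.write("\n")
    manifest["manifest"] = "manifest.json"

    truth = SyntheticTruth(
        elements=elements,
        gene_regulation={gid: reg for gid, _, reg, _ in genes},
    )
    return manifest, truth


def read_truth(path: str | Path) -> list[TruthElement]:
    """Re-load the truth table written by :func:`generate_dataset`."""
    out: list[TruthElement] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            eid, chrom, start, end, cls, reg, has_cpg, conserved, n_mot = (
                line.rstrip("\n").split("\t")
            )
            out.append(
                TruthElement(
                    eid, GenomicInterval(chrom, int(start), int(end)), cls, reg,
                    bool(int(has_cpg)), bool(int(conserved)), int(n_mot),
                )
            )
    return out
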