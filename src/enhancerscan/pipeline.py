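"""End-to-end orchestration: filter -> regulation -> signatures -> cluster
-> associations -> conservation -> motifs, with config, logging and
TSV/BED reports.

Every number in the reports is recomputable by calling the underlying
module operation directly on the stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .associations import (
    assign_to_genes,
    distance_to_nearest_distribution,
    gene_class_enrichment,
    median_intra_region_cage_distance,
    overlap_fraction_with_null,
    tag_support_comparison,
)
from .conservation import conservation_profile, conservation_significance
from .genome_io import (
    GenomicInterval,
    TagTrack,
    count_tags,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_gene_table,
    read_jaspar,
    read_tag_track,
    write_bed,
)
from .motifs import (
    build_background_pool,
    enrichment_p,
    region_match_probability,
)
from .peaks import (
    PeakCluster,
    annotate_peaks,
    call_peaks,
    classify_regulation,
    cluster_and_filter,
    filter_extragenic,
)
from .signatures import (
    build_training_set,
    extract_profile,
    holdout_accuracy,
    predict_class,
    train,
)
from .synthetic import SyntheticSpec, generate_dataset, read_truth

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad pipeline configuration (unknown key, bad value)."""


class InputError(ValueError):
    """Missing or malformed pipeline input."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, parsed from a flat key=value file."""

    flank3_bp: int = 10_000
    continuity_gap_bp: int = 500
    cluster_gap_bp: int = 2_000
    window_half_bp: int = 2_500
    bin_bp: int = 100
    gene_assign_max: int = 20_000
    pu1_slop: int = 500
    fold_min: float = 2.0
    p_max: float = 1e-3
    n_random: int = 1_000
    alpha: float = 0.01
    seed: int = 1
    smooth_bp: int = 50
    peak_window_bp: int = 500
    peak_step_bp: int = 50
    peak_p: float = 1e-5
    peak_min_width: int = 200
    n_train_per_class: int = 0  # 0 = use all available (balanced)
    polii_positive_min_tags: int = 5
    motif_n_draws: int = 1_000
    motif_n_shuffles: int = 100

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value <= 0 and f.name not in ("n_train_per_class",):
                raise ConfigError(f"config key {f.name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, float | int] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = float(value) if "float" in str(known[key]) else int(value)
        config = cls(**kwargs)  # type: ignore[arg-type]
        config.validate()
        return config

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


REQUIRED_ROLES = (
    "gene_table", "chrom_sizes", "polII_ut", "polII_lps", "me1", "me3",
)


def load_manifest(data_dir: str | Path) -> dict[str, Path]:
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {data_dir}")
    with open(manifest_path) as fh:
        roles = json.load(fh)["roles"]
    paths = {role: data_dir / name for role, name in roles.items()}
    for role in REQUIRED_ROLES:
        if role not in paths or not paths[role].exists():
            raise InputError(f"missing required input role {role!r}")
    return paths


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
    simulate: SyntheticSpec | None = None,
) -> dict:
    """Run all stages; returns the summary dict (also written to disk).

    Exactly one of ``data_dir`` (a directory with manifest.json) or
    ``simulate`` (a SyntheticSpec, generating its inputs first) must be
    given.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if (data_dir is None) == (simulate is None):
        raise InputError("provide exactly one of data_dir or simulate")
    if simulate is not None:
        data_dir = out / "synthetic_inputs"
        generate_dataset(simulate, data_dir)
    paths = load_manifest(data_dir)

    summary: dict[str, object] = {}

    # ---- load inputs -----------------------------------------------------
    stage = "load_inputs"
    try:
        chrom_sizes = read_chrom_sizes(paths["chrom_sizes"])
        genes = read_gene_table(paths["gene_table"], "simple_tsv")
        track_ut = read_tag_track(paths["polII_ut"])
        track_lps = read_tag_track(paths["polII_lps"])
        me1 = read_tag_track(paths["me1"])
        me3 = read_tag_track(paths["me3"])
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

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

    # ---- peak calling and extragenic filter ------------------------------
    stage = "annotate"
    try:
        if "peaks" in paths:
            raw_peaks = read_bed(paths["peaks"])
        else:
            raw_peaks = call_peaks(
                pooled, chrom_sizes, config.peak_window_bp, config.peak_step_bp,
                config.peak_p, config.peak_min_width,
            )
        retained, rejected = filter_extragenic(
            raw_peaks, genes, pooled, config.flank3_bp, config.continuity_gap_bp,
        )
        peaks = annotate_peaks(
            retained, track_ut, track_lps, config.fold_min, config.p_max,
            config.smooth_bp,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    _write_tsv(
        out / "rejections.tsv",
        ("chrom", "start", "end", "rule"),
        [(iv.chrom, iv.start, iv.end, rule) for iv, rule in rejected],
    )
    write_bed(
        [
            dataclasses.replace(
                p.interval,
                name=p.regulation,
                score=round(-np.log10(max(p.regulation_p, 1e-300)), 3),
            )
            for p in peaks
        ],
        out / "peaks_curated.bed",
        header="curated extragenic Pol II peaks; name=regulation, score=-log10 p",
    )
    summary["n_raw_peaks"] = len(raw_peaks)
    summary["n_extragenic_peaks"] = len(peaks)
    for cls in ("constitutive", "inducible", "repressed"):
        summary[f"n_peaks_{cls}"] = sum(1 for p in peaks if p.regulation == cls)

    # ---- chromatin-signature classification ------------------------------
    stage = "classify"
    try:
        tss_positions = [
            (g.interval.chrom, g.tss) for g in genes
        ]
        if "p300" in paths:
            p300 = read_bed(paths["p300"])
        else:
            raise InputError("p300 exemplar peaks are required for training")
        n_per_class = config.n_train_per_class
        if n_per_class == 0:
            from .signatures import informative_p300_peaks

            n_per_class = min(
                len(informative_p300_peaks(p300, tss_positions, config.window_half_bp)),
                len(tss_positions),
            )
        training = build_training_set(
            p300, tss_positions, me1, me3, n_per_class, seed=config.seed,
            window_half_bp=config.window_half_bp, bin_bp=config.bin_bp,
        )
        model = train(training, seed=config.seed)
        holdout_acc, holdout_abstain = holdout_accuracy(training, seed=config.seed)
        for p in peaks:
            profile = extract_profile(
                me1, me3, p.interval.chrom, p.summit, p.peak_id or "",
                config.window_half_bp, config.bin_bp,
                chrom_size=chrom_sizes.get(p.interval.chrom),
            )
            p.signature_class = predict_class(model, profile)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    model.save_tsv(out / "classifier_model.tsv")
    write_bed(
        [
            dataclasses.replace(p.interval, name=p.signature_class)
            for p in peaks
        ],
        out / "peak_predictions.bed",
        header="signature class per extragenic Pol II peak",
    )
    summary["classifier_cv_accuracy"] = round(float(np.mean(model.cv_accuracies)), 4)
    summary["classifier_holdout_accuracy"] = round(holdout_acc, 4)
    summary["classifier_holdout_abstention"] = round(holdout_abstain, 4)

    # ---- clustering -------------------------------------------------------
    stage = "cluster"
    try:
        clusters = cluster_and_filter(peaks, genes, config.cluster_gap_bp)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
    write_bed(
        [
            dataclasses.replace(
                c.interval, name=f"{c.signature_class}|{c.regulation}"
            )
            for c in clusters
        ],
        out / "clusters.bed",
        header="Pol II clusters; name=signature_class|regulation",
    )
    summary["n_clusters"] = len(clusters)
    for cls in ("enhancer", "promoter", "unpredictable"):
        n_cls = sum(1 for c in clusters if c.signature_class == cls)
        summary[f"n_clusters_{cls}"] = n_cls
        summary[f"fraction_clusters_{cls}"] = (
            round(n_cls / len(clusters), 4) if clusters else 0.0
        )

    gene_bodies = [g.interval for g in genes]
    by_class: dict[str, list[PeakCluster]] = {}
    for c in clusters:
        by_class.setdefault(c.signature_class, []).append(c)

    # ---- associations -----------------------------------------------------
    stage = "associate"
    try:
        assoc_rows: list[tuple] = []
        if "cpg" in paths:
            cpg = read_bed(paths["cpg"])
            for cls, cls_clusters in sorted(by_class.items()):
                res = overlap_fraction_with_null(
                    [c.interval for c in cls_clusters], cpg, chrom_sizes,
                    n_random=config.n_random, seed=config.seed,
                    exclude=gene_bodies,
                )
                assoc_rows.append(
                    ("cpg", cls, res.n_query, res.n_overlapping,
                     round(res.fraction, 4), round(res.expected_fraction, 4),
                     res.empirical_p, res.direction)
                )
                summary[f"cpg_fraction_{cls}"] = round(res.fraction, 4)
                summary[f"cpg_p_{cls}"] = res.empirical_p
        if "pu1" in paths:
            pu1 = read_bed(paths["pu1"])
            for cls, cls_clusters in sorted(by_class.items()):
                res = overlap_fraction_with_null(
                    [c.interval for c in cls_clusters], pu1, chrom_sizes,
                    n_random=config.n_random, slop=config.pu1_slop,
                    seed=config.seed, exclude=gene_bodies,
                )
                assoc_rows.append(
                    ("pu1", cls, res.n_query, res.n_overlapping,
                     round(res.fraction, 4), round(res.expected_fraction, 4),
                     res.empirical_p, res.direction)
                )
                summary[f"pu1_fraction_{cls}"] = round(res.fraction, 4)
        _write_tsv(
            out / "overlap_stats.tsv",
            ("feature", "class", "n_query", "n_overlap", "fraction",
             "expected", "empirical_p", "direction"),
            assoc_rows,
        )

        # gene assignment + gene-class enrichment for enhancer clusters
        coding = [g for g in genes if g.is_protein_coding]
        enh_clusters = by_class.get("enhancer", [])
        assignments = assign_to_genes(
            [(c.cluster_id or "", c.interval) for c in enh_clusters],
            coding, config.gene_assign_max,
        )
        gene_reg: dict[str, str] = {}
        lib_ut, lib_lps = track_ut.library_size, track_lps.library_size
        polii_positive: list[str] = []
        for g in coding:
            tss_iv = GenomicInterval(
                g.interval.chrom, max(0, g.tss - 500), g.tss + 500
            )
            t_ut, t_lps = count_tags(track_ut, tss_iv), count_tags(track_lps, tss_iv)
            if t_ut + t_lps >= config.polii_positive_min_tags:
                label, _ = classify_regulation(
                    t_ut, t_lps, lib_ut, lib_lps, config.fold_min, config.p_max
                )
                gene_reg[g.gene_id] = label
                polii_positive.append(label)
        _write_tsv(
            out / "gene_assignments.tsv",
            ("cluster_id", "gene_id", "distance"),
            [(a.cluster_id, a.gene_id or ".", a.distance if a.distance is not None else ".")
             for a in assignments],
        )
        enr_rows: list[tuple] = []
        for enh_reg in ("inducible", "repressed"):
            labels = [
                gene_reg[a.gene_id]
                for a, c in zip(assignments, enh_clusters)
                if a.gene_id is not None and a.gene_id in gene_reg
                and c.regulation == enh_reg
            ]
            if labels and polii_positive:
                enr = gene_class_enrichment(labels, polii_positive)
                for cls in enr.classes:
                    enr_rows.append(
                        (enh_reg, cls, round(enr.observed_fraction[cls], 4),
                         round(enr.expected_fraction[cls], 4),
                         enr.p_value[cls], enr.p_bh[cls], enr.direction[cls])
                    )
                if enh_reg == "inducible":
                    summary["inducible_enh_inducible_gene_p"] = (
                        enr.p_value.get("inducible")
                    )
                    summary["inducible_enh_inducible_gene_direction"] = (
                        enr.direction.get("inducible")
                    )
        _write_tsv(
            out / "gene_class_enrichment.tsv",
            ("enhancer_group", "gene_class", "observed", "expected", "p",
             "p_bh", "direction"),
            enr_rows,
        )

        # Ser5 distances, CAGE spacing, RNA-seq support
        if "ser5" in paths:
            ser5_track = read_tag_track(paths["ser5"])
            ser5_peaks = call_peaks(
                ser5_track, chrom_sizes, config.peak_window_bp,
                config.peak_step_bp, config.peak_p, config.peak_min_width,
            )
            if enh_clusters and ser5_peaks:
                dist = distance_to_nearest_distribution(
                    [c.interval for c in enh_clusters], ser5_peaks
                )
                summary["ser5_median_distance_enhancer"] = dist.median
                summary["n_ser5_peaks"] = len(ser5_peaks)
        if "cage" in paths:
            cage = read_bed(paths["cage"])
            cage_rows = []
            for cls in ("enhancer", "promoter"):
                values = []
                for c in by_class.get(cls, []):
                    v = median_intra_region_cage_distance(c.interval, cage)
                    cage_rows.append((c.cluster_id, cls, v))
                    if isinstance(v, float):
                        values.append(v)
                if values:
                    summary[f"cage_median_spacing_{cls}"] = float(np.median(values))
            _write_tsv(
                out / "cage_spacing.tsv",
                ("cluster_id", "class", "median_intra_distance"), cage_rows,
            )
        if "rnaseq" in paths:
            rnaseq = read_tag_track(paths["rnaseq"])
            all_intervals = [c.interval for c in clusters]
            if all_intervals:
                support = tag_support_comparison(all_intervals, rnaseq, track_ut)
                summary["rnaseq_supported_fraction"] = round(
                    float(np.mean(support.supported)), 4
                )
                if support.log10_ratio is not None:
                    summary["rnaseq_polII_log10_ratio"] = round(
                        support.log10_ratio, 4
                    )
                _write_tsv(
                    out / "rnaseq_support.tsv",
                    ("cluster_id", "supported", "polII_cpm"),
                    [(c.cluster_id, int(s), round(v, 4))
                     for c, s, v in zip(clusters, support.supported, support.polII_cpm)],
                )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- conservation -----------------------------------------------------
    stage = "conserve"
    try:
        if "conservation" in paths:
            cons = read_bedgraph(paths["conservation"], chrom_sizes)
            cons_rows = []
            for cls, cls_clusters in sorted(by_class.items()):
                if not cls_clusters:
                    continue
                summits = [(c.interval.chrom, c.summit) for c in cls_clusters]
                profile = conservation_profile(
                    cons, summits, config.window_half_bp, group=cls
                )
                center = config.window_half_bp
                sig = conservation_significance(
                    [c.interval for c in cls_clusters], cons, chrom_sizes,
                    n_random=config.n_random, seed=config.seed,
                    alpha=config.alpha, exclude=gene_bodies,
                )
                cons_rows.append(
                    (cls, len(cls_clusters),
                     round(float(profile.mean_scores[center]), 4),
                     round(sig.observed_mean, 4),
                     round(float(np.mean(sig.null_means)), 4),
                     sig.empirical_p, int(sig.significant))
                )
                summary[f"conservation_p_{cls}"] = sig.empirical_p
                summary[f"conservation_significant_{cls}"] = int(sig.significant)
            _write_tsv(
                out / "conservation_significance.tsv",
                ("class", "n_regions", "mean_at_summit", "observed_mean",
                 "null_mean", "empirical_p", "significant"),
                cons_rows,
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- motif enrichment -------------------------------------------------
    stage = "motifs"
    try:
        if "motifs_jaspar" in paths and "genome_fasta" in paths:
            pwms = read_jaspar(paths["motifs_jaspar"])
            genome = read_fasta(paths["genome_fasta"])
            backgrounds: dict[str, list[str]] = {}
            if "bg_upstream" in paths:
                backgrounds["upstream5k"] = list(
                    read_fasta(paths["bg_upstream"]).values()
                )
            if "bg_chromosome" in paths:
                backgrounds["chromosome"] = list(
                    read_fasta(paths["bg_chromosome"]).values()
                )
            groups: dict[str, list[str]] = {}
            group_clusters: dict[str, list[PeakCluster]] = {}
            for c in clusters:
                if c.signature_class not in ("enhancer", "promoter"):
                    continue
                key = f"{c.regulation}_{c.signature_class}"
                seq = genome.get(c.interval.chrom, "")[
                    c.interval.start : c.interval.end
                ]
                if seq:
                    groups.setdefault(key, []).append(seq)
                    group_clusters.setdefault(key, []).append(c)
            motif_rows: list[tuple] = []
            for pwm in pwms:
                pools = {
                    bg_name: build_background_pool(pwm, seqs)
                    for bg_name, seqs in backgrounds.items()
                }
                for key, seqs in sorted(groups.items()):
                    for bg_name, pool in sorted(pools.items()):
                        res = enrichment_p(
                            pwm, seqs, n_draws=config.motif_n_draws,
                            seed=config.seed, group=key, pool=pool,
                        )
                        motif_rows.append(
                            (pwm.motif_id, key, bg_name,
                             round(res.raw_score, 6), res.p_value)
                        )
                        if key == "inducible_enhancer" and bg_name == next(
                            iter(sorted(pools))
                        ):
                            summary.setdefault(
                                "motif_p_inducible_enhancer", {}
                            )[pwm.motif_id] = res.p_value  # type: ignore[union-attr]
            _write_tsv(
                out / "motif_enrichment.tsv",
                ("motif_id", "group", "background", "raw_score", "p"),
                motif_rows,
            )
            # per-region match probabilities (heat-table analog) for the
            # inducible enhancer group
            heat_rows: list[tuple] = []
            for c in group_clusters.get("inducible_enhancer", []):
                seq = genome[c.interval.chrom][c.interval.start : c.interval.end]
                probs = [
                    region_match_probability(
                        pwm, seq, config.motif_n_shuffles, seed=config.seed
                    )
                    for pwm in pwms
                ]
                heat_rows.append((c.cluster_id, *[round(p, 4) for p in probs]))
            _write_tsv(
                out / "motif_region_probabilities.tsv",
                ("cluster_id", *[p.motif_id for p in pwms]),
                heat_rows,
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- truth-based recovery (synthetic runs) ---------------------------
    if "truth" in paths:
        truth = read_truth(paths["truth"])
        recovery = evaluate_recovery(clusters, truth)
        summary.update(recovery)

    summary["runtime_s"] = round(time.time() - t0, 2)
    summary["seed"] = config.seed

    with open(out / "summary.tsv", "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": config.to_dict(),
                "inputs": {k: str(v) for k, v in paths.items()},
                "summary": {k: v for k, v in summary.items()},
            },
            fh, indent=1, sort_keys=True, default=str,
        )
        fh.write("\n")
    return summary


def evaluate_recovery(
    clusters: Sequence[PeakCluster], truth: Sequence
) -> dict[str, float]:
    """Match clusters to planted elements and score class/regulation calls.

    Each truth element is matched to the cluster overlapping it (if any);
    recovery rates are computed over matched elements, with abstentions
    ("unpredictable") excluded from the class-accuracy denominator but
    reported as their own rate.
    """
    matched = 0
    class_correct = 0
    class_called = 0
    unpredictable = 0
    reg_correct = 0
    reg_total = 0
    for el in truth:
        hit = None
        for c in clusters:
            if c.interval.overlaps(el.interval):
                hit = c
                break
        if hit is None:
            continue
        matched += 1
        if hit.signature_class == "unpredictable":
            unpredictable += 1
        else:
            class_called += 1
            if hit.signature_class == el.element_class:
                class_correct += 1
        if hit.regulation is not None:
            reg_total += 1
            if hit.regulation == el.regulation:
                reg_correct += 1
    out: dict[str, float] = {
        "truth_n_elements": float(len(truth)),
        "truth_n_matched": float(matched),
    }
    if matched:
        out["truth_class_accuracy"] = round(
            class_correct / class_called if class_called else 0.0, 4
        )
        out["truth_unpredictable_fraction"] = round(unpredictable / matched, 4)
    if reg_total:
        out["truth_regulation_accuracy"] = round(reg_correct / reg_total, 4)
    return out
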