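"""H3K4me1/H3K4me3 chromatin-signature classification of Pol II sites.

Enhancers carry broad H3K4me1 with little H3K4me3; active or poised TSSs
carry a sharp H3K4me3 peak flanked by H3K4me1.  Each Pol II summit is
summarized as two 50-bin tag profiles over a +-2.5 kb window, and a linear
max-margin classifier (SVM) trained on unambiguous p300 peaks (enhancer
exemplars) versus annotated TSSs separates the two signatures.  Decision
scores inside a calibrated rejection band are abstained on as
"unpredictable" — the third, non-predictive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .genome_io import GenomicInterval, TagTrack

ENHANCER, PROMOTER, UNPREDICTABLE = "enhancer", "promoter", "unpredictable"


@dataclass
class SignatureProfile:
    """Binned me1/me3 tag vectors in a summit-centered window.

    Counts are converted to tags-per-million of library and then rescaled
    to unit sum per mark, so the feature encodes the *shape* of the
    signature, not its amplitude; a mark with no signal stays all-zero and
    is flagged.
    """

    peak_id: str
    me1_bins: np.ndarray
    me3_bins: np.ndarray
    window_half_bp: int = 2500
    bin_bp: int = 100
    me1_zero: bool = False
    me3_zero: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        n_bins = 2 * self.window_half_bp // self.bin_bp
        self.me1_bins = np.asarray(self.me1_bins, dtype=float)
        self.me3_bins = np.asarray(self.me3_bins, dtype=float)
        for name, vec, zero in (
            ("me1", self.me1_bins, self.me1_zero),
            ("me3", self.me3_bins, self.me3_zero),
        ):
            if vec.shape != (n_bins,):
                raise ValueError(f"{name} vector must have length {n_bins}")
            if np.any(vec < 0):
                raise ValueError(f"{name} bins must be >= 0")
            total = vec.sum()
            if not (zero and total == 0) and not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} bins must sum to 1 (or be all-zero)")

    @property
    def features(self) -> np.ndarray:
        return np.concatenate([self.me1_bins, self.me3_bins])


def _bin_counts(
    track: TagTrack, chrom: str, edges: np.ndarray
) -> np.ndarray:
    pos = track.chrom_positions(chrom)
    idx = np.searchsorted(pos, edges, side="left")
    return np.diff(idx).astype(float)


def extract_profile(
    me1: TagTrack,
    me3: TagTrack,
    chrom: str,
    summit: int,
    peak_id: str = "",
    window_half_bp: int = 2500,
    bin_bp: int = 100,
    chrom_size: int | None = None,
) -> SignatureProfile:
    """Profile the two marks in [summit - half, summit + half) at bin_bp.

    Bin i covers [summit - window_half_bp + i*bin_bp, ... + bin_bp).  A
    window reaching past a chromosome edge is truncated (missing bins stay
    zero) and flagged.
    """
    if window_half_bp % bin_bp != 0:
        raise ValueError("window_half_bp must be divisible by bin_bp")
    edges = np.arange(
        summit - window_half_bp, summit + window_half_bp + bin_bp, bin_bp,
        dtype=np.int64,
    )
    truncated = edges[0] < 0 or (chrom_size is not None and edges[-1] > chrom_size)

    vectors = []
    zeros = []
    for track in (me1, me3):
        counts = _bin_counts(track, chrom, edges)
        lib = track.library_size
        cpm = counts / lib * 1e6 if lib > 0 else counts
        total = cpm.sum()
        if total > 0:
            cpm = cpm / total
            zeros.append(False)
        else:
            zeros.append(True)
        vectors.append(cpm)
    return SignatureProfile(
        peak_id=peak_id,
        me1_bins=vectors[0],
        me3_bins=vectors[1],
        window_half_bp=window_half_bp,
        bin_bp=bin_bp,
        me1_zero=zeros[0],
        me3_zero=zeros[1],
        truncated=truncated,
    )


@dataclass
class TrainingSet:
    """Balanced enhancer/promoter exemplar profiles."""

    profiles: list[SignatureProfile]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.labels):
            raise ValueError("profiles and labels must align")
        n_enh = sum(1 for l in self.labels if l == ENHANCER)
        n_pro = sum(1 for l in self.labels if l == PROMOTER)
        if n_enh != n_pro:
            raise ValueError("training classes must be balanced")
        ids = [p.peak_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak_id in training set")

    @property
    def X(self) -> np.ndarray:
        return np.vstack([p.features for p in self.profiles])

    @property
    def y(self) -> np.ndarray:
        return np.asarray([1 if l == ENHANCER else 0 for l in self.labels])


def informative_p300_peaks(
    p300_peaks: Sequence[GenomicInterval],
    tss_positions: Sequence[tuple[str, int]],
    min_tss_dist: int = 2500,
) -> list[GenomicInterval]:
    """p300 peaks >= min_tss_dist from any annotated TSS (unambiguous
    enhancer exemplars whose profile window cannot touch promoter
    chromatin)."""
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss_positions:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[union-attr]
    for chrom in list(by_chrom):
        by_chrom[chrom] = np.sort(np.asarray(by_chrom[chrom], dtype=np.int64))
    keep: list[GenomicInterval] = []
    for peak in p300_peaks:
        tss = by_chrom.get(peak.chrom)
        if tss is None or tss.size == 0:
            keep.append(peak)
            continue
        mid = peak.midpoint
        i = int(np.searchsorted(tss, mid))
        d = min(
            abs(mid - int(tss[j])) for j in (max(0, i - 1), min(i, tss.size - 1))
        )
        if d >= min_tss_dist:
            keep.append(peak)
    return keep


def build_training_set(
    p300_peaks: Sequence[GenomicInterval],
    tss_positions: Sequence[tuple[str, int]],
    me1: TagTrack,
    me3: TagTrack,
    n_per_class: int,
    seed: int = 0,
    window_half_bp: int = 2500,
    bin_bp: int = 100,
) -> TrainingSet:
    """Balanced exemplars: informative p300 peaks vs sampled TSSs."""
    informative = informative_p300_peaks(p300_peaks, tss_positions, window_half_bp)
    if len(informative) < n_per_class or len(tss_positions) < n_per_class:
        raise ValueError(
            f"insufficient candidates: {len(informative)} informative p300 peaks, "
            f"{len(tss_positions)} TSSs, need {n_per_class} per class"
        )
    rng = np.random.default_rng(seed)
    enh_idx = rng.choice(len(informative), size=n_per_class, replace=False)
    tss_idx = rng.choice(len(tss_positions), size=n_per_class, replace=False)
    profiles: list[SignatureProfile] = []
    labels: list[str] = []
    for k, i in enumerate(sorted(enh_idx)):
        peak = informative[i]
        profiles.append(
            extract_profile(
                me1, me3, peak.chrom, peak.midpoint,
                peak_id=f"p300_{k:04d}", window_half_bp=window_half_bp, bin_bp=bin_bp,
            )
        )
        labels.append(ENHANCER)
    for k, i in enumerate(sorted(tss_idx)):
        chrom, pos = tss_positions[i]
        profiles.append(
            extract_profile(
                me1, me3, chrom, pos,
                peak_id=f"tss_{k:04d}", window_half_bp=window_half_bp, bin_bp=bin_bp,
            )
        )
        labels.append(PROMOTER)
    return TrainingSet(profiles, labels)


@dataclass
class ClassifierModel:
    """Linear max-margin decision function with a rejection band.

    Scores s = w.x + b with s >= band called enhancer, s <= -band called
    promoter, and |s| < band (or both marks silent) abstained on as
    unpredictable.
    """

    weights: np.ndarray
    bias: float
    rejection_band: float
    seed: int
    cv_accuracies: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rejection_band < 0:
            raise ValueError("rejection_band must be >= 0")
        self.weights = np.asarray(self.weights, dtype=float)

    def decision_score(self, profile: SignatureProfile) -> float:
        x = profile.features
        if x.shape != self.weights.shape:
            raise ValueError(
                f"profile has {x.shape[0]} features, model expects "
                f"{self.weights.shape[0]}"
            )
        return float(self.weights @ x + self.bias)

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write(
                "# cv_accuracies=" + ",".join(f"{a:.6f}" for a in self.cv_accuracies) + "\n"
            )
            fh.write(f"bias\t{float(self.bias)!r}\n")
            fh.write(f"rejection_band\t{float(self.rejection_band)!r}\n")
            for i, w in enumerate(self.weights):
                fh.write(f"w{i}\t{float(w)!r}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "ClassifierModel":
        seed = 0
        cv: list[float] = []
        bias = 0.0
        band = 0.0
        weights: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# seed="):
                    seed = int(line.split("=", 1)[1])
                elif line.startswith("# cv_accuracies="):
                    val = line.split("=", 1)[1]
                    cv = [float(v) for v in val.split(",") if v]
                elif line.startswith("bias\t"):
                    bias = float(line.split("\t")[1])
                elif line.startswith("rejection_band\t"):
                    band = float(line.split("\t")[1])
                elif line.startswith("w"):
                    weights.append(float(line.split("\t")[1]))
        return cls(np.asarray(weights), bias, band, seed, cv)


def train(
    training: TrainingSet,
    seed: int = 0,
    band_percentile: float = 5.0,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit the linear SVM and calibrate the rejection band.

    The band is the band_percentile-th percentile of |decision score| over
    correctly classified training profiles, so the model abstains on
    signatures less cleanly separated than nearly all exemplars it got
    right.  5-fold stratified CV accuracies are recorded as metadata.
    """
    X, y = training.X, training.y
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate training set: constant features")
    for cls in (0, 1):
        if np.all(X[y == cls].std(axis=0) == 0) and len(set(map(tuple, X[y == cls]))) == 1:
            raise ValueError("degenerate training set: one class is constant")

    cv_acc: list[float] = []
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        m = SVC(kernel="linear", C=C)
        m.fit(X[train_idx], y[train_idx])
        cv_acc.append(float(np.mean(m.predict(X[test_idx]) == y[test_idx])))

    model = SVC(kernel="linear", C=C)
    model.fit(X, y)
    w = model.coef_.ravel()
    b = float(model.intercept_[0])
    scores = X @ w + b
    correct = (scores > 0) == (y == 1)
    if np.any(correct):
        band = float(np.percentile(np.abs(scores[correct]), band_percentile))
    else:
        band = 0.0
    return ClassifierModel(w, b, band, seed, cv_acc)


def predict_class(model: ClassifierModel, profile: SignatureProfile) -> str:
    """Enhancer / promoter / unpredictable call for one profile."""
    if profile.me1_zero and profile.me3_zero:
        return UNPREDICTABLE
    s = model.decision_score(profile)
    band = model.rejection_band
    if s >= band and s > 0:
        return ENHANCER
    if s <= -band and s < 0:
        return PROMOTER
    return UNPREDICTABLE


def holdout_accuracy(
    training: TrainingSet,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> tuple[float, float]:
    """Accuracy and abstention rate on a held-out split of the exemplars."""
    rng = np.random.default_rng(seed)
    n = len(training.profiles)
    order = rng.permutation(n)
    n_test = max(2, int(round(n * test_fraction)))
    test_idx = set(order[:n_test].tolist())
    # rebalance the training part: keep equal class counts
    train_profiles = [p for i, p in enumerate(training.profiles) if i not in test_idx]
    train_labels = [l for i, l in enumerate(training.labels) if i not in test_idx]
    n_enh = sum(1 for l in train_labels if l == ENHANCER)
    n_pro = len(train_labels) - n_enh
    keep = min(n_enh, n_pro)
    bal_p: list[SignatureProfile] = []
    bal_l: list[str] = []
    kept = {ENHANCER: 0, PROMOTER: 0}
    for p, l in zip(train_profiles, train_labels):
        if kept[l] < keep:
            bal_p.append(p)
            bal_l.append(l)
            kept[l] += 1
    model = train(TrainingSet(bal_p, bal_l), seed=seed)
    n_correct = 0
    n_abstain = 0
    for i in sorted(test_idx):
        pred = predict_class(model, training.profiles[i])
        if pred == UNPREDICTABLE:
            n_abstain += 1
        elif pred == training.labels[i]:
            n_correct += 1
    n_called = n_test - n_abstain
    acc = n_correct / n_called if n_called else 0.0
    return acc, n_abstain / n_test


def validate_against_tss(
    predictions: Sequence[tuple[str, int, str]],
    annotated_tss: Sequence[tuple[str, int]],
    half_window: int = 2500,
) -> dict[str, float]:
    """Per-class fraction of predicted summits within half_window of a TSS.

    ``predictions`` are (chrom, summit, predicted_class) triples.  A class
    with no predictions (or no TSS on any predicted chromosome) reports 0.
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in annotated_tss:
        by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[union-attr]
    for chrom in list(by_chrom):
        by_chrom[chrom] = np.sort(np.asarray(by_chrom[chrom], dtype=np.int64))
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for chrom, summit, cls in predictions:
        totals[cls] = totals.get(cls, 0) + 1
        tss = by_chrom.get(chrom)
        if tss is None or tss.size == 0:
            continue
        i = int(np.searchsorted(tss, summit))
        d = min(
            abs(summit - int(tss[j])) for j in (max(0, i - 1), min(i, tss.size - 1))
        )
        if d <= half_window:
            hits[cls] = hits.get(cls, 0) + 1
    return {cls: hits.get(cls, 0) / n for cls, n in totals.items()}
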