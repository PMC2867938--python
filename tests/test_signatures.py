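"""Chromatin-signature profiles and the enhancer/promoter SVM."""

import numpy as np
import pytest

from enhancerscan.genome_io import GenomicInterval, TagTrack
from enhancerscan.signatures import (
    ENHANCER,
    PROMOTER,
    UNPREDICTABLE,
    ClassifierModel,
    SignatureProfile,
    TrainingSet,
    build_training_set,
    extract_profile,
    holdout_accuracy,
    predict_class,
    train,
    validate_against_tss,
)

N_BINS = 50


def synthetic_profile(rng, kind, peak_id, mean_tags=40.0):
    """Planted signature shapes: enhancer = broad bimodal me1 with weak me3;
    promoter = sharp unimodal me3 flanked by me1.  Poisson noise per bin."""
    x = (np.arange(N_BINS) - N_BINS / 2 + 0.5) * 100  # bin centers, bp
    if kind == ENHANCER:
        me1_shape = np.exp(-0.5 * ((x - 1000) / 400) ** 2) + np.exp(
            -0.5 * ((x + 1000) / 400) ** 2
        )
        me3_shape = 0.2 * np.exp(-0.5 * (x / 800) ** 2)
    else:
        me3_shape = np.exp(-0.5 * (x / 300) ** 2)
        me1_shape = np.exp(-0.5 * ((x - 800) / 300) ** 2) + np.exp(
            -0.5 * ((x + 800) / 300) ** 2
        )
    me1 = rng.poisson(me1_shape / me1_shape.sum() * mean_tags).astype(float)
    me3 = rng.poisson(me3_shape / me3_shape.sum() * mean_tags).astype(float)
    kw = {}
    if me1.sum() > 0:
        me1 = me1 / me1.sum()
    else:
        kw["me1_zero"] = True
    if me3.sum() > 0:
        me3 = me3 / me3.sum()
    else:
        kw["me3_zero"] = True
    return SignatureProfile(peak_id, me1, me3, **kw)


def planted_training_set(rng, n_per_class=60, mean_tags=40.0):
    profiles, labels = [], []
    for i in range(n_per_class):
        profiles.append(synthetic_profile(rng, ENHANCER, f"e{i}", mean_tags))
        labels.append(ENHANCER)
    for i in range(n_per_class):
        profiles.append(synthetic_profile(rng, PROMOTER, f"p{i}", mean_tags))
        labels.append(PROMOTER)
    return TrainingSet(profiles, labels)


class TestExtractProfile:
    def test_single_central_tag(self):
        me1 = TagTrack({"chr1": np.array([5_000])})
        me3 = TagTrack()
        prof = extract_profile(me1, me3, "chr1", 5_000)
        assert prof.me1_bins[25] == 1.0
        assert prof.me1_bins.sum() == 1.0
        assert prof.me3_zero and not prof.me1_zero

    def test_no_signal_flags(self):
        prof = extract_profile(TagTrack(), TagTrack(), "chr1", 5_000)
        assert prof.me1_zero and prof.me3_zero
        assert prof.me1_bins.sum() == 0

    def test_matches_per_tag_assignment_oracle(self, rng):
        pos = np.sort(rng.integers(0, 10_000, size=1_000))
        me1 = TagTrack({"chr1": pos})
        summit = 5_000
        prof = extract_profile(me1, TagTrack(), "chr1", summit)
        counts = np.zeros(N_BINS)
        for p in pos:
            b = (p - (summit - 2_500)) // 100
            if 0 <= b < N_BINS:
                counts[b] += 1
        assert np.allclose(prof.me1_bins, counts / counts.sum(), atol=1e-12)

    def test_translation_equivariance(self, rng):
        pos = np.sort(rng.integers(2_500, 7_500, size=300))
        delta = 123_456
        p0 = extract_profile(TagTrack({"chr1": pos}), TagTrack(), "chr1", 5_000)
        p1 = extract_profile(
            TagTrack({"chr1": pos + delta}), TagTrack(), "chr1", 5_000 + delta
        )
        assert np.allclose(p0.me1_bins, p1.me1_bins)

    def test_edge_truncation_flag(self):
        me1 = TagTrack({"chr1": np.array([500])})
        prof = extract_profile(me1, TagTrack(), "chr1", 1_000, chrom_size=100_000)
        assert prof.truncated


class TestBuildTrainingSet:
    def _tracks(self, rng):
        pos = np.sort(rng.integers(0, 1_000_000, size=5_000))
        return TagTrack({"chr1": pos}), TagTrack({"chr1": pos + 7})

    def test_balanced_and_informative_filter(self, rng):
        me1, me3 = self._tracks(rng)
        p300 = [GenomicInterval("chr1", s, s + 500) for s in range(10_000, 200_000, 10_000)]
        tss = [("chr1", t) for t in range(500_000, 800_000, 20_000)]
        ts = build_training_set(p300, tss, me1, me3, n_per_class=10, seed=0)
        assert len(ts.profiles) == 20
        assert sum(1 for l in ts.labels if l == ENHANCER) == 10

    def test_p300_near_tss_excluded(self, rng):
        me1, me3 = self._tracks(rng)
        p300 = [GenomicInterval("chr1", 10_000, 10_500)]
        tss = [("chr1", 10_900), ("chr1", 500_000)]
        # the only p300 peak is < 2.5 kb from a TSS -> insufficient
        with pytest.raises(ValueError, match="insufficient"):
            build_training_set(p300, tss, me1, me3, n_per_class=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        me1, me3 = self._tracks(rng)
        p300 = [GenomicInterval("chr1", s, s + 500) for s in range(10_000, 400_000, 5_000)]
        tss = [("chr1", t) for t in range(500_000, 900_000, 5_000)]
        a = build_training_set(p300, tss, me1, me3, 20, seed=42)
        b = build_training_set(p300, tss, me1, me3, 20, seed=42)
        assert np.allclose(a.X, b.X)


class TestTrain:
    def test_separable_profiles_perfect_cv(self, rng):
        model = train(planted_training_set(rng), seed=0)
        assert np.mean(model.cv_accuracies) == 1.0
        assert model.rejection_band > 0

    def test_permuted_labels_chance_cv(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ts = planted_training_set(rng, n_per_class=30)
            labels = list(ts.labels)
            rng.shuffle(labels)
            # re-balance after shuffle: pair profiles with shuffled labels
            # while keeping class counts equal (permutation preserves them)
            ts_perm = TrainingSet(ts.profiles, labels)
            model = train(ts_perm, seed=seed)
            accs.append(np.mean(model.cv_accuracies))
        assert abs(float(np.mean(accs)) - 0.5) < 0.05

    def test_deterministic(self, rng):
        ts = planted_training_set(rng)
        m1 = train(ts, seed=3)
        m2 = train(ts, seed=3)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias and m1.rejection_band == m2.rejection_band

    def test_degenerate_training_rejected(self):
        flat = np.full(N_BINS, 1.0 / N_BINS)
        profiles = [
            SignatureProfile(f"x{i}", flat, flat) for i in range(4)
        ]
        ts = TrainingSet(profiles, [ENHANCER, ENHANCER, PROMOTER, PROMOTER])
        with pytest.raises(ValueError, match="degenerate"):
            train(ts, seed=0)


class TestPredict:
    def test_centroid_and_zero_and_boundary(self, rng):
        ts = planted_training_set(rng)
        model = train(ts, seed=0)
        enh_X = np.vstack(
            [p.features for p, l in zip(ts.profiles, ts.labels) if l == ENHANCER]
        )
        centroid = enh_X.mean(axis=0)
        me1, me3 = centroid[:N_BINS], centroid[N_BINS:]
        prof = SignatureProfile(
            "c", me1 / me1.sum(), me3 / me3.sum()
        )
        assert predict_class(model, prof) == ENHANCER
        zero = SignatureProfile(
            "z", np.zeros(N_BINS), np.zeros(N_BINS), me1_zero=True, me3_zero=True
        )
        assert predict_class(model, zero) == UNPREDICTABLE
        # exact decision boundary: score 0 falls inside the band
        flat = np.full(N_BINS, 1.0 / N_BINS)
        boundary = SignatureProfile("b", flat, flat)
        s = model.decision_score(boundary)
        if abs(s) < model.rejection_band:
            assert predict_class(model, boundary) == UNPREDICTABLE

    def test_library_size_invariance(self, rng):
        """Doubling every tag count changes no prediction (unit-sum)."""
        pos1 = np.sort(rng.integers(0, 10_000, size=400))
        pos3 = np.sort(rng.integers(0, 10_000, size=400))
        ts = planted_training_set(rng)
        model = train(ts, seed=0)
        p_single = extract_profile(
            TagTrack({"chr1": pos1}), TagTrack({"chr1": pos3}), "chr1", 5_000
        )
        p_double = extract_profile(
            TagTrack({"chr1": np.sort(np.r_[pos1, pos1])}),
            TagTrack({"chr1": np.sort(np.r_[pos3, pos3])}),
            "chr1", 5_000,
        )
        assert np.allclose(p_single.features, p_double.features)
        assert predict_class(model, p_single) == predict_class(model, p_double)

    def test_dimension_mismatch(self, rng):
        model = train(planted_training_set(rng), seed=0)
        small = SignatureProfile(
            "s", np.full(10, 0.1), np.full(10, 0.1), window_half_bp=500
        )
        with pytest.raises(ValueError, match="features"):
            model.decision_score(small)


class TestHeldOutRecovery:
    def test_planted_signatures_recovered(self):
        """500 + 500 planted profiles at mean 40 tags: >= 95 % held-out
        accuracy with <= 10 % abstention."""
        rng = np.random.default_rng(11)
        ts = planted_training_set(rng, n_per_class=500, mean_tags=40.0)
        acc, abstain = holdout_accuracy(ts, seed=1)
        assert acc >= 0.95
        assert abstain <= 0.10


class TestModelSerialization:
    def test_tsv_round_trip(self, tmp_path, rng):
        model = train(planted_training_set(rng), seed=5)
        path = tmp_path / "model.tsv"
        model.save_tsv(path)
        back = ClassifierModel.load_tsv(path)
        assert np.array_equal(back.weights, model.weights)
        assert back.bias == model.bias
        assert back.rejection_band == model.rejection_band
        assert back.cv_accuracies == pytest.approx(model.cv_accuracies, abs=1e-6)


class TestValidateAgainstTss:
    def test_fractions(self):
        preds = [
            ("chr1", 1_000, PROMOTER),
            ("chr1", 50_000, PROMOTER),
            ("chr1", 200_000, ENHANCER),
        ]
        tss = [("chr1", 1_200), ("chr1", 49_000)]
        frac = validate_against_tss(preds, tss, half_window=2_500)
        assert frac[PROMOTER] == 1.0
        assert frac[ENHANCER] == 0.0

    def test_no_tss_on_chromosome(self):
        frac = validate_against_tss([("chr5", 100, PROMOTER)], [("chr1", 1)])
        assert frac[PROMOTER] == 0.0
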