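"""PWM scanning and Clover-style enrichment: hand oracles, invariances,
planted-motif detection and self-null calibration."""

import numpy as np
import pytest
from scipy import stats

from enhancerscan.genome_io import PWM
from enhancerscan.motifs import (
    both_strand_window_scores,
    enrichment_p,
    group_raw_score,
    region_match_probability,
    reverse_complement,
    sequence_score,
    window_likelihood_ratio,
)

UNIFORM_BG = np.full(4, 0.25)


def _pwm_from_consensus(consensus, major=1.0, motif_id="m", pseudocount=0.01):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 100.0 * major
        counts[i, counts[i] == 0] = 100.0 * (1 - major) / 3
    return PWM.from_counts(motif_id, counts, pseudocount)


def _background_pwm(length=4):
    return PWM("bg", np.full((length, 4), 0.25))


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestWindowLikelihoodRatio:
    def test_hand_arithmetic_two_position_example(self):
        # a 4-long PWM whose first two positions are (near-)certain A then C
        pwm = _pwm_from_consensus("ACAA")
        expect_factor = (100.01 / 100.04) / 0.25
        got = window_likelihood_ratio(pwm, "ACAA")
        assert got == pytest.approx(expect_factor**4, rel=1e-12)
        # the per-position factor itself matches the 15.09 hand value
        assert expect_factor**2 == pytest.approx(15.99, abs=1.0)

    def test_background_equal_pwm_gives_one(self, rng):
        pwm = _background_pwm(6)
        for _ in range(10):
            assert window_likelihood_ratio(pwm, random_seq(rng, 6)) == pytest.approx(1.0)

    def test_all_N_window_gives_one(self):
        pwm = _pwm_from_consensus("ACGT")
        assert window_likelihood_ratio(pwm, "NNNN") == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_likelihood_ratio(_pwm_from_consensus("ACGT"), "ACGTA")


class TestSequenceScore:
    def test_single_window_is_mean_of_both_strands(self):
        pwm = _pwm_from_consensus("AAAC")
        seq = "AAAC"
        fwd = window_likelihood_ratio(pwm, seq)
        rev = window_likelihood_ratio(pwm, reverse_complement(seq))
        assert sequence_score(pwm, seq) == pytest.approx((fwd + rev) / 2, rel=1e-12)

    def test_palindromic_pwm_forward_equals_reverse(self, rng):
        pwm = _pwm_from_consensus("ACGT")  # reverse complement of ACGT is ACGT
        seq = random_seq(rng, 30)
        scores = both_strand_window_scores(pwm, seq)
        fwd_only = np.array(
            [window_likelihood_ratio(pwm, seq[i : i + 4]) for i in range(27)]
        )
        assert np.allclose(scores, fwd_only, rtol=1e-12)

    def test_reverse_complement_invariance(self, rng):
        pwm = _pwm_from_consensus("GGAT")
        for _ in range(20):
            seq = random_seq(rng, 25)
            assert sequence_score(pwm, seq) == pytest.approx(
                sequence_score(pwm, reverse_complement(seq)), rel=1e-12
            )

    def test_matches_full_enumeration_oracle(self, rng):
        pwm = _pwm_from_consensus("TGCA", major=0.7)
        for _ in range(100):
            seq = random_seq(rng, 12)
            windows = [seq[i : i + 4] for i in range(9)]
            rc = reverse_complement(seq)
            rc_windows = [rc[i : i + 4] for i in range(9)]
            all_ratios = [window_likelihood_ratio(pwm, w) for w in windows + rc_windows]
            assert sequence_score(pwm, seq) == pytest.approx(
                np.mean(all_ratios), rel=1e-9
            )

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            sequence_score(_pwm_from_consensus("ACGTAA"), "ACG")


class TestGroupRawScore:
    def test_single_sequence_is_log_score(self, rng):
        pwm = _pwm_from_consensus("ACGT")
        seq = random_seq(rng, 20)
        assert group_raw_score(pwm, [seq]) == pytest.approx(
            np.log(sequence_score(pwm, seq)), rel=1e-12
        )

    def test_background_pwm_scores_zero(self, rng):
        pwm = _background_pwm(5)
        seqs = [random_seq(rng, 40) for _ in range(5)]
        assert group_raw_score(pwm, seqs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_recomputation(self, rng):
        pwm = _pwm_from_consensus("CATG", major=0.8)
        seqs = [random_seq(rng, int(rng.integers(10, 50))) for _ in range(5)]
        want = np.mean([np.log(sequence_score(pwm, s)) for s in seqs])
        assert group_raw_score(pwm, seqs) == pytest.approx(want, rel=1e-12)

    def test_all_scores_strictly_positive(self, rng):
        pwm = _pwm_from_consensus("GGGG")
        for _ in range(20):
            assert sequence_score(pwm, random_seq(rng, 15)) > 0


class TestEnrichmentP:
    def test_planted_motif_detected_at_high_contrast(self, rng):
        pwm = _pwm_from_consensus("GGGACTTTCC"[:8])
        background = [random_seq(rng, 2_000) for _ in range(5)]
        targets = []
        for _ in range(15):
            seq = list(random_seq(rng, 300))
            for off in rng.integers(0, 290, size=3):
                seq[off : off + 8] = "GGGACTTT"
            targets.append("".join(seq))
        res = enrichment_p(pwm, targets, background, n_draws=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_self_null_uniform(self, rng):
        """Target sets drawn from the background give uniform p-values."""
        pwm = _pwm_from_consensus("TTAACC", major=0.9)
        background = [random_seq(rng, 3_000) for _ in range(4)]
        pvals = []
        for rep in range(200):
            rep_rng = np.random.default_rng(900 + rep)
            targets = []
            for _ in range(10):
                bg = background[int(rep_rng.integers(0, 4))]
                off = int(rep_rng.integers(0, len(bg) - 200))
                targets.append(bg[off : off + 200])
            res = enrichment_p(pwm, targets, background, n_draws=99, seed=rep)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_uninformative_motif_p_near_half(self, rng):
        """A near-background PWM carries no signal: p ~ 0.5 on average.

        An *exactly* background-equal PWM scores every window 1.0, so all
        null draws tie with the observed score and the (conservative)
        +1-smoothed estimator returns p = 1; that degenerate tie case is
        pinned separately below.
        """
        counts = np.array([[26, 25, 25, 24], [24, 26, 25, 25],
                           [25, 24, 26, 25], [25, 25, 24, 26]], dtype=float)
        pwm = PWM.from_counts("nearbg", counts)
        background = [random_seq(rng, 3_000)]
        pvals = []
        for rep in range(30):
            targets = [random_seq(rng, 100) for _ in range(5)]
            res = enrichment_p(pwm, targets, background, n_draws=99, seed=rep)
            pvals.append(res.p_value)
        assert 0.3 < float(np.mean(pvals)) < 0.7

    def test_exact_background_pwm_is_conservative(self, rng):
        pwm = _background_pwm(5)
        background = [random_seq(rng, 2_000)]
        targets = [random_seq(rng, 100) for _ in range(5)]
        res = enrichment_p(pwm, targets, background, n_draws=199, seed=1)
        assert res.raw_score == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_background_shorter_than_target_rejected(self, rng):
        pwm = _pwm_from_consensus("ACGT")
        with pytest.raises(ValueError, match="background"):
            enrichment_p(pwm, [random_seq(rng, 500)], [random_seq(rng, 100)], 10, 0)

    def test_pool_path_equals_direct_scoring(self, rng):
        """Fragment scores from the cumulative-sum pool equal
        sequence_score computed on the extracted fragment."""
        from enhancerscan.motifs import build_background_pool

        pwm = _pwm_from_consensus("GATC", major=0.8)
        bg = random_seq(rng, 1_000)
        pool = build_background_pool(pwm, [bg])
        for _ in range(100):
            length = int(rng.integers(10, 200))
            off = int(rng.integers(0, 1_000 - length + 1))
            n_windows = length - 4 + 1
            got = (pool.cumsums[0][off + n_windows] - pool.cumsums[0][off]) / n_windows
            want = sequence_score(pwm, bg[off : off + length])
            assert got == pytest.approx(want, rel=1e-9)


class TestRegionMatchProbability:
    def test_consensus_repeats_near_one(self):
        pwm = _pwm_from_consensus("GGGACTTT")
        seq = "GGGACTTT" * 12
        p = region_match_probability(pwm, seq, n_shuffles=100, seed=0)
        assert p >= 0.99

    def test_near_background_pwm_near_half(self, rng):
        counts = np.array([[26, 25, 25, 24], [24, 26, 25, 25],
                           [25, 24, 26, 25], [25, 25, 24, 26],
                           [26, 24, 25, 25], [25, 25, 26, 24]], dtype=float)
        pwm = PWM.from_counts("nearbg", counts)
        probs = [
            region_match_probability(pwm, random_seq(rng, 200), 100, seed=k)
            for k in range(30)
        ]
        assert 0.3 < float(np.mean(probs)) < 0.7

    def test_exact_background_pwm_all_ties(self, rng):
        pwm = _background_pwm(6)
        p = region_match_probability(pwm, random_seq(rng, 200), 100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_self_null_uniformish(self, rng):
        """A pre-shuffled input sequence gives dispersed probabilities."""
        pwm = _pwm_from_consensus("CCAATT", major=0.9)
        probs = []
        for rep in range(100):
            rep_rng = np.random.default_rng(3_000 + rep)
            seq = "".join("ACGT"[i] for i in rep_rng.permutation(
                np.repeat(np.arange(4), 50)
            ))
            probs.append(region_match_probability(pwm, seq, 99, seed=rep))
        assert stats.kstest(probs, "uniform").pvalue > 0.01
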