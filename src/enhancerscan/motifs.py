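"""PWM scanning and Clover-style TFBS enrichment with randomization nulls.

The per-window statistic is the likelihood ratio of the PWM against a
background base-composition model; a sequence's score is the arithmetic
mean of that ratio over every window on both strands, and a group's raw
score is the mean log sequence score (geometric-mean aggregation).
Enrichment significance comes from re-drawing length-matched fragment
sets from a background sequence pool; per-region match probabilities come
from mononucleotide-composition-preserving shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import PWM, BASES

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to int codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _ratio_table(pwm: PWM) -> np.ndarray:
    """(L, 5) per-position probability ratios; the N column contributes 1."""
    table = np.ones((len(pwm), 5))
    table[:, :4] = pwm.matrix / pwm.background[None, :]
    return table


def window_likelihood_ratio(pwm: PWM, window: str) -> float:
    """Product over positions of P_pwm(base) / P_background(base).

    Any N (or non-ACGT base) contributes a factor of 1 at its position.
    """
    codes = encode(window)
    if codes.size != len(pwm):
        raise ValueError(
            f"window length {codes.size} != motif length {len(pwm)}"
        )
    table = _ratio_table(pwm)
    return float(np.prod(table[np.arange(len(pwm)), codes]))


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Likelihood ratios of all forward windows of an encoded sequence."""
    L = len(pwm)
    n = codes.size - L + 1
    if n <= 0:
        raise ValueError("sequence shorter than motif")
    table = _ratio_table(pwm)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return np.prod(table[np.arange(L)[None, :], windows], axis=1)


def both_strand_window_scores(pwm: PWM, sequence: str) -> np.ndarray:
    """Per-start mean of forward and reverse-complement window ratios.

    Scanning the reverse complement of the sequence equals scanning the
    forward sequence with the reverse-complemented PWM, so the result is
    aligned by window start and reverse-complement invariant.
    """
    codes = encode(sequence)
    fwd = _window_scores(pwm, codes)
    rev = _window_scores(pwm.reverse_complement(), codes)
    return (fwd + rev) / 2.0


def sequence_score(pwm: PWM, sequence: str) -> float:
    """Mean window likelihood ratio over both strands of the sequence."""
    return float(both_strand_window_scores(pwm, sequence).mean())


def group_raw_score(pwm: PWM, sequences: Sequence[str]) -> float:
    """Mean log sequence score over the group (geometric-mean aggregation).

    A PWM identical to the background scores exactly 0 on any group.
    """
    if not sequences:
        raise ValueError("group must contain at least one sequence")
    return float(np.mean([np.log(sequence_score(pwm, s)) for s in sequences]))


@dataclass
class EnrichmentResult:
    motif_id: str
    group: str
    raw_score: float
    p_value: float
    n_target: int
    n_draws: int


class _BackgroundPool:
    """Cumulative window scores over a background pool for O(1) fragments.

    For each background sequence the per-start both-strand window ratios
    are computed once; the score of any fragment [off, off + length) is
    then the mean of the window ratios whose windows lie fully inside the
    fragment, read off a cumulative sum.  This equals sequence_score of
    the fragment exactly.
    """

    def __init__(self, pwm: PWM, pool: Sequence[str]):
        self.L = len(pwm)
        self.cumsums: list[np.ndarray] = []
        self.lengths: list[int] = []
        for seq in pool:
            if len(seq) < self.L:
                continue
            scores = both_strand_window_scores(pwm, seq)
            self.cumsums.append(np.concatenate(([0.0], np.cumsum(scores))))
            self.lengths.append(len(seq))
        if not self.cumsums:
            raise ValueError("background pool has no sequence >= motif length")

    def fragment_log_score(
        self, rng: np.random.Generator, length: int
    ) -> float:
        eligible = [i for i, n in enumerate(self.lengths) if n >= length]
        if not eligible:
            raise ValueError(
                f"background shorter than target length {length}"
            )
        i = eligible[int(rng.integers(0, len(eligible)))]
        off = int(rng.integers(0, self.lengths[i] - length + 1))
        n_windows = length - self.L + 1
        cs = self.cumsums[i]
        mean_ratio = (cs[off + n_windows] - cs[off]) / n_windows
        return float(np.log(mean_ratio))


def build_background_pool(pwm: PWM, background_seqs: Sequence[str]) -> _BackgroundPool:
    """Precompute background window scores once, reusable across groups."""
    return _BackgroundPool(pwm, background_seqs)


def enrichment_p(
    pwm: PWM,
    target_seqs: Sequence[str],
    background_seqs: Sequence[str] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    group: str = "",
    pool: _BackgroundPool | None = None,
) -> EnrichmentResult:
    """Randomization p-value of the group raw score vs a background pool.

    Each null replicate draws one length-matched fragment per target
    sequence from the background pool and recomputes the group raw score;
    p = (1 + #null >= observed) / (1 + n_draws).  A precomputed ``pool``
    (see :func:`build_background_pool`) may replace ``background_seqs``.
    """
    rng = np.random.default_rng(seed)
    observed = group_raw_score(pwm, target_seqs)
    if pool is None:
        if background_seqs is None:
            raise ValueError("either background_seqs or pool is required")
        pool = _BackgroundPool(pwm, background_seqs)
    lengths = [len(s) for s in target_seqs]
    for length in lengths:
        if not any(n >= length for n in pool.lengths):
            raise ValueError(f"background shorter than target length {length}")
    exceed = 0
    for _ in range(n_draws):
        null_score = float(
            np.mean([pool.fragment_log_score(rng, length) for length in lengths])
        )
        if null_score >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_draws)
    return EnrichmentResult(
        motif_id=pwm.motif_id,
        group=group,
        raw_score=observed,
        p_value=float(p),
        n_target=len(target_seqs),
        n_draws=n_draws,
    )


def _dinucleotide_shuffle(
    rng: np.random.Generator, codes: np.ndarray
) -> np.ndarray:
    """Euler-walk shuffle preserving dinucleotide composition."""
    # build adjacency lists per code, shuffle edge order, keep last edge of
    # the original walk fixed so a closed walk exists
    n = codes.size
    if n < 3:
        return codes.copy()
    adj: dict[int, list[int]] = {}
    for a, b in zip(codes[:-1], codes[1:]):
        adj.setdefault(int(a), []).append(int(b))
    for key, targets in adj.items():
        order = rng.permutation(len(targets))
        adj[key] = [targets[i] for i in order]
    out = [int(codes[0])]
    ptr = {k: 0 for k in adj}
    cur = int(codes[0])
    for _ in range(n - 1):
        targets = adj.get(cur)
        if not targets or ptr[cur] >= len(targets):
            break
        nxt = targets[ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    if len(out) < n:  # fall back to mononucleotide shuffle on dead ends
        return rng.permutation(codes)
    return np.asarray(out, dtype=codes.dtype)


def region_match_probability(
    pwm: PWM,
    sequence: str,
    n_shuffles: int = 100,
    seed: int = 0,
    dinucleotide: bool = False,
) -> float:
    """Probability that the PWM matches the region better than chance.

    The observed sequence score is compared with scores of
    composition-preserving shuffles of the same sequence
    (mononucleotide by default); the probability is
    (1 + #shuffles below observed) / (1 + n_shuffles).
    """
    rng = np.random.default_rng(seed)
    codes = encode(sequence)
    observed = sequence_score(pwm, sequence)
    table = _ratio_table(pwm)
    L = len(pwm)
    rc_table = _ratio_table(pwm.reverse_complement())
    below = 0
    for _ in range(n_shuffles):
        if dinucleotide:
            shuffled = _dinucleotide_shuffle(rng, codes)
        else:
            shuffled = rng.permutation(codes)
        windows = np.lib.stride_tricks.sliding_window_view(shuffled, L)
        fwd = np.prod(table[np.arange(L)[None, :], windows], axis=1)
        rev = np.prod(rc_table[np.arange(L)[None, :], windows], axis=1)
        if float(((fwd + rev) / 2.0).mean()) < observed:
            below += 1
    return (1 + below) / (1 + n_shuffles)
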