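"""Independent brute-force oracles used to check the package's fast paths.

Everything here recomputes from first principles (per-window python scoring,
exhaustive enumeration over all 4^L words, closed-form normal tails) and
never calls the implementation it is checking.
"""
from __future__ import annotations

import math

import numpy as np

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_score_table(pwm) -> list[list[float]]:
    """log2 likelihood-ratio table recomputed directly from the PWM fields."""
    table = []
    for row in pwm.probs:
        if pwm.pseudocount > 0:
            row = (np.asarray(row) + pwm.pseudocount * pwm.background) / (1 + pwm.pseudocount)
        scores = []
        for b in range(4):
            p = float(row[b])
            scores.append(math.log2(p / float(pwm.background[b])) if p > 0 else -math.inf)
        table.append(scores)
    return table


def _word_score(table, word: str) -> float:
    total = 0.0
    for i, base in enumerate(word):
        s = table[i][_IDX[base]]
        if s == -math.inf:
            return -math.inf
        total += s
    return total


def brute_force_hits(pwm, seq: str, threshold: float, eps: float = 1e-9):
    """All windows on both strands scoring >= threshold, per-window python loop.

    Returns a set of (start, strand, round(score, 6)) tuples with minus-strand
    hits in forward coordinates.
    """
    table = oracle_score_table(pwm)
    L = len(table)
    hits = set()
    for start in range(len(seq) - L + 1):
        win = seq[start : start + L].upper()
        if "N" in win:
            continue
        fwd = _word_score(table, win)
        rev = _word_score(table, revcomp(win))
        if fwd >= threshold - eps:
            hits.add((start, "+", round(fwd, 6)))
        if rev >= threshold - eps:
            hits.add((start, "-", round(rev, 6)))
    return hits


def enumerate_threshold(pwm, pvalue: float) -> float:
    """Exhaustive-null threshold: enumerate all 4^L words under the background."""
    table = np.array(oracle_score_table(pwm))
    L = table.shape[0]
    words = np.array(np.unravel_index(np.arange(4**L), (4,) * L))  # (L, 4^L)
    scores = table[np.arange(L)[:, None], words].sum(axis=0)
    probs = np.prod(np.asarray(pwm.background)[words], axis=0)
    finite = np.isfinite(scores)
    scores, probs = scores[finite], probs[finite]
    uniq, inverse = np.unique(np.round(scores, 9), return_inverse=True)
    mass = np.bincount(inverse, weights=probs)
    desc = uniq[::-1]
    tail = np.cumsum(mass[::-1])
    ok = tail <= pvalue + 1e-12
    if not ok.any():
        return float(desc[0])
    return float(desc[np.nonzero(ok)[0][-1]])


def exceedance_probability(pwm, threshold: float, eps: float = 1e-9) -> float:
    """Exact P(window score >= threshold) under the background, by enumeration."""
    table = np.array(oracle_score_table(pwm))
    L = table.shape[0]
    words = np.array(np.unravel_index(np.arange(4**L), (4,) * L))
    scores = table[np.arange(L)[:, None], words].sum(axis=0)
    probs = np.prod(np.asarray(pwm.background)[words], axis=0)
    return float(probs[scores >= threshold - eps].sum())


def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail via the complementary error function."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def random_pwm(rng: np.random.Generator, length: int, concentration: float = 0.5):
    """Dirichlet-random PWM with a random (bounded-away-from-zero) background."""
    from enhancerkit.pwm import PositionWeightMatrix

    probs = rng.dirichlet(np.full(4, concentration), size=length)
    background = rng.dirichlet(np.full(4, 5.0))
    background = np.clip(background, 0.05, None)
    background = background / background.sum()
    return PositionWeightMatrix(
        f"rand{length}", probs, background, pseudocount=float(rng.choice([0.0, 0.05, 0.2]))
    )


def random_dna(rng: np.random.Generator, length: int, n_rate: float = 0.0) -> str:
    bases = np.array(list("ACGTN"))
    p = [(1 - n_rate) / 4] * 4 + [n_rate]
    return "".join(bases[rng.choice(5, size=length, p=p)])
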