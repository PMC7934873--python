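"""Position-weight-matrix scanning with exact p-value threshold calibration.

A transcription factor binding motif is modeled as a position weight matrix
(PWM): per-position probabilities over the DNA alphabet. Windows of a sequence
are scored with the log2 likelihood ratio against an i.i.d. background model,
and a hit is any window (on either strand) scoring at or above a threshold.
The threshold is calibrated so that the probability of a background window
reaching it is at most a requested p-value; that null exceedance probability
is computed exactly by dynamic programming over the score distribution.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: merge tolerance (bits) for exact score sums in the threshold DP
EXACT_MERGE_DECIMALS = 9
#: coarse discretization bin width (bits) used when the exact DP grows too large
COARSE_BIN_WIDTH = 0.01
#: cap on the number of distinct score states kept by the exact DP
MAX_EXACT_STATES = 1_000_000
#: float slop when comparing window scores against the threshold
SCORE_EPS = 1e-9


class MotifParseError(ValueError):
    """Raised for malformed MEME motif files; message carries motif id and line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities for one motif.

    Parameters
    ----------
    motif_id:
        Identifier carried into hit records.
    probs:
        L x 4 array of base probabilities in A, C, G, T order; each row must
        sum to 1 (tolerance 1e-9 after pseudocount smoothing).
    background:
        Length-4 background base probabilities, summing to 1.
    pseudocount:
        Nonnegative smoothing weight; the scored probabilities are
        ``(probs + pseudocount * background) / (1 + pseudocount)``.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: probs must be an L x 4 array with L >= 1")
        if self.pseudocount < 0:
            raise ValueError(f"{self.motif_id}: pseudocount must be nonnegative")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")
        smoothed = self.smoothed_probs()
        if not np.allclose(smoothed.sum(axis=1), 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(smoothed.sum(axis=1) - 1.0)))
            raise ValueError(
                f"{self.motif_id}: probability row {bad} sums to "
                f"{self.probs[bad].sum():.6g}, expected 1"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def smoothed_probs(self) -> np.ndarray:
        if self.pseudocount == 0:
            return self.probs
        return (self.probs + self.pseudocount * self.background[None, :]) / (
            1.0 + self.pseudocount
        )

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


def log_odds(pwm: PositionWeightMatrix) -> np.ndarray:
    """L x 4 log2 likelihood-ratio score table (bits) for *pwm*.

    ``score[i, b] = log2(p_smoothed[i, b] / background[b])``. With
    pseudocount 0, zero probabilities give ``-inf`` scores; any window
    crossing them can never reach a finite threshold.
    """
    if np.any(pwm.background <= 0):
        raise ValueError(f"{pwm.motif_id}: background entries must be positive")
    p = pwm.smoothed_probs()
    with np.errstate(divide="ignore"):
        return np.log2(p / pwm.background[None, :])


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path) -> list[PositionWeightMatrix]:
    """Parse a MEME minimal-format motif file into a list of PWMs.

    Only the DNA alphabet (ACGT) is accepted. The file-level background
    letter frequencies are used if present, otherwise uniform. Rows whose
    probabilities do not sum to ~1 (tolerance 0.01 before renormalization)
    raise :class:`MotifParseError` naming the motif and line.
    """
    with open(path) as fh:
        lines = fh.readlines()

    background = np.full(4, 0.25)
    motifs: list[PositionWeightMatrix] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip()
            if alpha.upper() != "ACGT":
                raise MotifParseError(f"line {i + 1}: alphabet must be ACGT, got {alpha!r}")
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            try:
                freq = {tokens[j].upper(): float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
                background = np.array([freq[b] for b in BASES])
            except (IndexError, KeyError, ValueError) as exc:
                raise MotifParseError(f"line {i}: malformed background frequencies") from exc
            if not math.isclose(float(background.sum()), 1.0, abs_tol=1e-3):
                raise MotifParseError(f"line {i}: background frequencies sum to {background.sum():.4g}")
            background = background / background.sum()
            continue
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"line {i + 1}: MOTIF line without an identifier")
            motif_id = parts[1]
            i += 1
            # seek the letter-probability header
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(
                        f"motif {motif_id}, line {i + 1}: no letter-probability matrix block"
                    )
                i += 1
            if i >= n:
                raise MotifParseError(
                    f"motif {motif_id}: no letter-probability matrix block before end of file"
                )
            header = lines[i].strip()
            width = None
            for tok_key, tok_val in zip(header.split(), header.split()[1:]):
                if tok_key == "w=":
                    width = int(tok_val)
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL", "letter-")):
                    break
                fields = stripped.split()
                try:
                    row = [float(x) for x in fields]
                except ValueError as exc:
                    raise MotifParseError(
                        f"motif {motif_id}, line {i + 1}: non-numeric matrix row"
                    ) from exc
                if len(row) != 4:
                    raise MotifParseError(
                        f"motif {motif_id}, line {i + 1}: expected 4 columns, got {len(row)}"
                    )
                if not math.isclose(sum(row), 1.0, abs_tol=0.01):
                    raise MotifParseError(
                        f"motif {motif_id}, line {i + 1}: row sums to {sum(row):.4g}, expected 1"
                    )
                rows.append(row)
                i += 1
            if not rows:
                raise MotifParseError(f"motif {motif_id}, line {i}: empty matrix block")
            if width is not None and width != len(rows):
                raise MotifParseError(
                    f"motif {motif_id}: header width {width} != {len(rows)} matrix rows"
                )
            probs = np.asarray(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            motifs.append(PositionWeightMatrix(motif_id, probs, background.copy()))
            continue
        i += 1
    return motifs


def write_meme(pwms: Iterable[PositionWeightMatrix], path, background=None) -> None:
    """Write motifs in MEME minimal format (readable by :func:`read_meme`)."""
    pwms = list(pwms)
    if background is None:
        background = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, background)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Threshold calibration


def _tail_threshold(scores: np.ndarray, probs: np.ndarray, pvalue: float):
    """Smallest score s with P(score >= s) <= pvalue, else None."""
    order = np.argsort(scores)[::-1]
    tail = np.cumsum(probs[order])
    ok = tail <= pvalue + 1e-12
    if not np.any(ok):
        return None
    # last index (lowest score) whose cumulative tail still satisfies the cut
    idx = np.nonzero(ok)[0][-1]
    return float(scores[order][idx])


def threshold_from_pvalue(
    score_table: np.ndarray,
    background: np.ndarray,
    pvalue: float,
    *,
    max_states: int = MAX_EXACT_STATES,
    bin_width: float = COARSE_BIN_WIDTH,
) -> float:
    """Score threshold whose null exceedance probability is <= *pvalue*.

    The null model scores i.i.d. background positions; the distribution of the
    window score is built by dynamic programming over per-position score
    distributions. Exact score sums are merged at 1e-9 bits; if the number of
    distinct states exceeds *max_states* the DP restarts on a fixed grid of
    *bin_width* bits (0.01 by default).

    Returns the smallest attainable score ``s`` with ``P(score >= s) <= pvalue``.
    If even the maximum score is more probable than *pvalue* (e.g. *pvalue*
    below 1/4^L under a uniform background), the maximum attainable score is
    returned with a warning.
    """
    score_table = np.asarray(score_table, dtype=float)
    background = np.asarray(background, dtype=float)
    if not 0 < pvalue <= 1:
        raise ValueError("pvalue must be in (0, 1]")
    if np.any(background <= 0):
        raise ValueError("background entries must be positive")

    dist: dict[float, float] = {0.0: 1.0}
    exact = True
    for i in range(score_table.shape[0]):
        new: dict[float, float] = {}
        for s, pr in dist.items():
            for b in range(4):
                sc = score_table[i, b]
                if not math.isfinite(sc):
                    continue  # -inf paths can never reach a finite threshold
                key = round(s + sc, EXACT_MERGE_DECIMALS)
                new[key] = new.get(key, 0.0) + pr * background[b]
        dist = new
        if len(dist) > max_states:
            exact = False
            break

    if not exact:
        quant = np.where(
            np.isfinite(score_table),
            np.round(score_table / bin_width).astype(np.int64),
            np.iinfo(np.int64).min,
        )
        idist: dict[int, float] = {0: 1.0}
        for i in range(score_table.shape[0]):
            inew: dict[int, float] = {}
            for s, pr in idist.items():
                for b in range(4):
                    q = quant[i, b]
                    if q == np.iinfo(np.int64).min:
                        continue
                    inew[s + q] = inew.get(s + q, 0.0) + pr * background[b]
            idist = inew
        scores = np.array(list(idist.keys()), dtype=float) * bin_width
        probs = np.array(list(idist.values()))
    else:
        scores = np.array(list(dist.keys()))
        probs = np.array(list(dist.values()))

    if scores.size == 0:
        raise ValueError("score table has no finite-score windows")
    thr = _tail_threshold(scores, probs, pvalue)
    if thr is None:
        warnings.warn(
            "requested p-value is below the attainable minimum; returning the "
            "maximum attainable score",
            stacklevel=2,
        )
        return float(scores.max())
    return thr


# ---------------------------------------------------------------------------
# Scanning


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan(
    sequences: Mapping[str, str] | str,
    score_table: np.ndarray,
    threshold: float,
    motif_id: str = "motif",
) -> pd.DataFrame:
    """Report every window on either strand scoring >= *threshold*.

    *sequences* maps sequence names (chromosomes) to ACGTN strings; a bare
    string is scanned under the name ``"seq"``. Windows containing N are
    skipped. Reverse-strand hits are reported in forward coordinates
    (BED-style 0-based half-open span of the matched window).
    """
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    score_table = np.asarray(score_table, dtype=float)
    L = score_table.shape[0]
    # 5th column handles N: -inf sinks any window that touches it
    ext = np.full((L, 5), -np.inf)
    ext[:, :4] = score_table
    # reverse-complement table scores the minus strand in forward coordinates
    rc = ext[::-1][:, [3, 2, 1, 0, 4]]

    records = []
    for chrom in sequences:
        seq = sequences[chrom]
        if len(seq) < L:
            continue
        codes = _encode(seq)
        W = len(seq) - L + 1
        fwd = np.zeros(W)
        rev = np.zeros(W)
        for i in range(L):
            fwd += ext[i, codes[i : i + W]]
            rev += rc[i, codes[i : i + W]]
        for strand, sc in (("+", fwd), ("-", rev)):
            hits = np.nonzero(sc >= threshold - SCORE_EPS)[0]
            for start in hits:
                records.append(
                    (chrom, int(start), int(start) + L, strand, float(sc[start]), motif_id)
                )

    df = pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "score", "motif_id"]
    )
    return df.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)


def write_hits_bed(hits: pd.DataFrame, path) -> None:
    """BED6 with the motif id in the name column and score x100, integer-rounded."""
    out = hits.copy()
    out["score100"] = np.rint(out["score"] * 100).astype(int)
    out[["chrom", "start", "end", "motif_id", "score100", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_hits_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "motif_id", "score100", "strand"],
    )
    df["score"] = df.pop("score100") / 100.0
    return df[["chrom", "start", "end", "strand", "score", "motif_id"]]
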