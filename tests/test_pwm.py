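"""PWM parsing, log-odds scoring, threshold calibration, and scanning."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enhancerkit.pwm import (
    MotifParseError,
    PositionWeightMatrix,
    log_odds,
    read_meme,
    reverse_complement,
    scan,
    threshold_from_pvalue,
    write_meme,
)
from helpers import brute_force_hits, enumerate_threshold, random_dna, random_pwm

MEME_TWO_MOTIFS = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.3 C 0.2 G 0.2 T 0.3

MOTIF uniform1
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 0
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25
 0.25 0.25 0.25 0.25

MOTIF sharp2
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
 0.97 0.01 0.01 0.01
 0.01 0.01 0.97 0.01
"""


class TestReadMeme:
    def test_two_motifs_ids_in_order(self, tmp_path):
        path = tmp_path / "motifs.meme"
        path.write_text(MEME_TWO_MOTIFS)
        pwms = read_meme(path)
        assert [p.motif_id for p in pwms] == ["uniform1", "sharp2"]
        assert np.allclose(pwms[0].probs, 0.25)
        assert np.allclose(pwms[0].background, [0.3, 0.2, 0.2, 0.3])
        assert pwms[1].length == 2

    def test_row_not_summing_to_one_names_the_row(self, tmp_path):
        bad = MEME_TWO_MOTIFS.replace("0.97 0.01 0.01 0.01", "0.70 0.05 0.03 0.02")
        path = tmp_path / "bad.meme"
        path.write_text(bad)
        with pytest.raises(MotifParseError, match="sharp2.*line.*sums to 0.8"):
            read_meme(path)

    def test_non_dna_alphabet_rejected(self, tmp_path):
        path = tmp_path / "protein.meme"
        path.write_text("MEME version 4\n\nALPHABET= ACDEFGHIKLMNPQRSTVWY\n")
        with pytest.raises(MotifParseError, match="alphabet"):
            read_meme(path)

    def test_write_read_roundtrip(self, tmp_path, rng):
        pwms = [random_pwm(rng, 5), random_pwm(rng, 3)]
        for p in pwms:
            p.background = np.full(4, 0.25)  # shared file-level background
        path = tmp_path / "rt.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        for orig, re_read in zip(pwms, back):
            assert orig.motif_id == re_read.motif_id
            np.testing.assert_allclose(orig.probs, re_read.probs, atol=1e-5)


class TestLogOdds:
    def test_certain_base_uniform_background(self):
        pwm = PositionWeightMatrix("m", [[1.0, 0.0, 0.0, 0.0]])
        scores = log_odds(pwm)
        assert scores[0, 0] == pytest.approx(2.0)
        assert np.all(np.isneginf(scores[0, 1:]))

    def test_pseudocount_removes_neg_inf(self):
        pwm = PositionWeightMatrix("m", [[1.0, 0.0, 0.0, 0.0]], pseudocount=0.1)
        assert np.all(np.isfinite(log_odds(pwm)))

    def test_background_pwm_scores_zero(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = PositionWeightMatrix("m", np.tile(bg, (3, 1)), bg)
        np.testing.assert_allclose(log_odds(pwm), 0.0, atol=1e-12)

    def test_perfect_consensus_max_window_score(self):
        probs = np.eye(4)[[0, 1, 2, 3]]
        pwm = PositionWeightMatrix("m", probs)
        assert log_odds(pwm).max(axis=1).sum() == pytest.approx(8.0)

    def test_zero_background_entry_rejected(self):
        pwm = PositionWeightMatrix("m", [[0.25] * 4])
        pwm.background = np.array([0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError, match="background"):
            log_odds(pwm)


class TestThreshold:
    def test_single_position_certain_base(self):
        pwm = PositionWeightMatrix("m", [[1.0, 0.0, 0.0, 0.0]])
        # only A scores 2 bits, with background probability 0.25
        assert threshold_from_pvalue(log_odds(pwm), pwm.background, 0.25) == pytest.approx(2.0)

    def test_pvalue_one_returns_minimum_attainable(self, rng):
        pwm = random_pwm(rng, 3)
        table = log_odds(pwm)
        thr = threshold_from_pvalue(table, pwm.background, 1.0)
        finite_min = np.sum(np.min(np.where(np.isfinite(table), table, np.inf), axis=1))
        assert thr == pytest.approx(float(finite_min), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("pvalue", [0.3, 0.05, 0.01])
    def test_matches_exhaustive_enumeration(self, seed, pvalue):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, int(rng.integers(2, 7)))
        thr = threshold_from_pvalue(log_odds(pwm), pwm.background, pvalue)
        assert thr == pytest.approx(enumerate_threshold(pwm, pvalue), abs=1e-6)

    def test_unattainable_pvalue_warns_and_returns_max(self):
        pwm = PositionWeightMatrix("m", [[0.97, 0.01, 0.01, 0.01]] * 2, pseudocount=0.0)
        table = log_odds(pwm)
        with pytest.warns(UserWarning, match="below the attainable minimum"):
            thr = threshold_from_pvalue(table, pwm.background, 1e-9)
        assert thr == pytest.approx(float(table.max(axis=1).sum()), abs=1e-6)

    def test_monotone_in_pvalue_and_nested_hits(self, rng):
        pwm = random_pwm(rng, 5)
        table = log_odds(pwm)
        seq = random_dna(rng, 2000)
        prev_thr, prev_hits = -np.inf, None
        for pvalue in (0.001, 0.01, 0.1, 0.5):
            thr = threshold_from_pvalue(table, pwm.background, pvalue)
            hits = set(map(tuple, scan(seq, table, thr)[["start", "strand"]].to_numpy()))
            if prev_hits is not None:
                assert thr <= prev_thr + 1e-9  # smaller p-value, larger threshold
                assert prev_hits <= hits  # and nested hit sets
            prev_thr, prev_hits = thr, hits


class TestScan:
    def test_single_embedded_consensus(self, rng):
        pwm = random_pwm(rng, 6)
        pwm.pseudocount = 0.05
        table = log_odds(pwm)
        max_score = float(table.max(axis=1).sum())
        seq = "A" * 100 + pwm.consensus + "A" * 50
        hits = scan(seq, table, max_score - 1e-6)
        fwd = hits[hits.strand == "+"]
        assert list(fwd.start) == [100] and list(fwd.end) == [106]

    def test_palindrome_hits_both_strands_same_span(self):
        probs = np.eye(4)[[0, 1, 2, 3]]  # consensus ACGT, its own reverse complement
        pwm = PositionWeightMatrix("pal", probs)
        table = log_odds(pwm)
        hits = scan("GGACGTGG", table, 7.9)
        assert sorted(zip(hits.start, hits.strand)) == [(2, "+"), (2, "-")]

    def test_windows_with_n_are_skipped(self, rng):
        pwm = random_pwm(rng, 4)
        pwm.pseudocount = 0.2
        table = log_odds(pwm)
        seq = "ACGTNACGT"
        hits = scan(seq, table, -1e9)  # every scorable window
        spans = set(hits.start)
        assert spans == {0, 5}  # windows 1-4 touch the N

    def test_matches_brute_force_on_short_sequences(self, rng):
        for _ in range(10):
            pwm = random_pwm(rng, int(rng.integers(1, 7)))
            seq = random_dna(rng, int(rng.integers(8, 30)), n_rate=0.05)
            thr = float(rng.normal(0, 2))
            got = {
                (int(r.start), r.strand, round(float(r.score), 6))
                for r in scan(seq, log_odds(pwm), thr).itertuples()
            }
            assert got == brute_force_hits(pwm, seq, thr)

    @given(st.text(alphabet="ACGT", min_size=6, max_size=40))
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement swaps strands and mirrors coordinates."""
        pwm = random_pwm(np.random.default_rng(7), 4)
        table = log_odds(pwm)
        fwd = scan(seq, table, 1.0)
        rev = scan(reverse_complement(seq), table, 1.0)
        L = pwm.length
        mirrored = {
            (len(seq) - r.end, {"+": "-", "-": "+"}[r.strand], round(r.score, 6))
            for r in rev.itertuples()
        }
        assert {(r.start, r.strand, round(r.score, 6)) for r in fwd.itertuples()} == mirrored
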