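"""Six-frame translation, local alignment, classification and naming."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from venomkit import annotate, synthetic
from venomkit.seqio import ESTRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AAS = "ACDEFGHIKLMNPQRSTVWY"


# ------------------------------------------------------------- ORF scanning

def _orf_oracle(seq: str, min_orf_aa: int) -> set[tuple[int, str]]:
    """Independent six-frame ORF enumeration (same candidate policy)."""
    out = set()
    rc = str(Seq(seq).reverse_complement())
    for off in range(3):
        for frame, s in ((off + 1, seq), (-(off + 1), rc)):
            sub = s[off: off + 3 * ((len(s) - off) // 3)]
            aa = str(Seq(sub).translate())
            segments = aa.split("*")
            for k, seg in enumerate(segments):
                m = seg.find("M")
                if k == 0 and seg and (m == -1 or m > 10):
                    if len(seg) >= min_orf_aa and "X" not in seg:
                        out.add((frame, seg))
                if m != -1:
                    cand = seg[m:]
                    if len(cand) >= min_orf_aa and "X" not in cand:
                        out.add((frame, cand))
    return out


class TestTranslateOrfs:
    def test_single_met_stop(self):
        orfs = annotate.translate_orfs("ATGAAATGA", min_orf_aa=1)
        assert ("MK", True, True) in {(o.protein, o.has_start, o.has_stop)
                                      for o in orfs}

    def test_strand_symmetry(self):
        fwd = "ATGAAATGA"
        rev = str(Seq(fwd).reverse_complement())
        fwd_prots = {o.protein for o in annotate.translate_orfs(fwd, 1)}
        rev_prots = {o.protein for o in annotate.translate_orfs(rev, 1)}
        assert "MK" in fwd_prots and "MK" in rev_prots

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_scanner(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        got = {(o.frame, o.protein)
               for o in annotate.translate_orfs(seq, min_orf_aa=20)}
        assert got == _orf_oracle(seq, 20)

    def test_orf_spanning_n_dropped(self):
        orfs = annotate.translate_orfs("ATG" + "AAA" * 30 + "NAA" + "TGA", 10)
        assert all("X" not in o.protein for o in orfs)


# ----------------------------------------------------------- local alignment

def _sw_oracle(a: str, b: str, open_cost=12.0, ext_cost=1.0) -> float:
    """Exhaustive affine-gap Smith-Waterman DP (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - ext_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - ext_cost)
            best = max(best, M[i][j])
    return best


class TestLocalAlign:
    def test_identical_sequences_full_identity(self):
        seq = "MKVLITGACDEFGHIKLMNPQRSTVWYAAGGHHKKLLMMNNPPQQRRSS"[:50]
        score, identity, span = annotate.local_align(seq, seq)
        assert identity == 100.0
        assert span == len(seq)

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(AAS[i] for i in rng.integers(0, 20, 25))
            b = "".join(AAS[i] for i in rng.integers(0, 20, 25))
            sa, _, _ = annotate.local_align(a, b)
            sb, _, _ = annotate.local_align(b, a)
            assert sa == sb

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_dp(self, seed):
        rng = np.random.default_rng(seed)
        la, lb = rng.integers(5, 31, 2)
        a = "".join(AAS[i] for i in rng.integers(0, 20, la))
        b = "".join(AAS[i] for i in rng.integers(0, 20, lb))
        score, _, _ = annotate.local_align(a, b)
        assert score == pytest.approx(_sw_oracle(a, b))

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            annotate.local_align("MKV", "MKV", matrix="NOSUCH62")


def test_karlin_altschul_constants_match_calibration():
    """Shipped (lambda, K) agree with a shuffled-null fit for this aligner."""
    lam, k = annotate.calibrate_karlin_altschul(np.random.default_rng(0))
    assert annotate.KA_LAMBDA == pytest.approx(lam, rel=0.5)
    assert math.log10(k) == pytest.approx(math.log10(annotate.KA_K), abs=1.5)


# ------------------------------------------------------------ classification

class TestClassifyEst:
    def test_verbatim_toxin_is_toxin_like(self, clean_bundle):
        refs = clean_bundle.references
        toxin_ref = next(r for r in refs if r.category == "toxin")
        est = ESTRecord(id="q", seq="ATG" + synthetic._rt(
            np.random.default_rng(0), toxin_ref.seq[1:]) + "TGA")
        ann = annotate.classify_est(est, refs)
        assert ann.category == "toxin_like"
        assert ann.identity_pct == 100.0

    def test_random_codons_no_match(self, clean_bundle):
        rng = np.random.default_rng(4)
        est = ESTRecord(id="rand",
                        seq="".join("ACGT"[i] for i in rng.integers(0, 4, 400)))
        ann = annotate.classify_est(est, clean_bundle.references)
        assert ann.category == "no_match"
        assert ann.best_hit_id is None

    def test_cellular_fragment_is_cellular(self, clean_bundle):
        refs = clean_bundle.references
        cell = next(r for r in refs if r.category == "cellular")
        fragment = cell.seq[10:80]
        est = ESTRecord(id="cellfrag",
                        seq=synthetic._rt(np.random.default_rng(1), fragment))
        ann = annotate.classify_est(est, refs)
        assert ann.category == "cellular"

    def test_reference_closed_monotonicity(self, clean_bundle):
        """Adding a reference can never demote a hit to no_match."""
        refs = clean_bundle.references
        toxin_ref = next(r for r in refs if r.category == "toxin")
        est = ESTRecord(id="q", seq="ATG" + synthetic._rt(
            np.random.default_rng(2), toxin_ref.seq[1:]) + "TGA")
        before = annotate.classify_est(est, refs[:14])
        after = annotate.classify_est(est, refs)
        assert before.category != "no_match"
        assert after.category != "no_match"


class TestNameToxin:
    @pytest.mark.parametrize("args,expected", [
        ((208, False, False), "HptTx-208"),
        ((1151, True, True), "HptTx-1151-P-T"),
        ((5, False, True), "HptTx-5-T"),
        ((7, True, False), "HptTx-7-P"),
    ])
    def test_suffix_rules(self, args, expected):
        assert annotate.name_toxin(*args) == expected

    def test_negative_clone_rejected(self):
        with pytest.raises(ValueError):
            annotate.name_toxin(-1)
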