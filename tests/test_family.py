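"""Family grouping by homology + framework, and identity histograms."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from venomkit import family, framework
from venomkit.seqio import ReferenceEntry

AAS = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _nw_identity_oracle(a, b, open_cost=12.0, ext_cost=1.0):
    """Independent global (Needleman-Wunsch/Gotoh) identity computation."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    # traceback pointers: 0=diag,1=up(gap in b),2=left(gap in a)
    ptr = {}
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -open_cost - (i - 1) * ext_cost
    for j in range(1, m + 1):
        Iy[0][j] = -open_cost - (j - 1) * ext_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                          Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - ext_cost)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - ext_cost)
    # recover identity by full traceback over the best ending state
    import numpy as _np
    states = {"M": M, "Ix": Ix, "Iy": Iy}
    st = max(states, key=lambda k: states[k][n][m])
    i, j = n, m
    ident = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if st == "M":
            ident += a[i - 1] == b[j - 1]
            s = BLOSUM62[a[i - 1], b[j - 1]]
            prev = {"M": M[i - 1][j - 1], "Ix": Ix[i - 1][j - 1],
                    "Iy": Iy[i - 1][j - 1]}
            st = max(prev, key=prev.get)
            i, j = i - 1, j - 1
        elif st == "Ix":
            st = "M" if Ix[i][j] == M[i - 1][j] - open_cost else "Ix"
            i -= 1
        else:
            st = "M" if Iy[i][j] == M[i][j - 1] - open_cost else "Iy"
            j -= 1
        if i == 0 and j > 0:
            st = "Iy"
        elif j == 0 and i > 0:
            st = "Ix"
    return 100.0 * ident / cols


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        m = family.pairwise_identity_matrix(["MKVCA", "MKVCA"])
        assert m[0, 1] == 100.0

    def test_single_substitution_of_forty(self):
        a = ("MKVLITGACDEFGHIKWNPQRSTVWYAAGGHHKKLLNNPP")[:40]
        b = a[:10] + "W" + a[11:]
        m = family.pairwise_identity_matrix([a, b])
        assert m[0, 1] == pytest.approx(97.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_entrywise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(AAS[i] for i in rng.integers(0, 20, rng.integers(12, 30)))
                for _ in range(5)]
        mat = family.pairwise_identity_matrix(seqs)
        for i in range(5):
            for j in range(i + 1, 5):
                # oracle identity must match when the optimum is unique;
                # co-optimal alignments can differ in gap placement, so
                # allow the small column-count wobble that causes
                assert mat[i, j] == pytest.approx(
                    _nw_identity_oracle(seqs[i], seqs[j]), abs=6.0)
        assert np.allclose(mat, mat.T)
        assert np.all(np.diag(mat) == 100.0)


def _make_frameworks(matures):
    return [framework.extract_framework(m) for m in matures]


class TestAssignFamilies:
    def test_identical_matures_same_family(self):
        matures = ["MKVCAWWCDD", "MKVCAWWCDD"]
        fas = family.assign_families(
            [("a", matures[0]), ("b", matures[1])], _make_frameworks(matures))
        assert fas[0].family_label == fas[1].family_label

    def test_planted_families_recovered(self, clean_bundle):
        """Thirteen planted scaffolds -> thirteen recovered families whose
        partition matches the generator manifest up to label permutation."""
        rows = [r for r in clean_bundle.manifest.values()
                if r.category == "toxin_like"]
        # one entry per distinct mature peptide
        seen = {}
        for r in rows:
            seen.setdefault(r.mature_seq, r.family)
        matures = list(seen)
        truth = [seen[m] for m in matures]
        fas = family.assign_families(
            [(f"t{i:03d}", m) for i, m in enumerate(matures)],
            _make_frameworks(matures))
        labels = {fa.toxin_name: fa.family_label for fa in fas}
        got = [labels[f"t{i:03d}"] for i in range(len(matures))]
        assert len(set(got)) == 13
        mapping = {}
        for g, t in zip(got, truth):
            assert mapping.setdefault(g, t) == t, "partition differs from truth"

    def test_raising_threshold_never_merges(self, clean_bundle):
        rows = [r for r in clean_bundle.manifest.values()
                if r.category == "toxin_like"]
        matures = sorted({r.mature_seq for r in rows})[:40]
        pairs = [(f"t{i}", m) for i, m in enumerate(matures)]
        fws = _make_frameworks(matures)
        ident = family.pairwise_identity_matrix(matures)
        n_low = len({fa.family_label for fa in family.assign_families(
            pairs, fws, identity_threshold_pct=35, identity_matrix=ident)})
        n_high = len({fa.family_label for fa in family.assign_families(
            pairs, fws, identity_threshold_pct=60, identity_matrix=ident)})
        assert n_high >= n_low

    def test_input_order_invariance(self):
        matures = ["MKVCAWWCDD", "MKVCAWWCDE", "FFYYHHWWPPQQNN", "AAACCCWWW"]
        names = ["w", "x", "y", "z"]
        fws = _make_frameworks(matures)
        fwd = family.assign_families(list(zip(names, matures)), fws)
        rev = family.assign_families(list(zip(names, matures))[::-1], fws[::-1])
        assert {(f.toxin_name, f.family_label) for f in fwd} \
            == {(f.toxin_name, f.family_label) for f in rev}


class TestIdentityHistogram:
    def test_identical_query_top_bin(self):
        refs = [ReferenceEntry(id="r", seq="MKVCAWWCDDEEFFGGHHKKLL",
                               category="toxin")]
        hist = family.identity_histogram([refs[0].seq], refs)
        assert hist["90-100"] == 1

    def test_empty_queries_all_zero(self):
        refs = [ReferenceEntry(id="r", seq="MKVCAWWCDDEEFFGG", category="toxin")]
        hist = family.identity_histogram([], refs)
        assert sum(hist.values()) == 0

    def test_counts_conserve_queries(self, clean_bundle):
        refs = [r for r in clean_bundle.references if r.category == "toxin"]
        queries = sorted({r.mature_seq for r in clean_bundle.manifest.values()
                          if r.category == "toxin_like"})[:25]
        hist = family.identity_histogram(queries, refs)
        assert sum(hist.values()) == len(queries)
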