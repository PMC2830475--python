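import numpy as np
import pytest

from kinsca.core import CouplingMatrix, PerturbationSpec
from kinsca.reciprocal import (
    EquivalenceTable,
    ReciprocalPair,
    check_major_matching,
    compare_across_proteins,
    find_reciprocal_pairs,
    load_equivalence,
    pairs_from_frame,
    pairs_to_frame,
    top_k_partners,
)
from kinsca.refdata import reference_pair_sets


def matrix_from_array(arr, first_residue=0):
    arr = np.asarray(arr, dtype=float)
    nums = tuple(range(first_residue, first_residue + arr.shape[0]))
    perturbations = tuple(
        PerturbationSpec(site_j=j, residue_x="A", subset_size=1,
                         n_effective_at_site=1, anchor_residue_number=n)
        for j, n in enumerate(nums)
    )
    return CouplingMatrix(ddE=arr, anchor_residue_numbers=nums, perturbations=perturbations)


def oracle_reciprocal_pairs(arr, k):
    """Exhaustive double loop over all (a, b): both in the other's top-k."""
    L = arr.shape[0]

    def ranking(j):
        entries = [(i, arr[i, j]) for i in range(L) if i != j and not np.isnan(arr[i, j])]
        entries.sort(key=lambda t: (-t[1], t[0]))
        return [i for i, _ in entries[:k]]

    tops = {j: ranking(j) for j in range(L)}
    out = set()
    for a in range(L):
        for b in range(a + 1, L):
            if b in tops[a] and a in tops[b]:
                klass = "major" if tops[a][0] == b and tops[b][0] == a else "minor"
                out.add((a, b, klass))
    return out


class TestTopK:
    def test_exhaustive_sort(self):
        arr = np.array([[0.0, 5.0, 1.0], [2.0, 0.0, 6.0], [3.0, 4.0, 0.0]])
        M = matrix_from_array(arr)
        assert top_k_partners(M, 1, k=2) == [(2, 4.0), (0, 5.0)][::-1]

    def test_all_zero_column_orders_by_residue_number(self):
        M = matrix_from_array(np.zeros((4, 4)), first_residue=100)
        assert top_k_partners(M, 101, k=3) == [(100, 0.0), (102, 0.0), (103, 0.0)]

    def test_k_validation(self):
        M = matrix_from_array(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            top_k_partners(M, 0, k=0)

    def test_undefined_column(self):
        arr = np.zeros((3, 3))
        arr[:, 1] = np.nan
        M = matrix_from_array(arr)
        with pytest.raises(ValueError, match="undefined"):
            top_k_partners(M, 1, k=2)

    def test_diagonal_excluded(self):
        arr = np.full((3, 3), 1.0)
        np.fill_diagonal(arr, 99.0)
        M = matrix_from_array(arr)
        assert all(pos != 0 for pos, _ in top_k_partners(M, 0, k=2))


class TestFindReciprocalPairs:
    def test_single_dominant_symmetric_entry(self):
        arr = np.random.default_rng(0).uniform(0, 0.1, (5, 5))
        arr[1, 3] = arr[3, 1] = 5.0
        pairs = find_reciprocal_pairs(matrix_from_array(arr), k=1)
        assert [(p.pos_a, p.pos_b, p.klass) for p in pairs] == [(1, 3, "major")]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        arr = np.random.default_rng(seed).uniform(0, 1, (20, 20))
        pairs = find_reciprocal_pairs(matrix_from_array(arr), k=10)
        got = {(p.pos_a, p.pos_b, p.klass) for p in pairs}
        assert got == oracle_reciprocal_pairs(arr, 10)

    def test_role_symmetry_within_pairs(self):
        """Each unordered pair appears once, and swapping which member is
        treated as the perturbation leaves the mutual-rank condition intact."""
        arr = np.random.default_rng(5).uniform(0, 1, (15, 15))
        pairs = find_reciprocal_pairs(matrix_from_array(arr), k=6)
        assert len({p.positions for p in pairs}) == len(pairs)
        for p in pairs:
            assert p.pos_a < p.pos_b
            assert p.ddE_ab == arr[p.pos_b, p.pos_a]
            assert p.ddE_ba == arr[p.pos_a, p.pos_b]

    def test_equivariant_under_index_permutation(self):
        """Relabelling positions permutes the reported pairs accordingly."""
        rng = np.random.default_rng(6)
        arr = rng.uniform(0, 1, (12, 12))
        perm = rng.permutation(12)
        permuted = arr[np.ix_(perm, perm)]
        base = {
            tuple(sorted((perm.tolist().index(p.pos_a), perm.tolist().index(p.pos_b))))
            for p in find_reciprocal_pairs(matrix_from_array(arr), k=5)
        }
        # positions in the permuted matrix are indices into `perm`
        got = {
            tuple(sorted((p.pos_a, p.pos_b)))
            for p in find_reciprocal_pairs(matrix_from_array(permuted), k=5)
        }
        assert got == base

    def test_deterministic(self):
        arr = np.random.default_rng(9).uniform(0, 1, (12, 12))
        p1 = find_reciprocal_pairs(matrix_from_array(arr), k=5)
        p2 = find_reciprocal_pairs(matrix_from_array(arr.copy()), k=5)
        assert p1 == p2

    def test_rank1_tie_flagged_ambiguous(self):
        arr = np.zeros((3, 3))
        # two equal strongest couplings in column 0
        arr[1, 0] = arr[2, 0] = 1.0
        arr[0, 1] = 1.0
        arr[0, 2] = 1.0
        pairs = find_reciprocal_pairs(matrix_from_array(arr), k=2)
        rank1 = [p for p in pairs if 0 in p.positions and (p.rank_ab == 1 or p.rank_ba == 1)]
        assert rank1 and all(p.ambiguous for p in rank1)

    def test_major_pairs_form_matching(self):
        for seed in range(10):
            arr = np.random.default_rng(seed).uniform(0, 1, (20, 20))
            pairs = find_reciprocal_pairs(matrix_from_array(arr), k=10)
            assert check_major_matching(pairs) == []


class TestCompareAcrossProteins:
    def test_published_kinase_pair_sets_share_four_pairs(self):
        """Pak2, PKA and Src reciprocal pairs share exactly 4 equivalence classes."""
        comps = compare_across_proteins(reference_pair_sets(), load_equivalence())
        common = [c for c in comps if c.klass == "common"]
        assert len(common) == 4
        assert sorted(c.positions["pak2"] for c in common) == [
            (294, 367),
            (373, 386),
            (413, 488),
            (427, 439),
        ]

    def test_identity_comparison_all_common(self):
        table = EquivalenceTable(
            __import__("pandas").DataFrame({"p1": [1, 2, 3, 4]})
        )
        comps = compare_across_proteins({"p1": [(1, 2), (3, 4)]}, table)
        assert all(c.klass == "common" for c in comps)

    def test_disjoint_sets_all_specific(self):
        import pandas as pd

        table = EquivalenceTable(pd.DataFrame({"p1": [1, 2, 3, 4], "p2": [11, 12, 13, 14]}))
        comps = compare_across_proteins({"p1": [(1, 2)], "p2": [(13, 14)]}, table)
        assert len(comps) == 2
        assert all(c.klass == "specific" for c in comps)

    def test_unmapped_residue_named(self):
        import pandas as pd

        table = EquivalenceTable(pd.DataFrame({"p1": [1, 2]}))
        with pytest.raises(KeyError, match="99"):
            compare_across_proteins({"p1": [(1, 99)]}, table)


def test_pair_frame_round_trip():
    pairs = [
        ReciprocalPair(3, 7, 1, 1, 2.5, 2.1, "major"),
        ReciprocalPair(4, 9, 2, 5, 1.5, 0.9, "minor", ambiguous=True),
    ]
    assert pairs_from_frame(pairs_to_frame(pairs)) == pairs
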