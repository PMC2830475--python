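"""Conservation and coupling statistics against an arbitrary-precision oracle.

The oracle recounts residues directly from the alignment strings and evaluates
every binomial PMF with mpmath at 50 significant digits, independently of the
vectorised log-gamma path under test.
"""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinsca.alignment import AA_ALPHABET, Alignment
from kinsca.background import BackgroundFrequencies
from kinsca.core import (
    binomial_log_prob,
    conservation_profile,
    delta_E,
    delta_delta_E,
    full_coupling_matrix,
    perturbation_subset,
)
from kinsca.synthetic import ConservedColumn, SyntheticSpec, generate

mpmath.mp.dps = 50


# ---------------------------------------------------------------------------
# oracle


def mp_binom_logpmf(k, n, q):
    if n == 0:
        return mpmath.mpf(0)
    q = mpmath.mpf(q)
    return (
        mpmath.log(mpmath.binomial(n, k))
        + k * mpmath.log(q)
        + (n - k) * mpmath.log(1 - q)
    )


def oracle_log_ratios(aln: Alignment, bg) -> list:
    """Per-column 20-vectors of ln P_obs − ln P_ref, recounted from strings."""
    n_cols = aln.n_columns
    counts = [
        {aa: sum(row[c] == aa for row in aln.rows) for aa in AA_ALPHABET}
        for c in range(n_cols)
    ]
    n_eff = [sum(v for v in counts[c].values()) for c in range(n_cols)]
    total = sum(n_eff)
    global_freq = {
        aa: sum(counts[c][aa] for c in range(n_cols)) / total for aa in AA_ALPHABET
    }
    out = []
    for c in range(n_cols):
        vec = []
        for a, aa in enumerate(AA_ALPHABET):
            q = float(bg.freq[a])
            ref = math.floor(n_eff[c] * global_freq[aa] + 0.5)
            vec.append(
                mp_binom_logpmf(counts[c][aa], n_eff[c], q)
                - mp_binom_logpmf(ref, n_eff[c], q)
            )
        out.append(vec)
    return out


def oracle_delta_E(aln, bg, column):
    vec = oracle_log_ratios(aln, bg)[column]
    return float(mpmath.sqrt(mpmath.fsum(v**2 for v in vec)))


def oracle_delta_delta_E(aln, bg, site_i, site_j, residue):
    keep = [r for r in range(aln.n_sequences) if aln.rows[r][site_j] == residue]
    sub = Alignment(
        ids=tuple(aln.ids[r] for r in keep),
        rows=tuple(aln.rows[r] for r in keep),
        anchor_index=0,
    )
    r_full = oracle_log_ratios(aln, bg)[site_i]
    r_sub = oracle_log_ratios(sub, bg)[site_i]
    return float(mpmath.sqrt(mpmath.fsum((a - b) ** 2 for a, b in zip(r_sub, r_full))))


# ---------------------------------------------------------------------------
# binomial_log_prob


class TestBinomialLogProb:
    def test_empty_product(self):
        assert binomial_log_prob(0, 0, 0.05) == 0.0

    def test_half(self):
        assert binomial_log_prob(1, 2, 0.5) == pytest.approx(math.log(0.5), rel=1e-12)

    def test_against_exact_arithmetic(self):
        expected = float(mp_binom_logpmf(7, 10, 0.05))
        assert binomial_log_prob(7, 10, 0.05) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "count,n,q", [(3, 2, 0.5), (-1, 2, 0.5), (1, 2, 0.0), (1, 2, 1.0), (1, 2, 1.5)]
    )
    def test_domain_errors(self, count, n, q):
        with pytest.raises(ValueError):
            binomial_log_prob(count, n, q)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(0, 600),
        frac=st.floats(0, 1),
        q=st.floats(1e-4, 1 - 1e-4),
    )
    def test_matches_mpmath_everywhere(self, n, frac, q):
        count = int(round(frac * n))
        got = binomial_log_prob(count, n, q)
        want = float(mp_binom_logpmf(count, n, q))
        assert math.isfinite(got)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# delta_E


class TestDeltaE:
    def test_zero_when_column_matches_global_composition(self, bg):
        # every column is a permutation of the same residues, so each column's
        # composition equals the alignment-wide composition exactly
        rows = ("AC", "CA", "AC", "CA")
        aln = Alignment(ids=("a", "b", "c", "d"), rows=rows)
        assert delta_E(aln, 0, bg) == pytest.approx(0.0, abs=1e-12)
        assert delta_E(aln, 1, bg) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_column_matches_oracle(self, toy_alignment, bg):
        got = delta_E(toy_alignment, 2, bg)
        assert got == pytest.approx(oracle_delta_E(toy_alignment, bg, 2), rel=1e-9)
        assert got > 0

    def test_all_gap_column_undefined(self, bg):
        aln = Alignment(ids=("a", "b"), rows=("-A", "-C"))
        with pytest.raises(ValueError, match="undefined|non-gap"):
            delta_E(aln, 0, bg)

    def test_oracle_equivalence_random_alignments(self, random_alignment_factory, bg):
        for seed in range(6):
            aln = random_alignment_factory(
                n=4 + seed, L=8, seed=seed, gap_rate=0.1 if seed % 2 else 0.0
            )
            for c in range(aln.n_columns):
                assert delta_E(aln, c, bg) == pytest.approx(
                    oracle_delta_E(aln, bg, c), rel=1e-9
                )

    def test_monotone_in_depth_for_invariant_column(self, bg):
        # duplicating every sequence sharpens the binomial: ΔE non-decreasing
        base_rows = ("WAC", "WCA", "WAA")
        values = []
        for reps in (1, 2, 4, 8):
            rows = base_rows * reps
            aln = Alignment(ids=tuple(f"s{i}" for i in range(len(rows))), rows=rows)
            values.append(delta_E(aln, 0, bg))
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestConservationProfile:
    def test_single_column_profile(self, bg):
        # with one column the alignment-wide composition IS the column's, so
        # the reference count equals the observed count and ΔE is exactly 0;
        # the percent normalisation of an all-zero profile stays 0
        aln = Alignment(ids=("a", "b"), rows=("W", "W"))
        prof = conservation_profile(aln, bg)
        assert len(prof.delta_E) == 1
        assert prof.delta_E[0] == pytest.approx(0.0, abs=1e-12)
        assert prof.normalized_percent.tolist() == [0.0]

    def test_two_column_profile_normalises_to_100(self, bg):
        aln = Alignment(ids=("a", "b", "c"), rows=("WA", "WC", "WA"))
        prof = conservation_profile(aln, bg)
        assert prof.normalized_percent.max() == pytest.approx(100.0)

    def test_planted_conserved_column_is_argmax(self, bg):
        spec = SyntheticSpec(
            n_sequences=300,
            n_columns=25,
            conserved_columns=(ConservedColumn(9, "W", 0.98),),
            seed=42,
        )
        aln, truth = generate(spec)
        prof = conservation_profile(aln, bg)
        assert int(np.argmax(prof.delta_E)) == truth["conserved_columns"][0]["column"]
        assert prof.normalized_percent.max() == pytest.approx(100.0)

    def test_numbering_carried(self, toy_alignment, bg):
        prof = conservation_profile(toy_alignment, bg, tuple(range(249, 254)))
        assert prof.at(251) == pytest.approx(prof.delta_E[2])


# ---------------------------------------------------------------------------
# perturbation and coupling


class TestPerturbationSubset:
    def test_direct_selection(self):
        rows = tuple(c + "AAAA" for c in "AAGGTT")
        aln = Alignment(ids=tuple("abcdef"), rows=rows)
        sub, spec = perturbation_subset(aln, 0, "G")
        assert sub.ids == ("c", "d")
        assert spec.subset_size == 2
        assert spec.conservation_percent == pytest.approx(100 * 2 / 6)

    def test_invariant_column_keeps_everything(self, toy_alignment):
        sub, spec = perturbation_subset(toy_alignment, 2, "W")
        assert sub.n_sequences == toy_alignment.n_sequences
        assert spec.conservation_percent == 100.0

    def test_gap_excluded_from_denominator(self):
        aln = Alignment(ids=("a", "b", "c"), rows=("TA", "-A", "TA"))
        _, spec = perturbation_subset(aln, 0, "T")
        assert spec.n_effective_at_site == 2
        assert spec.conservation_percent == 100.0

    def test_absent_residue_is_an_error(self, toy_alignment):
        with pytest.raises(ValueError, match="undefined"):
            perturbation_subset(toy_alignment, 2, "Y")


class TestDeltaDeltaE:
    def test_fully_conserved_perturbation_is_exact_zero(self, bg):
        rows = ("WACDE", "WGCDE", "WACKE", "WTCDE")
        aln = Alignment(ids=tuple("abcd"), rows=rows)
        _, spec = perturbation_subset(aln, 0, "W")
        for i in range(aln.n_columns):
            assert delta_delta_E(aln, i, spec, bg) == 0.0

    def test_matches_oracle(self, random_alignment_factory, bg):
        aln = random_alignment_factory(8, 6, seed=2)
        residue = aln.anchor_row[1]
        _, spec = perturbation_subset(aln, 1, residue)
        for i in range(aln.n_columns):
            got = delta_delta_E(aln, i, spec, bg)
            want = oracle_delta_delta_E(aln, bg, i, 1, residue)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_all_gap_in_subset_is_missing(self, bg):
        rows = ("TW", "TW", "C-", "C-")
        aln = Alignment(ids=tuple("abcd"), rows=rows)
        _, spec = perturbation_subset(aln, 0, "C")
        assert math.isnan(delta_delta_E(aln, 1, spec, bg))


class TestFullCouplingMatrix:
    def test_equals_elementwise_recomputation(self, random_alignment_factory, bg):
        aln = random_alignment_factory(9, 10, seed=8)
        M = full_coupling_matrix(aln, bg)
        for j in range(aln.n_columns):
            _, spec = perturbation_subset(aln, j, aln.anchor_row[j])
            for i in range(aln.n_columns):
                assert M.ddE[i, j] == pytest.approx(
                    delta_delta_E(aln, i, spec, bg), rel=1e-9, abs=1e-12
                )

    def test_non_negative_and_defined(self, random_alignment_factory, bg):
        aln = random_alignment_factory(10, 12, seed=9, gap_rate=0.15)
        M = full_coupling_matrix(aln, bg)
        finite = M.ddE[~np.isnan(M.ddE)]
        assert np.all(finite >= 0)
        assert M.column_defined.all()  # anchor always matches itself

    def test_requires_reduced_alignment(self, bg):
        aln = Alignment(ids=("a", "b"), rows=("A-", "AC"))
        with pytest.raises(ValueError, match="anchor-reduced"):
            full_coupling_matrix(aln, bg)

    def test_column_mean_excludes_diagonal(self, random_alignment_factory, bg):
        aln = random_alignment_factory(10, 5, seed=4)
        M = full_coupling_matrix(aln, bg)
        col = M.ddE[:, 2]
        manual = np.nanmean(np.delete(col, 2))
        assert M.column_mean(2) == pytest.approx(manual)


def test_background_validation():
    with pytest.raises(ValueError):
        BackgroundFrequencies(np.ones(19) / 19)
    with pytest.raises(ValueError):
        BackgroundFrequencies(np.concatenate([[-0.1], np.ones(19)]))
    bg = BackgroundFrequencies(np.ones(20))  # renormalised
    assert bg.freq.sum() == pytest.approx(1.0)
    assert bg["A"] == pytest.approx(0.05)
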