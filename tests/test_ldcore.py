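"""LD pair statistics, exact-test enumeration oracle, and pruning."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sprucepop.ldcore import (
    LDPair,
    LDPairSet,
    build_ld_pairs,
    ld_exact_test,
    ld_pair,
    prune_linked_snps,
)
from sprucepop.seqio import classify_sites

from conftest import make_alignment


def brute_force_fisher(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins
    and sum exact hypergeometric probabilities <= the observed one."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if 0 in (r1, r2, c1) or c1 == n:
        return 1.0
    def prob(k):
        return (
            Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))
        )
    p_obs = prob(a)
    total = sum(
        prob(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if prob(k) <= p_obs
    )
    return float(total)


class TestLdPair:
    def test_perfect_coupling(self):
        assert ld_pair((5, 0, 0, 5)) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_independence(self):
        r2, dp = ld_pair((4, 4, 4, 4))
        assert r2 == pytest.approx(0.0)
        assert dp == pytest.approx(0.0)

    def test_hand_worked_table(self):
        # D = 6/16 - 0.5*0.5 = 0.125, Dmax = 0.25
        r2, dp = ld_pair((6, 2, 2, 6))
        assert r2 == pytest.approx(0.25)
        assert dp == pytest.approx(0.5)

    def test_monomorphic_margin_rejected(self):
        with pytest.raises(ValueError):
            ld_pair((5, 5, 0, 0))

    @settings(max_examples=300, derandomize=True)
    @given(
        st.tuples(
            st.integers(1, 20), st.integers(1, 20),
            st.integers(1, 20), st.integers(1, 20),
        )
    )
    def test_relabeling_and_swap_invariance(self, counts):
        a, b, c, d = counts
        base = ld_pair((a, b, c, d))
        for image in ((c, d, a, b), (b, a, d, c), (d, c, b, a), (a, c, b, d)):
            r2, dp = ld_pair(image)
            assert r2 == pytest.approx(base[0], abs=1e-12)
            assert dp == pytest.approx(base[1], abs=1e-12)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.tuples(
            st.integers(1, 15), st.integers(1, 15),
            st.integers(1, 15), st.integers(1, 15),
        )
    )
    def test_r2_bounded_by_dprime(self, counts):
        r2, dp = ld_pair(counts)
        assert 0.0 <= r2 <= 1.0 and 0.0 <= dp <= 1.0
        assert r2 <= dp + 1e-12


class TestExactTest:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 0, 0, 5), 2 / 252),
            ((4, 4, 4, 4), 1.0),
        ],
    )
    def test_enumerated_values(self, table, expected):
        assert ld_exact_test(table) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_margin_convention(self):
        assert ld_exact_test((0, 0, 3, 5)) == 1.0

    def test_matches_brute_force_enumeration(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            ours = ld_exact_test((a, b, c, d))
            oracle = brute_force_fisher(a, b, c, d)
            assert ours == pytest.approx(oracle, abs=1e-12), (a, b, c, d)

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(8)
        for _ in range(200):
            t = tuple(int(v) for v in rng.integers(1, 12, size=4))
            sp = fisher_exact([[t[0], t[1]], [t[2], t[3]]]).pvalue
            assert ld_exact_test(t) == pytest.approx(sp, abs=1e-9)


def _pairs_alignment(k_snps, n=10, seed=0):
    """Alignment with k informative SNP columns at spaced positions."""
    rng = np.random.default_rng(seed)
    L = 20 * (k_snps + 1)
    matrix = np.full((n, L), "A", dtype="<U1")
    for j in range(k_snps):
        pos = 20 * (j + 1)
        minor = rng.choice(n, size=rng.integers(2, n - 1), replace=False)
        matrix[minor, pos - 1] = "G"
    return make_alignment(["".join(r) for r in matrix])


class TestBuildPairs:
    def test_pair_count_bookkeeping(self):
        aln = _pairs_alignment(19)
        sites = classify_sites(aln, "pairwise_available")
        ps = build_ld_pairs([aln], [sites])
        assert ps.n_pairs == math.comb(19, 2) == 171

    def test_multi_locus_pair_sum(self):
        alns = [_pairs_alignment(k, seed=k) for k in (4, 7, 10)]
        sites = [classify_sites(a, "pairwise_available") for a in alns]
        # give the loci distinct ids
        for i, a in enumerate(alns):
            a.locus_id = f"L{i}"
            sites[i].locus_id = f"L{i}"
        ps = build_ld_pairs(alns, sites)
        assert ps.n_pairs == sum(math.comb(k, 2) for k in (4, 7, 10))

    def test_pairwise_deletion_minimum(self):
        # two informative sites but only 3 jointly called individuals
        aln = make_alignment(
            ["AA", "AA", "AG", "GN", "GN", "NG", "NG"]
        )
        sites = classify_sites(aln, "pairwise_available")
        ps = build_ld_pairs([aln], [sites], informative_only=False)
        assert ps.n_pairs == 0 and ps.n_dropped == 1

    def test_no_ld_data_controls_false_positives(self):
        # independent sites: familywise error after Bonferroni stays small
        rng = np.random.default_rng(123)
        n_datasets, any_sig = 60, 0
        for ds in range(n_datasets):
            n, k = 30, 8
            matrix = np.full((n, 20 * (k + 1)), "A", dtype="<U1")
            for j in range(k):
                minor = rng.choice(n, size=rng.integers(5, 15), replace=False)
                matrix[minor, 20 * (j + 1) - 1] = "G"
            aln = make_alignment(["".join(r) for r in matrix])
            ps = build_ld_pairs([aln], [classify_sites(aln)])
            any_sig += ps.n_significant > 0
        assert any_sig / n_datasets <= 0.05


def _pair(locus, pi, pj, r2, sig, miss_i=0, miss_j=0):
    return LDPair(
        locus_id=locus, pos_i=pi, pos_j=pj, hap_counts=(5, 0, 0, 5),
        r2=r2, dprime=1.0, p_value=0.001, significant=sig,
        n_missing_i=miss_i, n_missing_j=miss_j,
    )


class TestPrune:
    def test_no_significant_pairs_identity(self):
        ps = LDPairSet(pairs=[_pair("L", 10, 20, 0.9, sig=False)])
        retained, removed = prune_linked_snps(ps)
        assert removed == [] and retained == {("L", 10), ("L", 20)}

    def test_single_offending_pair_removes_one(self):
        ps = LDPairSet(pairs=[_pair("L", 10, 20, 1.0, sig=True)])
        retained, removed = prune_linked_snps(ps)
        assert len(removed) == 1 and len(retained) == 1

    def test_chain_removes_shared_snp(self):
        # A-B and B-C offending: removing B resolves both
        ps = LDPairSet(
            pairs=[
                _pair("L", 10, 20, 0.9, sig=True, miss_i=0, miss_j=2),
                _pair("L", 20, 30, 0.9, sig=True, miss_i=2, miss_j=0),
                _pair("L", 10, 30, 0.1, sig=False),
            ]
        )
        retained, removed = prune_linked_snps(ps)
        assert removed == [("L", 20)]
        assert retained == {("L", 10), ("L", 30)}

    def test_result_has_no_offending_pairs(self):
        rng = np.random.default_rng(4)
        pairs = []
        positions = list(range(10, 110, 10))
        for pi, pj in itertools.combinations(positions, 2):
            pairs.append(
                _pair("L", pi, pj, float(rng.uniform()), bool(rng.uniform() < 0.3))
            )
        ps = LDPairSet(pairs=pairs)
        retained, _ = prune_linked_snps(ps, 0.2)
        for p in ps.pairs:
            if p.significant and p.r2 > 0.2:
                assert (
                    ("L", p.pos_i) not in retained
                    or ("L", p.pos_j) not in retained
                )
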