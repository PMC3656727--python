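"""Diversity statistics against brute-force and closed-form oracles."""

import itertools
import math

import numpy as np
import pytest

from sprucepop import popstats
from sprucepop.popstats import (
    InsufficientSampleError,
    global_fst,
    haplotype_stats,
    harmonic_number,
    nucleotide_diversity,
    pairwise_differences_total,
    summarize_locus,
    summarize_population,
    tajimas_d,
    watterson_theta,
)
from sprucepop.seqio import classify_sites
from sprucepop.simgen import SimTruth, simulate_locus

from conftest import make_alignment, make_popmap


class TestWattersonTheta:
    def test_two_sequences(self):
        assert watterson_theta(S=3, n=2, L=100) == pytest.approx(0.03)

    def test_harmonic_denominator(self):
        a1 = 1 + 1 / 2 + 1 / 3
        assert watterson_theta(S=5, n=4, L=1000) == pytest.approx(5 / (a1 * 1000))

    def test_no_segregation(self):
        assert watterson_theta(S=0, n=10, L=500) == 0.0

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            watterson_theta(S=1, n=1, L=100)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = make_alignment(["ACGT", "ACGT"])
        assert nucleotide_diversity(aln, classify_sites(aln)) == 0.0

    def test_two_sequences_three_diffs(self):
        base = "A" * 100
        other = "G" * 3 + "A" * 97
        aln = make_alignment([base, other])
        assert nucleotide_diversity(aln, classify_sites(aln)) == pytest.approx(0.03)

    def test_matches_brute_force_over_pairs(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACG"), size=40)) for _ in range(6)]
        aln = make_alignment(seqs)
        sites = classify_sites(aln)
        positions = sites.analyzed_positions - 1
        # brute force: average Hamming distance over all C(6,2) pairs
        diffs = [
            sum(a[p] != b[p] for p in positions)
            for a, b in itertools.combinations(seqs, 2)
        ]
        expected = np.mean(diffs)
        assert pairwise_differences_total(aln, sites) == pytest.approx(expected)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(7)]
        aln1 = make_alignment(seqs)
        aln2 = make_alignment(seqs[::-1])
        v1 = nucleotide_diversity(aln1, classify_sites(aln1))
        v2 = nucleotide_diversity(aln2, classify_sites(aln2))
        assert v1 == pytest.approx(v2)


class TestHaplotypeStats:
    def test_all_identical(self):
        aln = make_alignment(["ACGT"] * 5)
        H, Hd = haplotype_stats(aln, classify_sites(aln))
        assert (H, Hd) == (1, 0.0)

    def test_all_distinct(self):
        aln = make_alignment(["AAAA", "AAAG", "AAGG", "AGGG"])
        H, Hd = haplotype_stats(aln, classify_sites(aln))
        assert H == 4
        assert Hd == pytest.approx(1.0)

    def test_two_haplotypes_four_four(self):
        aln = make_alignment(["AAT"] * 4 + ["AGT"] * 4)
        H, Hd = haplotype_stats(aln, classify_sites(aln))
        assert H == 2
        assert Hd == pytest.approx((8 / 7) * 0.5)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, S = 12, 9
        a1 = harmonic_number(n - 1)
        d, _, _ = tajimas_d(S, n, pi_total=S / a1)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_sign_matches_pi_minus_watterson(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            S = int(rng.integers(1, 60))
            pi_total = float(rng.uniform(0, 2 * S))
            d, _, _ = tajimas_d(S, n, pi_total)
            expected_sign = np.sign(pi_total - S / harmonic_number(n - 1))
            assert np.sign(d) == expected_sign or d == 0

    def test_undefined_when_no_segregation(self):
        assert tajimas_d(0, 10, 0.0) == (None, None, None)

    def test_survey_scale_significance(self):
        # at n = 96, S = 62 a D of -1.81 sits just inside the 5% tail
        c = popstats.tajima_constants(96)
        sd = math.sqrt(c["e1"] * 62 + c["e2"] * 62 * 61)
        pi_total = -1.81 * sd + 62 / c["a1"]
        d, significant, p = tajimas_d(62, 96, pi_total)
        assert d == pytest.approx(-1.81)
        assert significant and p < 0.05


class TestSummarize:
    def test_matches_component_statistics(self, tiny_alignment):
        sites = classify_sites(tiny_alignment)
        row = summarize_locus(tiny_alignment, sites)
        assert row.S == sites.n_segregating
        assert row.theta_w == pytest.approx(
            watterson_theta(row.S, row.n, row.L)
        )
        assert row.pi == pytest.approx(
            nucleotide_diversity(tiny_alignment, sites)
        )

    def test_small_population_not_computed(self, tiny_alignment):
        popmap = make_popmap({"ind01": "solo", "ind02": "rest"})
        row = summarize_population(tiny_alignment, popmap, "solo")
        assert not row.computed
        assert row.tajimas_d is None

    def test_monomorphic_alignment(self):
        aln = make_alignment(["ACGT"] * 4)
        row = summarize_locus(aln)
        assert (row.S, row.theta_w, row.pi) == (0, 0.0, 0.0)
        assert row.tajimas_d is None


class TestGlobalFst:
    def test_identical_populations_estimator_signature(self):
        # two literal copies of one sample of n=4: the unbiased-within
        # estimator returns exactly -1/(n-1) on this degenerate input
        seqs = ["AACG", "AGCG", "AACT", "AGCT"]
        aln = make_alignment(seqs + seqs, ids=[f"i{k}" for k in range(8)])
        popmap = make_popmap(
            {f"i{k}": ("a" if k < 4 else "b") for k in range(8)}
        )
        res = global_fst(aln, popmap)
        assert res.fst == pytest.approx(-1 / 3, abs=1e-12)

    def test_island_model_near_panmixia_small(self):
        # strong migration with survey-sized demes: F_ST stays at the
        # few-percent level (the survey's regime)
        vals = []
        for seed in range(8):
            truth = SimTruth(
                theta_per_site=0.005, rho_per_site=0.0, locus_length_bp=2000,
                n_populations=3, migration_rate=100.0,
                samples_per_population=[8, 8, 24], seed=900 + seed,
            )
            res = simulate_locus(truth)
            f = global_fst(res.alignments[0], res.popmap)
            if f.fst is not None:
                vals.append(f.fst)
        assert np.mean(vals) < 0.05

    def test_fixed_differences_one(self):
        aln = make_alignment(
            ["AAAA"] * 3 + ["GGGG"] * 3, ids=[f"i{k}" for k in range(6)]
        )
        popmap = make_popmap(
            {f"i{k}": ("a" if k < 3 else "b") for k in range(6)}
        )
        assert global_fst(aln, popmap).fst == pytest.approx(1.0)

    def test_panmictic_pool_near_zero(self):
        truth = SimTruth(
            theta_per_site=0.01,
            rho_per_site=0.0,
            locus_length_bp=2000,
            samples_per_population=[60],
            seed=17,
        )
        aln = simulate_locus(truth).alignments[0]
        # split one panmictic sample arbitrarily into two "populations"
        popmap = make_popmap(
            {
                ind: ("a" if i < 30 else "b")
                for i, ind in enumerate(aln.individual_ids)
            }
        )
        assert abs(global_fst(aln, popmap).fst) < 0.05

    def test_migration_rate_ranking(self):
        fsts = {}
        for label, mig in (("low", 0.5), ("high", 50.0)):
            vals = []
            for seed in range(6):
                truth = SimTruth(
                    theta_per_site=0.005,
                    rho_per_site=0.0,
                    locus_length_bp=1500,
                    n_populations=2,
                    migration_rate=mig,
                    samples_per_population=[15, 15],
                    seed=100 + seed,
                )
                res = simulate_locus(truth)
                f = global_fst(res.alignments[0], res.popmap)
                if f.fst is not None:
                    vals.append(f.fst)
            fsts[label] = np.mean(vals)
        assert fsts["low"] > fsts["high"]
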