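"""Two-locus lookup tables and composite-likelihood rho estimation."""

import numpy as np
import pytest

from sprucepop import rho as rho_mod
from sprucepop.rho import (
    LookupError_,
    build_lookup,
    canonical_config,
    estimate_rho,
    log_grid,
    read_ldhat_lookup,
    write_lookup,
    _project_config,
)
from sprucepop.seqio import classify_sites
from sprucepop.simgen import SimTruth, simulate_locus

from conftest import make_alignment

SMALL_GRID = np.array([0.0, 1.0, 5.0, 20.0, 100.0])


@pytest.fixture(scope="module")
def small_table():
    return build_lookup(n=12, rho_grid=SMALL_GRID, n_sims_per_cell=400, seed=5)


class TestCanonicalConfig:
    def test_invariant_under_all_symmetries(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 10, size=4))
            base = canonical_config((a, b, c, d))
            images = [
                (c, d, a, b), (b, a, d, c), (d, c, b, a),
                (a, c, b, d), (b, d, a, c), (c, a, d, b), (d, b, c, a),
            ]
            for im in images:
                assert canonical_config(im) == base


class TestBuildLookup:
    def test_deterministic_under_seed(self):
        t1 = build_lookup(n=8, rho_grid=SMALL_GRID, n_sims_per_cell=50, seed=9)
        t2 = build_lookup(n=8, rho_grid=SMALL_GRID, n_sims_per_cell=50, seed=9)
        assert set(t1.log_likelihoods) == set(t2.log_likelihoods)
        for cfg in t1.log_likelihoods:
            assert np.array_equal(t1.log_likelihoods[cfg], t2.log_likelihoods[cfg])

    def test_likelihood_rows_normalized(self, small_table):
        # per grid point, summed probability over seen configs plus the
        # floor mass of unseen ones is 1 (up to smoothing arithmetic)
        universe = rho_mod._config_universe_size(12)
        for gi in range(len(small_table.rho_grid)):
            seen = sum(
                np.exp(row[gi]) for row in small_table.log_likelihoods.values()
            )
            unseen = (universe - len(small_table.log_likelihoods)) * np.exp(
                small_table.floor[gi]
            )
            assert seen + unseen == pytest.approx(1.0, abs=0.01)

    def test_four_gamete_configs_rarer_without_recombination(self, small_table):
        # probability mass on all-four-haplotypes configurations grows with rho
        def four_gamete_mass(gi):
            return sum(
                np.exp(row[gi])
                for cfg, row in small_table.log_likelihoods.items()
                if min(cfg) > 0
            )

        i_zero = 0
        i_high = len(small_table.rho_grid) - 1
        assert four_gamete_mass(i_zero) < four_gamete_mass(i_high)

    def test_grid_must_start_at_zero(self):
        with pytest.raises(LookupError_):
            build_lookup(n=6, rho_grid=[1.0, 2.0], n_sims_per_cell=10)


class TestLookupIO:
    def test_write_read_round_trip(self, small_table, tmp_path):
        p = tmp_path / "table.lk"
        write_lookup(small_table, p)
        back = read_ldhat_lookup(p)
        assert back.n == small_table.n
        assert np.allclose(back.rho_grid, small_table.rho_grid)
        for cfg, row in small_table.log_likelihoods.items():
            assert np.allclose(back.log_likelihoods[cfg], row, atol=1e-9)

    def test_truncated_file_reports_line(self, small_table, tmp_path):
        p = tmp_path / "table.lk"
        write_lookup(small_table, p)
        lines = p.read_text().splitlines()
        lines[4] = " ".join(lines[4].split()[:3])
        p.write_text("\n".join(lines))
        with pytest.raises(LookupError_, match=":5:"):
            read_ldhat_lookup(p)

    def test_theta_mismatch_warns_header_wins(self, small_table, tmp_path, caplog):
        import logging

        p = tmp_path / "table.lk"
        write_lookup(small_table, p)
        with caplog.at_level(logging.WARNING):
            back = read_ldhat_lookup(p, expected_theta=0.05)
        assert back.theta_per_site == small_table.theta_per_site
        assert any("theta" in r.message for r in caplog.records)

    def test_sample_size_mismatch_hard_error(self, small_table, tmp_path):
        p = tmp_path / "table.lk"
        write_lookup(small_table, p)
        with pytest.raises(LookupError_, match="does not match"):
            read_ldhat_lookup(p, expected_n=40)


class TestProjection:
    def test_identity_at_matching_n(self):
        assert _project_config((3, 4, 2, 3), 12) == (3, 4, 2, 3)

    def test_sums_to_target(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            cfg = tuple(int(v) for v in rng.integers(0, 30, size=4))
            if sum(cfg) == 0:
                continue
            target = int(rng.integers(4, 25))
            proj = _project_config(cfg, target)
            assert sum(proj) == target
            assert all(v >= 0 for v in proj)


def _simulated_estimate(table, rho_locus, seed, n=12, theta=8.0, L=1000):
    truth = SimTruth(
        theta_per_site=theta / L,
        rho_per_site=rho_locus / L,
        locus_length_bp=L,
        samples_per_population=[n],
        seed=seed,
    )
    res = simulate_locus(truth)
    sites = classify_sites(res.alignments[0], "pairwise_available")
    cand = np.linspace(0.0, 50.0, 26)
    return estimate_rho(res.alignments[0], sites, table, cand)


class TestEstimate:
    def test_insufficient_snps_flagged(self, small_table):
        aln = make_alignment(["ACGT"] * 12)
        sites = classify_sites(aln)
        est = estimate_rho(aln, sites, small_table)
        assert not est.computed and est.rho_per_kb is None

    def test_profile_invariant_to_pair_order(self, small_table):
        est = _simulated_estimate(small_table, 10.0, seed=3)
        # recomputing gives identical profile (pair enumeration is the only
        # ordering freedom and the sum is order-independent)
        est2 = _simulated_estimate(small_table, 10.0, seed=3)
        assert est.profile == est2.profile

    def test_allele_relabeling_equivariance(self, small_table):
        truth = SimTruth(
            theta_per_site=0.008, rho_per_site=0.01, locus_length_bp=1000,
            samples_per_population=[12], seed=21,
        )
        res = simulate_locus(truth)
        aln = res.alignments[0]
        sites = classify_sites(aln, "pairwise_available")
        est1 = estimate_rho(aln, sites, small_table)
        # swap the two alleles at one SNP column
        pos = int(sites.snp_positions()[0])
        col = aln.matrix[:, pos - 1].copy()
        alleles = np.unique(col[col != "N"])
        swapped = col.copy()
        swapped[col == alleles[0]] = alleles[1]
        swapped[col == alleles[1]] = alleles[0]
        aln.matrix[:, pos - 1] = swapped
        est2 = estimate_rho(aln, classify_sites(aln, "pairwise_available"), small_table)
        assert est1.profile == est2.profile

    def test_zero_recombination_estimates_near_grid_origin(self, small_table):
        cand = np.linspace(0.0, 50.0, 26)
        hits = 0
        reps = 15
        for rep in range(reps):
            est = _simulated_estimate(small_table, 0.0, seed=500 + rep)
            if est.computed and est.rho_per_kb <= cand[1]:
                hits += 1
        assert hits / reps >= 0.6

    def test_log_grid_shape(self):
        g = log_grid(10, 50.0)
        assert g[0] == 0.0 and g[-1] == pytest.approx(50.0) and len(g) == 10
        assert np.all(np.diff(g) > 0)
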