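"""Seeded Katz scoring, ranking, r-ratio calibration and top-fraction selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from katznet.prioritize import (
    ConvergenceError,
    DivergenceError,
    WeightedNetwork,
    build_activity_vector,
    build_candidate_set,
    calibrate_phi,
    default_phi_grid,
    katz_score_direct,
    katz_score_jacobi,
    r_ratio,
    rank_genes,
    select_top_fraction,
)
from katznet.synthdata import SyntheticScenario, generate_loci, generate_network

from conftest import make_random_network


def two_node_network() -> WeightedNetwork:
    return WeightedNetwork.from_edges([("a", "b", 1.0)])


class TestActivityVector:
    def test_indicator_over_network_order(self):
        net = WeightedNetwork(["g1", "g2", "g3"], sparse.csr_array((3, 3)))
        av = build_activity_vector(net, {"g2"})
        assert av.x.tolist() == [0.0, 1.0, 0.0]
        assert av.missing == () and av.n_seeds_in_network == 1

    def test_seeds_outside_network_reported_not_dropped_silently(self):
        net = WeightedNetwork(["g1", "g2"], sparse.csr_array((2, 2)))
        av = build_activity_vector(net, {"g2", "zz1", "zz2"})
        assert av.missing == ("zz1", "zz2")
        assert av.n_seeds_in_network == 1

    def test_empty_seeds_give_zero_vector(self):
        net = two_node_network()
        av = build_activity_vector(net, set())
        assert not av.x.any()


class TestSolvers:
    @pytest.mark.parametrize("solve", [katz_score_direct, katz_score_jacobi])
    def test_phi_zero_returns_activity_vector_exactly(self, solve):
        net = two_node_network()
        x = np.array([1.0, 0.0])
        assert solve(net, x, 0.0).s.tolist() == [1.0, 0.0]

    @pytest.mark.parametrize("solve", [katz_score_direct, katz_score_jacobi])
    def test_two_node_closed_form(self, solve):
        # (I - 0.5 W)^{-1} (1,0)^T = (4/3, 2/3) for a single unit edge
        net = two_node_network()
        s = solve(net, np.array([1.0, 0.0]), 0.5).s
        assert np.allclose(s, [4 / 3, 2 / 3], atol=1e-10, rtol=0)

    def test_empty_matrix_returns_x_for_any_phi(self):
        net = WeightedNetwork(["a", "b"], sparse.csr_array((2, 2)))
        s = katz_score_direct(net, np.array([0.3, 0.7]), 0.9).s
        assert s.tolist() == [0.3, 0.7]

    @pytest.mark.parametrize("seed", range(5))
    def test_jacobi_agrees_with_direct_solver(self, seed):
        rng = np.random.default_rng(seed)
        net = make_random_network(rng, int(rng.integers(10, 200)))
        phi = 0.5 / net.spectral_radius()
        x = (rng.random(net.n_genes) < 0.1).astype(float)
        tol = 1e-10
        sj = katz_score_jacobi(net, x, phi, tol=tol).s
        sd = katz_score_direct(net, x, phi).s
        assert np.max(np.abs(sj - sd)) < 10 * tol

    def test_divergent_phi_raises_with_spectral_bound(self):
        net = two_node_network()  # rho = 1
        with pytest.raises(DivergenceError, match="1/rho"):
            katz_score_direct(net, np.array([1.0, 0.0]), 1.0)
        with pytest.raises(ValueError):
            katz_score_direct(net, np.array([1.0, 0.0]), -0.1)

    def test_jacobi_nonconvergence_carries_residual(self):
        net = two_node_network()
        with pytest.raises(ConvergenceError) as exc:
            katz_score_jacobi(net, np.array([1.0, 0.0]), 0.5, tol=1e-15, max_iter=2)
        assert exc.value.residual > 0

    def test_scores_monotone_in_phi(self):
        # Neumann series of nonnegative terms: s(phi1) <= s(phi2) componentwise
        rng = np.random.default_rng(3)
        net = make_random_network(rng, 60)
        x = (rng.random(60) < 0.2).astype(float)
        bound = 1.0 / net.spectral_radius()
        s1 = katz_score_direct(net, x, 0.2 * bound).s
        s2 = katz_score_direct(net, x, 0.6 * bound).s
        assert np.all(s1 <= s2 + 1e-12)
        assert np.all(s1 >= x - 1e-12)  # s >= x for nonnegative W

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        net = make_random_network(rng, 40)
        x = (rng.random(40) < 0.2).astype(float)
        phi = 0.4 / net.spectral_radius()
        s = katz_score_direct(net, x, phi).s
        perm = rng.permutation(40)
        net_p = WeightedNetwork(
            [net.genes[i] for i in perm], sparse.csr_array(net.W.todense()[np.ix_(perm, perm)])
        )
        s_p = katz_score_direct(net_p, x[perm], phi).s
        assert np.allclose(s_p, s[perm], atol=1e-10)

    def test_truncated_series_approximation_bound(self):
        rng = np.random.default_rng(5)
        net = make_random_network(rng, 30)
        rho = net.spectral_radius()
        phi = 0.3 / rho
        x = (rng.random(30) < 0.3).astype(float)
        s = katz_score_direct(net, x, phi).s
        T = 12
        approx = np.zeros_like(x)
        term = x.copy()
        for _ in range(T + 1):
            approx += term
            term = phi * (net.W @ term)
        bound = (phi * rho) ** (T + 1) / (1 - phi * rho) * np.linalg.norm(x)
        assert np.linalg.norm(s - approx) <= bound + 1e-12


class TestRanking:
    def test_descending_rank_example(self):
        assert rank_genes(np.array([0.1, 0.9, 0.5])).tolist() == [3, 1, 2]

    def test_ties_follow_stable_gene_order(self):
        assert rank_genes(np.array([0.5, 0.5, 0.5])).tolist() == [1, 2, 3]

    def test_rank_invariant_under_constant_shift(self):
        s = np.array([0.2, 0.8, 0.4, 0.8])
        assert rank_genes(s).tolist() == rank_genes(s + 7.0).tolist()


def toy_loci(n: int, chrom: str = "chr1") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "gene": [f"L{i:03d}" for i in range(n)],
        }
    )


class TestCandidateSets:
    def test_large_region_truncates_to_n_nearest(self):
        cs = build_candidate_set(toy_loci(250), "L125", 100)
        assert cs.N == 100 and "L125" in cs.members

    def test_small_region_takes_all(self):
        cs = build_candidate_set(toy_loci(37), "L010", 100)
        assert cs.N == 37

    def test_n_one_gives_singleton(self):
        cs = build_candidate_set(toy_loci(10), "L005", 1)
        assert cs.members == ("L005",)

    def test_absent_disease_gene_errors(self):
        with pytest.raises(KeyError):
            build_candidate_set(toy_loci(10), "nope", 5)

    def test_members_are_nearest_by_coordinate(self):
        cs = build_candidate_set(toy_loci(100), "L050", 11)
        expected = {f"L{i:03d}" for i in range(45, 56)}
        assert set(cs.members) == expected


class TestRRatio:
    def _score(self, genes, s):
        return katz_score_direct(
            WeightedNetwork(genes, sparse.csr_array((len(genes), len(genes)))),
            np.asarray(s, dtype=float),
            0.0,
        )

    def test_top_gene_gets_one_over_n(self):
        genes = [f"L{i}" for i in range(100)]
        score = self._score(genes, np.linspace(1, 0.01, 100))
        cs = build_candidate_set(
            pd.DataFrame(
                {"chrom": "c", "start": range(100), "end": range(1, 101), "gene": genes}
            ),
            "L0",
            100,
        )
        assert r_ratio(cs, score) == pytest.approx(0.01)

    def test_bottom_gene_gets_one(self):
        genes = ["a", "b", "c"]
        score = self._score(genes, [0.9, 0.5, 0.1])
        cs = build_candidate_set(
            pd.DataFrame({"chrom": "c", "start": [0, 1, 2], "end": [1, 2, 3], "gene": genes}),
            "c",
            3,
        )
        assert r_ratio(cs, score) == 1.0

    def test_members_missing_from_network_shrink_n(self):
        score = self._score(["a", "b"], [0.1, 0.9])
        from katznet.prioritize import CandidateSet

        cs = CandidateSet(disease_gene="a", members=("a", "b", "zz"))
        assert r_ratio(cs, score) == pytest.approx(2 / 2)


class TestCalibration:
    def test_single_grid_value_returned(self, small_scenario):
        net = generate_network(small_scenario)
        loci = generate_loci(small_scenario, genes_per_locus=30)
        cal = calibrate_phi(
            net,
            small_scenario.seed_genes,
            small_scenario.omim_genes,
            loci,
            grid=[1e-4],
            n_candidates=30,
        )
        assert cal.phi_star == 1e-4 and cal.grid.tolist() == [1e-4]

    def test_holdout_overlap_and_empty_grid_rejected(self, small_scenario):
        net = generate_network(small_scenario)
        loci = generate_loci(small_scenario, genes_per_locus=30)
        with pytest.raises(ValueError, match="overlap"):
            calibrate_phi(net, {"g001"}, {"g001"}, loci, grid=[1e-4])
        with pytest.raises(ValueError):
            calibrate_phi(net, set(), set(), loci, grid=[1e-4])
        with pytest.raises(ValueError):
            calibrate_phi(net, {"g001"}, {"g002"}, loci, grid=[])

    def test_planted_module_genes_rank_high_in_their_loci(self, small_scenario):
        net = generate_network(small_scenario)
        loci = generate_loci(small_scenario, genes_per_locus=50)
        cal = calibrate_phi(
            net,
            small_scenario.seed_genes,
            small_scenario.omim_genes,
            loci,
            grid=default_phi_grid(n_points=10),
            n_candidates=50,
        )
        assert float(np.min(cal.mean_r_ratio)) < 0.25

    def test_random_holdouts_stay_near_uniform_and_flat(self, small_scenario):
        net = generate_network(small_scenario)
        rng = np.random.default_rng(99)
        module = set(small_scenario.module_genes)
        others = [g for g in net.genes if g not in module]
        rand = sorted(rng.choice(others, size=9, replace=False))
        loci = generate_loci(small_scenario, held_out_genes=rand, genes_per_locus=30)
        cal = calibrate_phi(
            net,
            small_scenario.seed_genes,
            rand,
            loci,
            grid=default_phi_grid(n_points=5),
            n_candidates=30,
        )
        assert 0.25 < float(np.mean(cal.mean_r_ratio)) < 0.75
        assert float(np.ptp(cal.mean_r_ratio)) < 0.25


class TestTopFraction:
    def _score_of(self, s):
        genes = [f"g{i:03d}" for i in range(len(s))]
        net = WeightedNetwork(genes, sparse.csr_array((len(s), len(s))))
        return katz_score_direct(net, np.asarray(s, dtype=float), 0.0)

    def test_ceil_of_fraction_of_all_genes(self):
        score = self._score_of(np.linspace(1, 0.05, 20))
        assert len(select_top_fraction(score, 0.10, "all_genes")) == 2

    def test_full_fraction_returns_everything(self):
        score = self._score_of(np.linspace(1, 0.05, 20))
        assert len(select_top_fraction(score, 1.0)) == 20

    def test_positive_score_denominator(self):
        s = np.zeros(50)
        s[:7] = np.linspace(1, 0.5, 7)
        score = self._score_of(s)
        top = select_top_fraction(score, 0.10, "positive_score")
        assert len(top) == 1 and top[0] == "g000"

    def test_invalid_fraction_or_mode_rejected(self):
        score = self._score_of([1.0, 0.5])
        with pytest.raises(ValueError):
            select_top_fraction(score, 0.0)
        with pytest.raises(ValueError):
            select_top_fraction(score, 0.5, "bogus")
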