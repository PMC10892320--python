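"""Topology enumeration, WAG+Γ likelihood machinery, topology tests."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from gamoscan.codec import AMINO_ACIDS
from gamoscan.phylo.likelihood import (
    LikelihoodEngine,
    brute_force_log_likelihood,
    compress_alignment,
)
from gamoscan.phylo.mlmodel import MLPhylogeny, topology_test_table
from gamoscan.phylo.substitution import GammaRates, SubstitutionModel, discrete_gamma
from gamoscan.phylo.trees import (
    TreeTopology,
    enumerate_topologies,
    parse_newick,
    parse_newick_subtree,
)

WAG = SubstitutionModel.wag()


def double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


class TestEnumeration:
    @pytest.mark.parametrize("m", [3, 4, 5, 6, 7])
    def test_counts_match_double_factorial(self, m):
        tops = enumerate_topologies([f"t{i}" for i in range(m)])
        assert len(tops) == double_factorial(2 * m - 5)
        assert len({t.canonical_id for t in tops}) == len(tops)

    def test_constrained_five_otus(self):
        # three fixed subtrees over 11 leaves -> five effective OTUs -> 15 trees
        constraints = [
            ((("YC-IV", "HT-IV"), "ATCC30299"), "R1072"),
            (("SDT1-II", "SDT2-II"), "EN-II"),
            ("CCAP1607", "KR-III"),
        ]
        leaves = ["YC-IV", "HT-IV", "ATCC30299", "R1072", "SDT1-II", "SDT2-II",
                  "EN-II", "CCAP1607", "KR-III", "SG1-III", "Stentor"]
        tops = enumerate_topologies(leaves, constraints)
        assert len(tops) == 15
        for t in tops:
            assert t.contains_split({"YC-IV", "HT-IV"})
            assert t.contains_split({"SDT1-II", "SDT2-II"})
            assert t.contains_split({"CCAP1607", "KR-III"})

    def test_overlapping_constraints_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            enumerate_topologies(list("abcde"), [("a", "b"), ("b", "c")])

    def test_too_few_leaves_raise(self):
        with pytest.raises(ValueError):
            enumerate_topologies(["a", "b"])

    def test_newick_roundtrip(self):
        topo = enumerate_topologies(list("abcde"))[7]
        bl = {k: 0.1 for k in topo.edges()}
        back, lengths = parse_newick(topo.newick(bl))
        assert back.canonical_id == topo.canonical_id
        assert all(abs(lengths[k] - 0.1) < 1e-9 for k in topo.edges())

    def test_rooted_subtree_parse(self):
        sub = parse_newick_subtree("((a,b),c);")
        assert sub == (("a", "b"), "c")


class TestSubstitutionModel:
    def test_rate_matrix_rows_sum_to_zero(self):
        assert np.allclose(WAG.rate_matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_mean_rate_is_one(self):
        assert np.isclose(-np.sum(WAG.equilibrium_freqs * np.diag(WAG.rate_matrix)), 1.0)

    def test_detailed_balance(self):
        pi = WAG.equilibrium_freqs
        flux = pi[:, None] * WAG.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_transition_matrix_is_stochastic(self):
        for t in (0.01, 0.3, 2.0):
            P = WAG.transition_matrix(t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert (P >= 0).all()
        assert np.allclose(WAG.transition_matrix(0.0), np.eye(20), atol=1e-12)

    def test_stationarity(self):
        pi = WAG.equilibrium_freqs
        assert np.allclose(pi @ WAG.transition_matrix(0.7), pi)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma(0.3, 1).tolist() == [1.0]
        assert discrete_gamma(7.0, 1).tolist() == [1.0]

    def test_large_alpha_limit(self):
        # bin-mean deviation from 1 shrinks like 1/sqrt(alpha); at alpha=100
        # the outer categories still sit ~13% out, so the 1%-band limit is
        # only reached at very large shape values
        dev100 = np.abs(discrete_gamma(100.0, 4) - 1.0).max()
        dev1e4 = np.abs(discrete_gamma(1e4, 4) - 1.0).max()
        dev1e6 = np.abs(discrete_gamma(1e6, 4) - 1.0).max()
        assert dev100 > dev1e4 > dev1e6
        assert dev1e6 < 0.01

    @pytest.mark.parametrize("alpha,k", [(1.28, 4), (0.5, 4), (2.0, 8)])
    def test_mean_one(self, alpha, k):
        rates = discrete_gamma(alpha, k)
        assert np.isclose(rates.mean(), 1.0, atol=1e-10)

    def test_matches_quadrature(self):
        # bin means by direct numerical integration of the gamma density
        alpha, k = 1.28, 4
        dist = gamma_dist(a=alpha, scale=1.0 / alpha)
        edges = [0.0] + list(dist.ppf(np.arange(1, k) / k)) + [np.inf]
        want = [
            k * quad(lambda x: x * dist.pdf(x), edges[i], edges[i + 1])[0]
            for i in range(k)
        ]
        assert np.allclose(discrete_gamma(alpha, k), want, atol=1e-6)


def _random_seqs(rng, taxa, n):
    return {t: "".join(rng.choice(list(AMINO_ACIDS), n)) for t in taxa}


class TestPruning:
    def test_three_and_four_leaf_oracle(self, rng):
        # pruning equals explicit summation over internal states
        gamma = GammaRates(alpha=0.9, k=2)
        for taxa in (["a", "b", "c"], ["a", "b", "c", "d"]):
            seqs = _random_seqs(rng, taxa, 10)
            for topo in enumerate_topologies(taxa):
                bl = {k: 0.02 + 0.5 * rng.random() for k in topo.edges()}
                eng = LikelihoodEngine(seqs, WAG, gamma)
                mine = eng.site_log_likelihoods(eng.build_tree(topo, bl))
                want = brute_force_log_likelihood(seqs, topo, bl, WAG, gamma)
                assert np.max(np.abs((mine - want) / want)) < 1e-10

    def test_missing_data_oracle(self, rng):
        gamma = GammaRates(alpha=1.5, k=3)
        seqs = _random_seqs(rng, ["a", "b", "c", "d"], 8)
        seqs["b"] = seqs["b"][:3] + "-X" + seqs["b"][5:]
        topo = enumerate_topologies(["a", "b", "c", "d"])[0]
        bl = {k: 0.3 for k in topo.edges()}
        eng = LikelihoodEngine(seqs, WAG, gamma)
        mine = eng.site_log_likelihoods(eng.build_tree(topo, bl))
        want = brute_force_log_likelihood(seqs, topo, bl, WAG, gamma)
        assert np.allclose(mine, want, rtol=1e-10)

    def test_zero_branches_give_log_frequency(self):
        # identical sequences, all branch lengths ~0: per-site lnL -> ln(pi)
        seqs = {t: "WWKAA" for t in ("a", "b", "c")}
        topo = enumerate_topologies(["a", "b", "c"])[0]
        bl = {k: 1e-9 for k in topo.edges()}
        eng = LikelihoodEngine(seqs, WAG, GammaRates(alpha=1.0, k=4))
        got = eng.site_log_likelihoods(eng.build_tree(topo, bl))
        pi = dict(zip(AMINO_ACIDS, WAG.equilibrium_freqs))
        want = np.log([pi[c] for c in "WWKAA"])
        assert np.allclose(got, want, atol=1e-6)

    def test_lnl_invariant_to_structure_rearrangement(self, rng):
        # the same unrooted topology written with different rooting/child
        # order gives identical likelihood (reversibility)
        seqs = _random_seqs(rng, ["a", "b", "c", "d"], 30)
        gamma = GammaRates(alpha=1.0, k=4)
        variants = [
            TreeTopology((("a", "b"), "c", "d")),
            TreeTopology(("c", ("a", "b"), "d")),
            TreeTopology(("d", "c", ("b", "a"))),
            TreeTopology((("c", "d"), "a", "b")),
        ]
        assert len({v.canonical_id for v in variants}) == 1
        bl = {k: 0.05 + 0.4 * rng.random() for k in variants[0].edges()}
        vals = []
        for v in variants:
            eng = LikelihoodEngine(seqs, WAG, gamma)
            vals.append(eng.log_likelihood(eng.build_tree(v, bl)))
        assert np.allclose(vals, vals[0], rtol=1e-12)

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError, match="unknown residue"):
            compress_alignment({"a": "MB", "b": "MK"})


class TestBranchOptimization:
    def test_identical_pair_collapses_to_zero(self):
        seqs = {"a": "MKWVTFISLLEE" * 5, "b": "MKWVTFISLLEE" * 5}
        topo = TreeTopology(("a", "b"))
        eng = LikelihoodEngine(seqs, WAG, GammaRates(alpha=1.0, k=1))
        bl, lnl, ok = eng.optimize_branch_lengths(topo)
        assert sum(bl.values()) < 1e-4
        assert ok

    def test_pair_distance_recovery(self):
        # simulate a pair at known distance, recover within 10%
        from gamoscan.phylo.trees import edge_key
        from gamoscan.simulate import FamilyConfig, simulate_family

        d = 0.4
        cfg = FamilyConfig(
            species_tree=TreeTopology(("x", "y", "z")),
            species_branch_lengths={
                edge_key({"x"}, {"x", "y", "z"}): d / 2,
                edge_key({"y"}, {"x", "y", "z"}): d / 2,
                edge_key({"z"}, {"x", "y", "z"}): d / 2,
            },
            strains_per_species={"x": 1, "y": 1, "z": 1},
            protein_length=4000,
            alpha=1.0,
            n_rate_categories=1,
            seed=3,
        )
        truth = simulate_family(cfg)
        seqs = {r.id: r.residues for r in truth.alignment.records if r.id != "z_1"}
        topo = TreeTopology(("x_1", "y_1"))
        eng = LikelihoodEngine(seqs, WAG, GammaRates(alpha=1.0, k=1))
        bl, lnl, _ = eng.optimize_branch_lengths(topo)
        assert sum(bl.values()) == pytest.approx(d, rel=0.10)

    def test_monotone_improvement(self, rng):
        seqs = _random_seqs(rng, ["a", "b", "c", "d"], 40)
        topo = enumerate_topologies(["a", "b", "c", "d"])[2]
        eng = LikelihoodEngine(seqs, WAG, GammaRates(alpha=1.0, k=4))
        init = {k: 0.1 for k in topo.edges()}
        lnl0 = eng.log_likelihood(eng.build_tree(topo, init))
        _, lnl1, _ = eng.optimize_branch_lengths(topo, init=init)
        assert lnl1 >= lnl0


class TestMLPhylogeny:
    def test_three_taxa_single_topology(self, rng):
        seqs = _random_seqs(rng, ["a", "b", "c"], 50)
        res = MLPhylogeny(seqs, n_rate_categories=2).fit(alpha=1.0)
        assert len(res.fits) == 1
        assert res.fits[0].loglike == res.loglike

    def test_row_order_does_not_change_winner(self, small_truth):
        seqs = {r.id: r.residues for r in small_truth.alignment.records}
        res1 = MLPhylogeny(seqs, n_rate_categories=2).fit(alpha=1.28)
        shuffled = dict(reversed(list(seqs.items())))
        res2 = MLPhylogeny(shuffled, n_rate_categories=2).fit(alpha=1.28)
        assert res1.tree.canonical_id == res2.tree.canonical_id
        assert res1.loglike == pytest.approx(res2.loglike, abs=1e-3)

    def test_too_many_effective_leaves(self, rng):
        seqs = _random_seqs(rng, [f"t{i}" for i in range(10)], 10)
        with pytest.raises(ValueError, match="fix resolved"):
            MLPhylogeny(seqs)

    def test_summary_mentions_model_and_tree(self, small_truth):
        seqs = {r.id: r.residues for r in small_truth.alignment.records}
        res = MLPhylogeny(seqs, n_rate_categories=2).fit(alpha=1.28)
        text = res.summary()
        assert "WAG" in text and "log-likelihood" in text


class TestBootstrap:
    def test_b1_supports_binary_and_seeded(self, small_truth):
        seqs = {r.id: r.residues for r in small_truth.alignment.records}
        res = MLPhylogeny(seqs, n_rate_categories=2).fit(alpha=1.28)
        sup = res.bootstrap(n_boot=1, seed=42)
        assert set(sup.values()) <= {0.0, 1.0}
        assert res.bootstrap(n_boot=1, seed=42) == sup
        assert res.bootstrap(n_boot=3, seed=7) == res.bootstrap(n_boot=3, seed=7)


class TestTopologyTests:
    def test_ml_row_and_bounds(self, rng):
        site_lnl = -np.abs(rng.normal(3, 1, size=(4, 120)))
        table = topology_test_table(site_lnl, n_rell=2000, seed=1)
        best = int(np.argmax(site_lnl.sum(axis=1)))
        assert table.loc[best, "delta_lnL"] == 0.0
        assert table.loc[best, "p_kh"] == 1.0
        assert table.loc[best, "p_sh"] == 1.0
        assert (table.delta_lnL >= 0).all()
        assert ((table[["p_au", "p_kh", "p_sh"]] >= 0) & (table[["p_au", "p_kh", "p_sh"]] <= 1)).all().all()
        assert (table.delta_lnL == 0).sum() == 1

    def test_uniformly_worse_topology_rejected(self, rng):
        good = -np.abs(rng.normal(3, 0.3, size=200))
        site_lnl = np.vstack([good, good - 0.5])  # worse by 0.5 at every site
        table = topology_test_table(site_lnl, n_rell=10000, seed=2)
        assert table.loc[1, "p_kh"] < 0.05
        assert table.loc[1, "p_sh"] < 0.05
        assert table.loc[1, "p_au"] < 0.05

    def test_identical_rows_degenerate(self, rng):
        good = -np.abs(rng.normal(3, 0.3, size=100))
        site_lnl = np.vstack([good, good.copy()])
        table = topology_test_table(site_lnl, n_rell=1000, seed=3)
        assert (table.p_kh == 1.0).all()
        assert (table.p_sh == 1.0).all()
        assert (table.p_au == 1.0).all()

    def test_sh_at_least_kh(self, rng):
        # SH's simultaneous correction is more conservative than KH
        for trial in range(3):
            site_lnl = -np.abs(rng.normal(3, 1, size=(5, 150)))
            site_lnl[1:] -= rng.random((4, 1)) * 0.1
            table = topology_test_table(site_lnl, n_rell=4000, seed=trial)
            non_ml = table[~table.is_ml]
            assert (non_ml.p_sh >= non_ml.p_kh - 1e-12).all()
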