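import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from genecascade.data_model import InteractionNetwork, PathwayGraph
from genecascade.propagation import (
    RWRParams,
    SeedSet,
    combine_significance,
    function_pvalues,
    infer_key_genes,
    rwr,
    select_seeds,
    transfer_matrix,
)


def _net(edges):
    return InteractionNetwork(nx.Graph(edges))


def direct_solve(network, seeds, r):
    """Independent dense-linear-algebra oracle: P = r (I - (1-r)W)^-1 P0."""
    w, nodes = transfer_matrix(network)
    w = w.toarray()
    p0 = np.zeros(len(nodes))
    idx = [nodes.index(s) for s in seeds]
    p0[idx] = 1.0 / len(seeds)
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * w, p0)
    return pd.Series(p, index=nodes)


def random_connected_graph(n, rng):
    while True:
        g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return InteractionNetwork(nx.relabel_nodes(g, lambda i: f"n{i:02d}"))


class TestSelectSeeds:
    def test_star_pathway_takes_hub_and_first_leaf(self):
        leaves = [f"L{i:02d}" for i in range(10)]
        star = PathwayGraph("star", nx.star_graph(10))
        star = PathwayGraph("star", nx.relabel_nodes(
            nx.star_graph(10), {0: "HUB", **{i + 1: leaves[i] for i in range(10)}}
        ))
        network = _net([("HUB", l) for l in leaves])
        seeds = select_seeds(star, network)  # ceil(0.1 * 11) = 2
        assert seeds.seeds == ("HUB", "L00")

    def test_path_graph_tie_broken_lexicographically(self):
        nodes = [f"n{i}" for i in range(10)]
        pw = PathwayGraph("path", nx.Graph(list(zip(nodes, nodes[1:]))))
        network = _net(list(zip(nodes, nodes[1:])))
        seeds = select_seeds(pw, network)  # 1 seed among degree-2 internals
        assert seeds.seeds == ("n1",)

    def test_zero_fraction_rejected(self):
        pw = PathwayGraph("p", nx.Graph([("a", "b")]))
        with pytest.raises(ValueError, match="fraction"):
            select_seeds(pw, _net([("a", "b")]), fraction=0)

    def test_disjoint_pathway_rejected(self):
        pw = PathwayGraph("p", nx.Graph([("a", "b")]))
        with pytest.raises(ValueError, match="no gene"):
            select_seeds(pw, _net([("x", "y")]))

    def test_seeds_absent_from_network_dropped(self):
        # 11 pathway genes -> 2 seeds (hub + "a"); hub missing from network
        pw = PathwayGraph("p", nx.Graph([("hub", x) for x in "abcdefghij"]))
        network = _net([("a", "b")])
        seeds = select_seeds(pw, network)
        assert seeds.seeds == ("a",)

    def test_all_seeds_absent_errors(self):
        pw = PathwayGraph("p", nx.Graph([("hub", x) for x in "abcdefghi"]))
        network = _net([("a", "b")])  # sole seed (hub) not present
        with pytest.raises(ValueError, match="absent"):
            select_seeds(pw, network)


class TestRwr:
    def test_restart_one_returns_p0_exactly(self):
        net = _net([("a", "b"), ("b", "c")])
        v = rwr(net, SeedSet("f", ("a",)), RWRParams(restart=1.0))
        assert v.probabilities["a"] == 1.0
        assert v.probabilities["b"] == 0.0

    def test_path_graph_worked_example(self):
        net = _net([("a", "b"), ("b", "c")])
        v = rwr(net, SeedSet("f", ("a",)), RWRParams(restart=0.7))
        expected = direct_solve(net, ["a"], 0.7)
        np.testing.assert_allclose(v.probabilities.to_numpy(), expected.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(
            v.probabilities[["a", "b", "c"]].to_numpy(),
            [0.734615, 0.230769, 0.034615],
            atol=1e-6,
        )

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        net = random_connected_graph(40, rng)
        v = rwr(net, SeedSet("f", ("n00", "n01")), RWRParams())
        assert abs(v.probabilities.sum() - 1.0) < 1e-10
        assert (v.probabilities >= 0).all()

    def test_iterative_agrees_with_direct_solve(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            net = random_connected_graph(50, rng)
            seeds = tuple(sorted(rng.choice(sorted(net.nodes), 3, replace=False)))
            v = rwr(net, SeedSet("f", seeds), RWRParams())
            oracle = direct_solve(net, list(seeds), 0.7)
            assert np.max(np.abs(v.probabilities.to_numpy() - oracle.to_numpy())) < 1e-6

    def test_fixed_point_independent_of_initialization(self):
        net = _net([("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
        w, nodes = transfer_matrix(net)
        p0 = np.zeros(len(nodes)); p0[0] = 1.0
        params = RWRParams()
        # iterate from p0 and from the uniform vector; same fixed point
        def run(start):
            p = start.copy()
            for _ in range(params.max_iter):
                nxt = 0.3 * (w @ p) + 0.7 * p0
                if np.max(np.abs(nxt - p)) < params.tolerance:
                    return nxt
                p = nxt
            raise AssertionError("no convergence")
        from_p0 = run(p0)
        from_uniform = run(np.full(len(nodes), 1 / len(nodes)))
        np.testing.assert_allclose(from_p0, from_uniform, atol=1e-7)

    def test_seed_mass_monotone_in_restart(self):
        rng = np.random.default_rng(2)
        net = random_connected_graph(30, rng)
        seeds = ("n00", "n05")
        masses = []
        for r in (0.1, 0.3, 0.5, 0.7, 0.9):
            v = rwr(net, SeedSet("f", seeds), RWRParams(restart=r))
            masses.append(v.probabilities[list(seeds)].sum())
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_nonconvergence_reports_residual(self):
        net = _net([("a", "b"), ("b", "c")])
        with pytest.raises(RuntimeError, match="residual"):
            rwr(net, SeedSet("f", ("a",)), RWRParams(max_iter=1, tolerance=1e-15))

    def test_unknown_seed_rejected(self):
        net = _net([("a", "b")])
        with pytest.raises(ValueError, match="not in network"):
            rwr(net, SeedSet("f", ("zz",)))


class TestFunctionPvalues:
    def _star(self, n_leaves=60):
        leaves = [f"L{i:02d}" for i in range(n_leaves)]
        network = _net([("HUB", l) for l in leaves] + [(leaves[0], leaves[1])])
        pw = PathwayGraph("p", nx.Graph([("HUB", l) for l in leaves[:5]]))
        return network, pw

    def test_hub_seed_gets_small_p(self):
        network, pw = self._star()
        p = function_pvalues(network, pw, n_random=1000, seed=3)
        assert p["HUB"] < 0.05

    def test_solve_and_iterative_agree(self):
        network, pw = self._star()
        p_it = function_pvalues(network, pw, n_random=200, seed=5, method="iterative")
        p_sv = function_pvalues(network, pw, n_random=200, seed=5, method="solve")
        # identical pseudo-seed draws; steady states agree within tolerance
        assert np.max(np.abs(p_it.to_numpy() - p_sv.to_numpy())) <= 1 / 201 + 1e-12

    def test_all_nodes_as_seeds_rejected(self):
        network = _net([("a", "b"), ("b", "c")])
        pw = PathwayGraph("p", nx.Graph([("a", "b"), ("b", "c")]))
        with pytest.raises(ValueError, match="smaller than the network"):
            function_pvalues(network, pw, n_random=10, seed=1, fraction=1.0)

    def test_zero_randomizations_rejected(self):
        network, pw = self._star()
        with pytest.raises(ValueError, match="n_random"):
            function_pvalues(network, pw, n_random=0, seed=1)

    def test_null_pvalues_super_uniform(self):
        # random-regular network, arbitrary "pathway" -> no real structure:
        # rejection rate at alpha=0.05 must not exceed the binomial bound
        rng = np.random.default_rng(8)
        g = nx.random_regular_graph(4, 60, seed=42)
        network = InteractionNetwork(nx.relabel_nodes(g, lambda i: f"n{i:02d}"))
        rejections, total = 0, 0
        for trial in range(10):
            nodes = sorted(network.nodes)
            picks = rng.choice(len(nodes), 5, replace=False)
            sub = nx.path_graph([nodes[i] for i in picks])
            try:
                pw = PathwayGraph("null", sub)
            except ValueError:
                continue
            p = function_pvalues(network, pw, n_random=200, seed=int(rng.integers(2**31)))
            rejections += int((p.to_numpy() <= 0.05).sum())
            total += len(p)
        rate = rejections / total
        assert rate <= 0.05 + 1.96 * math.sqrt(0.05 * 0.95 / total)


class TestCombineSignificance:
    def test_k1_reproduces_input_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1.0, size=1000)
        frame = pd.DataFrame({"f": p}, index=[f"g{i:04d}" for i in range(1000)])
        out = combine_significance(frame)
        recovered = np.array([c.p_combined for c in out])
        np.testing.assert_allclose(recovered, p, atol=1e-12)

    def test_k2_closed_form(self):
        frame = pd.DataFrame({"f1": [0.05], "f2": [0.05]}, index=["g"])
        c = combine_significance(frame)[0]
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert c.chi2 == pytest.approx(11.9829, abs=1e-4)
        assert c.p_combined == pytest.approx(math.exp(-x / 2) * (1 + x / 2), abs=1e-12)
        assert c.p_combined == pytest.approx(0.01748, abs=1e-4)
        assert c.df == 4

    def test_all_ones_give_chi2_zero(self):
        frame = pd.DataFrame({"f1": [1.0], "f2": [1.0]}, index=["g"])
        c = combine_significance(frame)[0]
        assert c.chi2 == 0.0
        assert c.p_combined == 1.0

    def test_zero_p_rejected(self):
        frame = pd.DataFrame({"f": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="pseudocount"):
            combine_significance(frame)

    def test_mutated_genes_reported_but_not_key(self):
        frame = pd.DataFrame({"f": [1e-9, 0.5]}, index=["APC", "other"])
        out = {c.gene: c for c in combine_significance(frame, mutated_genes={"APC"})}
        assert out["APC"].excluded_reason == "driver_mutated"
        assert not out["APC"].is_key
        assert out["APC"].q_value <= 0.05  # still reported with its statistics


class TestInferKeyGenes:
    def test_composition_matches_manual_pipeline(self):
        leaves = [f"L{i:02d}" for i in range(8)]
        network = _net([("HUB", l) for l in leaves] + [("L00", "L01")])
        pw = PathwayGraph("p", nx.Graph([("HUB", l) for l in leaves[:4]]))
        table = infer_key_genes(network, [pw], n_random=100, seed=77)
        manual_p = function_pvalues(
            network, pw, n_random=100,
            seed=int(np.random.SeedSequence(77).spawn(1)[0].generate_state(1)[0] % 2**31),
        )
        combined = combine_significance(pd.DataFrame({"p": manual_p}))
        manual = {c.gene: c.chi2 for c in combined}
        for _, row in table.iterrows():
            assert row["chi2"] == pytest.approx(manual[row["gene"]], abs=1e-9)

    def test_planted_keys_rank_above_background(self, small_bundle):
        from scipy.stats import mannwhitneyu

        dys = [pw for pw in small_bundle.pathways if pw.name in small_bundle.truth.dysregulated_pathways]
        table = infer_key_genes(small_bundle.network, dys, n_random=300, seed=13)
        rank_of = {g: i for i, g in enumerate(table["gene"])}
        planted = [rank_of[g] for g in small_bundle.truth.key_genes]
        background = [rank_of[g] for g in table["gene"] if g not in small_bundle.truth.key_genes]
        assert np.median(planted) < np.median(background)
        assert mannwhitneyu(planted, background, alternative="less").pvalue < 0.01

    def test_no_pathways_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            infer_key_genes(_net([("a", "b")]), [], seed=1)

    def test_chi2_consistent_with_per_function_columns(self):
        network, pw = TestFunctionPvalues()._star()
        table = infer_key_genes(network, [pw], n_random=50, seed=3)
        recomputed = -2 * np.log(table["p_p"].to_numpy())
        np.testing.assert_allclose(table["chi2"].to_numpy(), recomputed, atol=1e-9)
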