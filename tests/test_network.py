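"""Co-occurrence network: Spearman machinery, edge capping, module
detection, Zi/Pi (against an independent brute-force calculator), role
classification and network comparison."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import keloidomics as k
from keloidomics import network as net
from keloidomics.tables import AbundanceTable


def _table(arr, features=None):
    arr = np.asarray(arr, float)
    features = features or [f"f{j+1}" for j in range(arr.shape[1])]
    idx = [f"s{i+1}" for i in range(arr.shape[0])]
    return AbundanceTable(pd.DataFrame(arr, index=idx, columns=features))


class TestSpearman:
    def test_monotone_pair_rho_one(self):
        tab = _table(np.column_stack([np.arange(6), np.arange(6) ** 2 + 1]))
        rho, p = net.spearman_matrix(tab)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        # ranks of y are (1,3,2,5,4): sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        tab = _table(np.column_stack([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]]))
        rho, _ = net.spearman_matrix(tab)
        assert rho.iloc[0, 1] == pytest.approx(0.8)

    def test_constant_feature_never_edge(self):
        arr = np.random.default_rng(0).uniform(size=(10, 3))
        arr[:, 2] = 0.5
        rho, p = net.spearman_matrix(_table(arr))
        assert np.isnan(rho.iloc[0, 2]) and np.isnan(rho.iloc[2, 1])
        g = net.build_network(rho, p, corr_p=1.0, corr_r=0.0)
        assert "f3" not in [u for e in g.edges for u in e]

    def test_null_calibration(self, rng):
        arr = rng.uniform(size=(60, 46))  # 1035 pairs
        _, p = net.spearman_matrix(_table(arr))
        iu = np.triu_indices(46, k=1)
        rate = (p.to_numpy()[iu] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_cross_block_agrees_with_scipy(self, rng):
        from scipy import stats
        a = pd.DataFrame(rng.normal(size=(20, 4)))
        b = pd.DataFrame(rng.normal(size=(20, 3)))
        rho, p = net.spearman_cross(a, b)
        for i in range(4):
            for j in range(3):
                ref = stats.spearmanr(a.iloc[:, i], b.iloc[:, j])
                assert rho[i, j] == pytest.approx(ref.statistic)
                assert p[i, j] == pytest.approx(ref.pvalue)


def _mock_matrices(entries, ids):
    """Build symmetric rho/p frames from {(u,v): (rho, p)}."""
    n = len(ids)
    rho = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    p = pd.DataFrame(np.ones((n, n)) - np.eye(n), index=ids, columns=ids)
    np.fill_diagonal(p.values, 0.0)
    for (u, v), (r_, p_) in entries.items():
        rho.loc[u, v] = rho.loc[v, u] = r_
        p.loc[u, v] = p.loc[v, u] = p_
    return rho, p


class TestBuildNetwork:
    def test_cap_exact(self, rng):
        ids = [f"t{i}" for i in range(40)]
        entries = {}
        pairs = list(itertools.combinations(ids, 2))
        for u, v in pairs[:250]:
            entries[(u, v)] = (rng.uniform(0.4, 0.99), 0.001)
        rho, p = _mock_matrices(entries, ids)
        g = net.build_network(rho, p, top_edges=200)
        assert g.number_of_edges() == 200
        kept = sorted(abs(d["rho"]) for _, _, d in g.edges(data=True))
        excluded = sorted(entries.values())[:50]
        assert kept[0] >= max(r for r, _ in excluded[:0] or [(0, 0)])  # cap respected

    def test_cap_not_padded(self, rng):
        ids = [f"t{i}" for i in range(30)]
        pairs = list(itertools.combinations(ids, 2))
        entries = {pair: (rng.uniform(0.4, 0.99), 0.001) for pair in pairs[:150]}
        rho, p = _mock_matrices(entries, ids)
        g = net.build_network(rho, p, top_edges=200)
        assert g.number_of_edges() == 150

    def test_threshold_strictness_and_sign(self):
        ids = ["a", "b", "c", "d"]
        entries = {("a", "b"): (0.3, 0.001),    # |rho| not > 0.3 -> excluded
                   ("a", "c"): (0.8, 0.05),     # p not < 0.05 -> excluded
                   ("a", "d"): (-0.5, 0.01)}    # kept, negative
        rho, p = _mock_matrices(entries, ids)
        g = net.build_network(rho, p)
        assert set(g.edges) == {("a", "d")}
        assert g["a"]["d"]["sign"] == "neg"
        assert set(g.nodes) == set(ids)  # isolated nodes retained

    def test_tie_break_lexicographic(self):
        ids = ["a", "b", "c"]
        entries = {("a", "b"): (0.6, 0.001), ("b", "c"): (0.6, 0.001)}
        rho, p = _mock_matrices(entries, ids)
        g1 = net.build_network(rho, p, top_edges=1)
        g2 = net.build_network(rho, p, top_edges=1)
        assert set(g1.edges) == {("a", "b")} == set(g2.edges)

    def test_retained_dominate_excluded(self, rng):
        ids = [f"t{i}" for i in range(30)]
        pairs = list(itertools.combinations(ids, 2))
        entries = {pair: (rng.uniform(0.31, 0.99) * rng.choice([-1, 1]), 0.001)
                   for pair in pairs}
        rho, p = _mock_matrices(entries, ids)
        g = net.build_network(rho, p, top_edges=100)
        kept = {tuple(sorted(e)) for e in g.edges}
        kept_min = min(abs(d["rho"]) for _, _, d in g.edges(data=True))
        excl_max = max(abs(r) for pair, (r, _) in entries.items()
                       if tuple(sorted(pair)) not in kept)
        assert kept_min >= excl_max


class TestModules:
    def test_two_cliques(self):
        g = nx.Graph()
        g.add_edges_from(itertools.combinations(range(5), 2))
        g.add_edges_from(itertools.combinations(range(5, 10), 2))
        g.add_edge(0, 5)
        assign = net.detect_modules(g, seed=0)
        assert len(set(assign.values())) == 2
        assert len({assign[i] for i in range(5)}) == 1
        assert len({assign[i] for i in range(5, 10)}) == 1

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(6)
        assert len(set(net.detect_modules(g, seed=0).values())) == 1

    def test_seed_determinism(self, rng):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        a = net.detect_modules(g, seed=3)
        b = net.detect_modules(g.copy(), seed=3)
        assert a == b

    def test_edgeless_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assign = net.detect_modules(g, seed=0)
        assert len(set(assign.values())) == 3

    def test_planted_module_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        aris = []
        for seed in range(20):
            tab, _, truth = k.generate_microbiome(
                n_taxa=40, n_diff=0, n_modules=4,
                module_size=5, module_rho=0.8, seed=seed)
            sub = tab.subset_features(list(truth.module_assignments))
            g = net.finalize_network(sub, top_edges=500, seed=0)
            planted = [truth.module_assignments[f] for f in sub.feature_ids]
            found = [g.nodes[f]["module"] for f in sub.feature_ids]
            aris.append(adjusted_rand_score(planted, found))
        assert np.mean(aris) >= 0.9


def brute_force_zipi(g):
    """Independent Zi/Pi calculator working from raw adjacency lists."""
    module = {n: g.nodes[n]["module"] for n in g}
    zi, pi = {}, {}
    for n in g:
        counts = {}
        for nb in g.neighbors(n):
            counts[module[nb]] = counts.get(module[nb], 0) + 1
        ktot = sum(counts.values())
        pi[n] = 0.0 if ktot == 0 else 1 - sum((c / ktot) ** 2 for c in counts.values())
    for m in set(module.values()):
        members = [n for n in g if module[n] == m]
        kw = [sum(1 for nb in g.neighbors(n) if module[nb] == m) for n in members]
        mean = sum(kw) / len(kw)
        var = sum((x - mean) ** 2 for x in kw) / len(kw)
        sd = var ** 0.5
        for n, x in zip(members, kw):
            zi[n] = (x - mean) / sd if sd > 0 else 0.0
    return zi, pi


class TestZiPi:
    def test_all_edges_internal_pi_zero(self):
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, {n: 0 for n in g}, "module")
        _, pi = net.zipi(g)
        assert all(v == 0.0 for v in pi.values())

    def test_even_split_pi_half(self):
        g = nx.star_graph(4)  # center 0 with 4 leaves
        nx.set_node_attributes(g, {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}, "module")
        _, pi = net.zipi(g)
        assert pi[0] == pytest.approx(0.5)

    def test_star_module_zi(self):
        g = nx.star_graph(5)  # 6 nodes, one module
        nx.set_node_attributes(g, {n: 0 for n in g}, "module")
        zi, pi = net.zipi(g)
        bz, bp = brute_force_zipi(g)
        for n in g:
            assert zi[n] == pytest.approx(bz[n], abs=1e-12)
            assert pi[n] == pytest.approx(bp[n], abs=1e-12)

    def test_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for rep in range(100):
            n = int(rng.integers(5, 61))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.03, 0.3)), seed=rep)
            net.detect_modules(g, seed=rep)
            zi, pi = net.zipi(g)
            bz, bp = brute_force_zipi(g)
            for node in g:
                assert abs(zi[node] - bz[node]) <= 1e-12
                assert abs(pi[node] - bp[node]) <= 1e-12

    def test_pi_bound_and_zi_centering(self):
        g = nx.gnp_random_graph(50, 0.15, seed=9)
        net.detect_modules(g, seed=9)
        zi, pi = net.zipi(g)
        module = nx.get_node_attributes(g, "module")
        for n in g:
            mods = {module[nb] for nb in g.neighbors(n)}
            m = max(len(mods), 1)
            assert 0.0 <= pi[n] <= 1 - 1 / m + 1e-12
        for m in set(module.values()):
            zs = [zi[n] for n in g if module[n] == m]
            assert abs(np.mean(zs)) < 1e-9


class TestClassify:
    def _graph_with(self, zi, pi):
        g = nx.Graph()
        g.add_node("x")
        nx.set_node_attributes(g, {"x": 0}, "module")
        nx.set_node_attributes(g, {"x": zi}, "Zi")
        nx.set_node_attributes(g, {"x": pi}, "Pi")
        return g

    @pytest.mark.parametrize("zi,pi,expected", [
        (3.0, 0.5, "module_hub"),
        (1.0, 0.7, "connector"),
        (3.0, 0.7, "network_hub"),
        (1.0, 0.5, "peripheral"),
        (2.5, 0.62, "peripheral"),  # exact boundary falls to peripheral
        (2.5, 0.7, "peripheral"),
        (3.0, 0.62, "peripheral"),
    ])
    def test_role_thresholds(self, zi, pi, expected):
        g = self._graph_with(zi, pi)
        cat, core = net.classify_nodes(g)
        assert cat["x"] == expected
        assert ("x" in core) == (expected == "connector")

    def test_exhaustive_grid_matches_threshold_logic(self):
        grid = [2.3, 2.5 - 1e-9, 2.5, 2.5 + 1e-9, 2.7]
        pgrid = [0.6, 0.62 - 1e-9, 0.62, 0.62 + 1e-9, 0.7]
        for zi in grid:
            for pi in pgrid:
                g = self._graph_with(zi, pi)
                cat, _ = net.classify_nodes(g)
                if zi > 2.5 and pi < 0.62:
                    want = "module_hub"
                elif zi < 2.5 and pi > 0.62:
                    want = "connector"
                elif zi > 2.5 and pi > 0.62:
                    want = "network_hub"
                else:
                    want = "peripheral"
                assert cat["x"] == want


class TestCompare:
    def _finalized(self, seed=0):
        tab, meta, _ = k.generate_microbiome(n_mk=20, n_ns=20, n_taxa=40,
                                             n_diff=0, n_modules=4,
                                             module_size=5, seed=seed)
        return net.finalize_network(tab, top_edges=100, seed=0)

    def test_identical_networks_share_full_core(self):
        g = self._finalized()
        comp = net.compare_networks(g, g)
        core = sorted(n for n, c in g.nodes(data="category") if c == "connector")
        assert comp.shared_core == core

    def test_disjoint_nodes_empty_intersection(self):
        g1 = self._finalized(0)
        g2 = nx.relabel_nodes(g1, {n: n + "_other" for n in g1.nodes})
        comp = net.compare_networks(g1, g2)
        assert comp.shared_core == []

    def test_planted_shared_connectors(self):
        g1, g2 = nx.Graph(), nx.Graph()
        for g in (g1, g2):
            g.add_nodes_from(["h1", "h2", "h3", "x"])
            for n in g.nodes:
                g.nodes[n]["module"] = 0
                g.nodes[n]["Zi"] = 0.0
                g.nodes[n]["Pi"] = 0.8 if n.startswith("h") else 0.1
            net.classify_nodes(g)
        comp = net.compare_networks(g1, g2)
        assert comp.shared_core == ["h1", "h2", "h3"]

    def test_edge_sign_counts(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.5, p=0.01, sign="pos")
        g.add_edge("b", "c", rho=-0.5, p=0.01, sign="neg")
        for n in g.nodes:
            g.nodes[n].update(module=0, Zi=0.0, Pi=0.0, category="peripheral")
        comp = net.compare_networks(g, g, labels=("MK", "NS"))
        assert comp.edge_counts["MK"] == {"pos": 1, "neg": 1}
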