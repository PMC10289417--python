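"""Basin and nearest-neighbour graph construction and module detection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

import basinnet as bn
from basinnet.errors import InvalidArgumentError, InvalidDataError
from basinnet.networks import build_basin_graph, build_nn_graph, detect_modules, modularity
from conftest import random_occurrence, synthetic_dataset


def occurrence_from_sets(basins: dict) -> pd.DataFrame:
    species = sorted({s for members in basins.values() for s in members})
    occ = pd.DataFrame(0, index=species, columns=list(basins), dtype=np.int8)
    for b, members in basins.items():
        for s in members:
            occ.at[s, b] = 1
    return occ


def set_partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def exhaustive_best_q(g):
    best = -2.0
    for p in set_partitions(list(g.nodes)):
        memb = {n: i for i, blk in enumerate(p) for n in blk}
        best = max(best, modularity(g, memb))
    return best


class TestBasinGraph:
    def test_weights_are_shared_species_counts(self):
        occ = occurrence_from_sets({"A": {"s1", "s2", "s3"}, "B": {"s2", "s3"}})
        g = build_basin_graph(occ)
        assert g["A"]["B"]["weight"] == 2

    def test_disjoint_basins_have_no_edge(self):
        occ = occurrence_from_sets({"A": {"s1"}, "B": {"s2"}})
        g = build_basin_graph(occ)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 2  # isolated basins kept

    def test_random_matrices_match_set_intersection(self, rng):
        for _ in range(10):
            occ = random_occurrence(rng)
            g = build_basin_graph(occ)
            cols = {b: set(occ.index[occ[b] == 1]) for b in occ.columns}
            for a, b in itertools.combinations(occ.columns, 2):
                shared = len(cols[a] & cols[b])
                if shared:
                    assert g[a][b]["weight"] == shared
                else:
                    assert not g.has_edge(a, b)

    def test_non_binary_rejected(self):
        occ = occurrence_from_sets({"A": {"s1"}})
        occ.iloc[0, 0] = 2
        with pytest.raises(InvalidDataError):
            build_basin_graph(occ)


class TestNNGraph:
    def make_distance(self, arr, ids=None):
        ids = ids or [f"s{i}" for i in range(len(arr))]
        return pd.DataFrame(np.asarray(arr, float), index=ids, columns=ids)

    def test_full_nn_gives_complete_digraph(self, rng):
        n = 6
        d = rng.random((n, n))
        d = self.make_distance((d + d.T) / 2)
        g = build_nn_graph(d, n - 1)
        assert g.number_of_edges() == n * (n - 1)

    def test_nn1_targets_row_argmin(self, rng):
        for _ in range(5):
            a = rng.random((4, 4))
            d = self.make_distance((a + a.T) / 2)
            g = build_nn_graph(d, 1)
            arr = d.to_numpy().copy()
            np.fill_diagonal(arr, np.inf)
            for i, sp in enumerate(d.index):
                (target,) = list(g.successors(sp))
                assert target == d.index[int(np.argmin(arr[i]))]

    def test_out_degree_exactly_nn(self, rng):
        a = rng.random((9, 9))
        d = self.make_distance((a + a.T) / 2)
        for nn in (1, 3, 5):
            g = build_nn_graph(d, nn)
            assert all(deg == nn for _, deg in g.out_degree())
            assert sum(deg for _, deg in g.out_degree()) == 9 * nn

    def test_ties_break_by_ascending_identifier(self):
        ids = ["d", "a", "c", "b"]
        arr = np.ones((4, 4))
        np.fill_diagonal(arr, 0.0)
        d = self.make_distance(arr, ids=ids)
        g = build_nn_graph(d, 2)
        # all distances equal: each node links to the two smallest ids != self
        assert set(g.successors("d")) == {"a", "b"}
        assert set(g.successors("a")) == {"b", "c"}

    def test_bad_nn_and_nan_rejected(self, rng):
        a = rng.random((4, 4))
        d = self.make_distance((a + a.T) / 2)
        with pytest.raises(InvalidArgumentError):
            build_nn_graph(d, 0)
        with pytest.raises(InvalidArgumentError):
            build_nn_graph(d, 4)
        d.iloc[0, 1] = np.nan
        with pytest.raises(InvalidDataError):
            build_nn_graph(d, 1)


class TestModularity:
    def two_cliques(self, k=4):
        g = nx.Graph()
        for off in (0, k):
            for i, j in itertools.combinations(range(k), 2):
                g.add_edge(off + i, off + j)
        g.add_edge(0, k)
        return g

    def test_single_module_is_zero(self):
        g = self.two_cliques()
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0, abs=1e-12)

    def test_matches_networkx_oracle(self, rng):
        g = self.two_cliques()
        for _ in range(10):
            labels = rng.integers(0, 3, g.number_of_nodes())
            memb = dict(zip(g.nodes, labels))
            comms = {}
            for n, m in memb.items():
                comms.setdefault(m, set()).add(n)
            expected = nx.community.modularity(g, comms.values())
            assert modularity(g, memb) == pytest.approx(expected, abs=1e-12)

    def test_directed_formula_hand_value(self):
        # 3-cycle, all degrees 1, m = 3; one module -> Q = 0
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        assert modularity(g, {0: 0, 1: 0, 2: 0}) == pytest.approx(0.0, abs=1e-12)
        # modules {0,1} and {2}: ordered within-pairs contribute
        # (0,0):-1/3, (0,1):1-1/3, (1,0):-1/3, (1,1):-1/3, (2,2):-1/3
        # -> Q = (1/3) * (1 - 5/3) = -2/9
        q = modularity(g, {0: 0, 1: 0, 2: 1})
        assert q == pytest.approx(-2.0 / 9.0, abs=1e-12)

    def test_empty_graph_and_missing_nodes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            modularity(nx.Graph(), {})
        g = self.two_cliques()
        with pytest.raises(InvalidArgumentError):
            modularity(g, {0: 0})


class TestDetectModules:
    def test_planted_two_cliques_recovered(self):
        g = nx.Graph()
        for off in (0, 5):
            for i, j in itertools.combinations(range(5), 2):
                g.add_edge(off + i, off + j)
        g.add_edge(0, 5)
        part = detect_modules(g, seed=0)
        truth = [0] * 5 + [1] * 5
        found = [part.membership[n] for n in range(10)]
        assert adjusted_rand_score(truth, found) == 1.0
        assert part.q > 0.3

    def test_modules_stay_within_components(self):
        g = nx.disjoint_union_all(
            [nx.complete_graph(4), nx.complete_graph(3), nx.path_graph(3)]
        )
        part = detect_modules(g, seed=1)
        comps = list(nx.connected_components(g))
        for i, comp in enumerate(comps):
            mods = {part.membership[n] for n in comp}
            for other in comps[i + 1 :]:
                assert mods.isdisjoint({part.membership[n] for n in other})

    def test_exhaustive_optimum_undirected(self):
        g = TestModularity().two_cliques()
        best = exhaustive_best_q(g)
        hits = sum(
            abs(detect_modules(g, seed=s).q - best) < 1e-9 for s in range(100)
        )
        assert hits >= 95

    def test_exhaustive_optimum_directed(self):
        g = nx.DiGraph()
        for off in (0, 4):
            for i in range(4):
                g.add_edge(off + i, off + (i + 1) % 4)
                g.add_edge(off + (i + 1) % 4, off + i)
        g.add_edge(0, 4)
        best = exhaustive_best_q(g)
        hits = sum(
            abs(detect_modules(g, seed=s).q - best) < 1e-9 for s in range(100)
        )
        assert hits >= 95

    def test_seeded_reproducibility(self, small_dataset):
        g = build_nn_graph(small_dataset["cd"], 5)
        a = detect_modules(g, seed=42)
        b = detect_modules(g, seed=42)
        assert a.membership == b.membership and a.q == b.q

    def test_partition_indices_contiguous(self, small_dataset):
        g = build_basin_graph(small_dataset["occ"])
        part = detect_modules(g, seed=3)
        mods = set(part.membership.values())
        assert mods == set(range(len(mods)))
        assert -1.0 <= part.q <= 1.0


class TestStructuralTrends:
    def test_modularity_decreases_with_nn(self):
        """Denser NN graphs are less modular (Spearman rho < 0)."""
        ds = synthetic_dataset(7, n_species=120, n_basins=49, range_radius=0.21)
        nn_values = [5, 10, 25, 50]
        medians = []
        for nn in nn_values:
            g = build_nn_graph(ds["cd"], nn)
            qs = [detect_modules(g, seed=s).q for s in range(3)]
            medians.append(np.median(qs))
        rho, _ = spearmanr(nn_values, medians)
        assert rho < 0

    def test_basin_modules_are_geographic(self):
        """Range geometry makes basin modules spatially coherent."""
        ds = synthetic_dataset(8, n_species=100, n_basins=225, range_radius=0.14)
        part = detect_modules(build_basin_graph(ds["occ"]), seed=5)
        coords = ds["coords"].set_index("basin_id")
        xy = coords[["x", "y"]].to_numpy()
        labels = np.array([part.membership[b] for b in coords.index])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(xy))
        iu = np.triu_indices(len(xy), 1)
        same = (labels[:, None] == labels[None, :])[iu]
        assert d[iu][same].mean() < d[iu][~same].mean()
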