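"""Auto-CM training contract, weight→distance transform and MST filter."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dehpkids import autocm
from dehpkids.autocm import INIT_WEIGHT_FRACTION


class TestMinmaxScale:
    @pytest.mark.parametrize(
        "col,expected",
        [([2, 4, 6], [0, 0.5, 1]), ([-1, 0, 3], [0, 0.25, 1])],
    )
    def test_affine(self, col, expected):
        np.testing.assert_allclose(autocm.minmax_scale(col), expected)

    def test_constant_column_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            np.testing.assert_allclose(autocm.minmax_scale([7, 7, 7]), [0.5, 0.5, 0.5])

    def test_missing_stays_missing(self):
        out = autocm.minmax_scale([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and out[0] == 0.0 and out[2] == 1.0


class TestHighLowEncode:
    def test_doubles_columns_and_complements(self):
        df = pd.DataFrame({"a": [0.2, 0.9], "b": [0.0, 1.0]})
        enc = autocm.high_low_encode(df)
        assert list(enc.columns) == ["a high", "a low", "b high", "b low"]
        np.testing.assert_allclose(enc["a low"], [0.8, 0.1])
        high = enc[[c for c in enc.columns if c.endswith("high")]].to_numpy()
        low = enc[[c for c in enc.columns if c.endswith("low")]].to_numpy()
        np.testing.assert_allclose(high + low, 1.0)

    def test_eleven_variables_give_22_columns(self):
        df = pd.DataFrame(
            np.random.default_rng(0).random((5, 11)), columns=[f"v{i}" for i in range(11)]
        )
        assert autocm.high_low_encode(df).shape[1] == 22

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            autocm.high_low_encode(pd.DataFrame({"a": [0.5, 1.2]}))


class TestTraining:
    def test_deterministic(self):
        X = np.random.default_rng(1).random((30, 5))
        m1 = autocm.train_autocm(X)
        m2 = autocm.train_autocm(X.copy())
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.v, m2.v)
        assert m1.epochs_run == m2.epochs_run

    def test_all_zero_data_is_update_fixed_point(self):
        m = autocm.train_autocm(np.zeros((8, 4)))
        init = 4 * INIT_WEIGHT_FRACTION
        np.testing.assert_array_equal(m.v, np.full(4, init))
        np.testing.assert_array_equal(m.W, np.full((4, 4), init))
        assert m.converged

    def test_weights_stay_in_bounds(self):
        X = np.random.default_rng(2).random((40, 6))
        m = autocm.train_autocm(X, max_epochs=200)
        assert m.v.min() >= 0 and m.v.max() <= m.C
        assert m.W.min() >= 0 and m.W.max() <= m.C

    def test_one_record_hand_iteration(self):
        """Single record of ones, N=2, C=2, α=0.1: match the recurrences by hand."""
        C, alpha = 2.0, 0.1
        m = autocm.train_autocm(np.ones((1, 2)), C=C, learning_rate=alpha, max_epochs=1)
        v = np.full(2, C * INIT_WEIGHT_FRACTION)
        W = np.full((2, 2), C * INIT_WEIGHT_FRACTION)
        x = np.ones(2)
        h = x * (1 - v / C)
        net = (W @ h) / 2
        o = h * (1 - net / C)
        v_next = v + alpha * (x - h) * (1 - v / C)
        W_next = W + alpha * ((h - o)[:, None] * (1 - W / C)) * h[None, :]
        np.testing.assert_allclose(m.v, v_next, rtol=1e-12)
        np.testing.assert_allclose(m.W, W_next, rtol=1e-12)

    def test_duplicated_column_attains_row_max_weight(self):
        rng = np.random.default_rng(3)
        X = rng.random((50, 6))
        X[:, 3] = X[:, 1]
        m = autocm.train_autocm(X)
        wb = (m.W + m.W.T) / 2
        np.fill_diagonal(wb, -np.inf)
        assert wb[1, 3] == wb[1].max()
        assert wb[1, 3] == wb[3].max()

    def test_mean_delta_decreases_after_burn_in(self):
        X = np.random.default_rng(4).random((30, 5))
        m = autocm.train_autocm(X)
        hist = np.array(m.mean_delta_history)
        peak = int(hist.argmax())
        assert np.all(np.diff(hist[peak:]) <= 1e-12)
        assert m.converged

    def test_input_guards(self):
        with pytest.raises(ValueError, match="missing"):
            autocm.train_autocm(np.array([[0.1, np.nan]]))
        with pytest.raises(ValueError, match="positive"):
            autocm.train_autocm(np.ones((2, 2)) * 0.5, C=0.0)
        with pytest.raises(ValueError, match="scaled"):
            autocm.train_autocm(np.array([[0.1, 1.7]]))

    def test_batch_mode_also_trains_and_is_deterministic(self):
        X = np.random.default_rng(5).random((20, 4))
        m1 = autocm.train_autocm(X, batch=True)
        m2 = autocm.train_autocm(X, batch=True)
        np.testing.assert_array_equal(m1.W, m2.W)


class TestWeightsToDistances:
    def test_extremes_and_symmetrization(self):
        m = autocm.AutoCMModel(
            n_vars=3, C=1.0,
            v=np.zeros(3),
            W=np.array([[0.0, 0.2, 0.0], [0.4, 0.0, 1.0], [0.0, 1.0, 0.0]]),
            epochs_run=1, converged=True,
        )
        cmap = autocm.weights_to_distances(m)
        assert cmap.strengths[0, 1] == pytest.approx(0.3)  # (0.2+0.4)/2
        assert cmap.distances[0, 1] == pytest.approx(0.7)
        assert cmap.distances[0, 2] == pytest.approx(1.0)  # zero weight
        assert cmap.distances[1, 2] == pytest.approx(0.0)  # weight = C
        assert (np.diag(cmap.distances) == 0).all()
        assert (np.diag(cmap.strengths) == 1).all()

    def test_untrained_rejected(self):
        m = autocm.AutoCMModel(2, 1.0, np.zeros(2), np.zeros((2, 2)), 0, False)
        with pytest.raises(ValueError, match="trained"):
            autocm.weights_to_distances(m)


def _brute_force_mst_total(d):
    """Minimum spanning-tree weight by enumerating all edge subsets of size N−1."""
    n = d.shape[0]
    edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(d[i, j] for i, j in subset))
    return best


class TestMST:
    def test_three_node_enumeration(self):
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        tree = autocm.mst(d)
        assert sorted((i, j) for i, j, _ in tree) == [(0, 1), (0, 2)]
        assert sum(w for *_, w in tree) == pytest.approx(0.3)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        tree = autocm.mst(d)
        assert len(tree) == n - 1
        assert sum(w for *_, w in tree) == pytest.approx(_brute_force_mst_total(d), rel=1e-12)

    def test_equal_distances_tie_break_is_stable(self):
        d = np.ones((5, 5)) - np.eye(5)
        names = ["n4", "n3", "n2", "n1", "n0"]
        t1 = autocm.mst(d, node_names=names)
        t2 = autocm.mst(d.copy(), node_names=list(names))
        assert t1 == t2
        # lexicographically smallest pairs win: everything attaches to "n0" (index 4)
        assert all(4 in (i, j) for i, j, _ in t1)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            autocm.mst(d)


class TestBuildConnectivityMap:
    def test_two_variable_map(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.random(40), "y": rng.random(40)})
        cmap = autocm.build_connectivity_map(df, ["x", "y"])
        assert len(cmap.node_names) == 4
        assert len(cmap.mst_edges) == 3
        assert all(0 <= s <= 1 for *_, s in cmap.mst_edges)

    def test_duplicated_variable_nodes_are_mst_adjacent(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.random((60, 3)), columns=["x", "a", "b"])
        df["x_dup"] = df["x"]
        cmap = autocm.build_connectivity_map(df, ["x", "x_dup", "a", "b"])
        adj = {frozenset((u, v)) for u, v, _ in cmap.mst_edges}
        assert frozenset(("x high", "x_dup high")) in adj

    def test_planted_pair_beats_median_strength(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((500, 2))
        df = pd.DataFrame(
            {
                "a": z[:, 0],
                "b": 0.95 * z[:, 0] + np.sqrt(1 - 0.95**2) * z[:, 1],
                **{f"noise{i}": rng.standard_normal(500) for i in range(4)},
            }
        )
        cmap = autocm.build_connectivity_map(df, list(df.columns))
        s = cmap.strengths.copy()
        np.fill_diagonal(s, np.nan)
        ia = cmap.node_names.index("a high")
        ib = cmap.node_names.index("b high")
        assert s[ia, ib] > np.nanmedian(s)
        # complement coherence: the low-low link tracks the high-high link
        il_a = cmap.node_names.index("a low")
        il_b = cmap.node_names.index("b low")
        assert abs(s[ia, ib] - s[il_a, il_b]) < 0.01

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.random(20), "y": rng.random(20)})
        df.loc[:17, "y"] = np.nan  # rows 18, 19 remain complete
        with pytest.warns(UserWarning, match="dropped 18"):
            cmap = autocm.build_connectivity_map(df, ["x", "y"])
        assert len(cmap.mst_edges) == 3
        # with only one complete row left, the map is rejected
        df.loc[19, "x"] = np.nan
        with pytest.raises(ValueError, match="usable rows"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                autocm.build_connectivity_map(df, ["x", "y"])

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            autocm.build_connectivity_map(pd.DataFrame({"x": [1.0, 2.0]}), ["x", "zz"])


class TestExports:
    def test_graphml_dot_and_edges(self, tmp_path):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.random((30, 3)), columns=["a", "b", "c"])
        cmap = autocm.build_connectivity_map(df, ["a", "b", "c"])
        g = autocm.to_networkx(cmap)
        assert g.number_of_nodes() == 6 and g.number_of_edges() == 5
        assert set(nx_forms := {d["form"] for _, d in g.nodes(data=True)}) <= {"high", "low"}
        autocm.export_graphml(cmap, str(tmp_path / "m.graphml"))
        autocm.export_dot(cmap, str(tmp_path / "m.dot"))
        import networkx as nx

        g2 = nx.read_graphml(tmp_path / "m.graphml")
        assert g2.number_of_edges() == 5
        dot = (tmp_path / "m.dot").read_text()
        assert dot.startswith("graph") and dot.count("--") == 5
        edges = autocm.edges_frame(cmap)
        assert list(edges.columns) == ["node_a", "node_b", "strength"]
        assert edges.strength.between(0, 1).all()
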