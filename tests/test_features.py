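"""Metric derivation against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from ectpredict.features import (
    AtlasLabels,
    NodeSet,
    VoxelMap,
    build_strength_blocks,
    cbf_simple_subtraction,
    connectivity_strength,
    falff_map,
    graph_node_metrics,
    kendalls_w,
    reho_map,
    roi_average,
    threshold_weights,
)

# --- oracles -----------------------------------------------------------


def oracle_kendalls_w(series):
    """Direct rank-sum computation of Kendall's W (midranks)."""
    k, n = series.shape
    ranks = np.empty_like(series, dtype=float)
    for i in range(k):
        order = np.argsort(series[i], kind="stable")
        r = np.empty(n)
        r[order] = np.arange(1, n + 1)
        # midranks for ties
        for v in np.unique(series[i]):
            tie = series[i] == v
            r[tie] = r[tie].mean()
        ranks[i] = r
    rank_sums = ranks.sum(axis=0)
    s = sum((rs - rank_sums.mean()) ** 2 for rs in rank_sums)
    return 12.0 * s / (k**2 * (n**3 - n))


def oracle_dft_falff(x, tr, lo=0.01, hi=0.1):
    """FFT-free discrete-Fourier summation after manual detrending."""
    n = len(x)
    t = np.arange(n)
    slope, intercept = np.polyfit(t, x, 1)
    x = x - (slope * t + intercept)
    amps, freqs = [], []
    for m in range(n // 2 + 1):
        coef = sum(x[j] * np.exp(-2j * np.pi * m * j / n) for j in range(n))
        amps.append(abs(coef))
        freqs.append(m / (n * tr))
    amps, freqs = np.array(amps), np.array(freqs)
    pos = freqs > 0
    band = pos & (freqs >= lo) & (freqs <= hi)
    return amps[band].sum() / amps[pos].sum()


def oracle_pearson(a, b):
    """Covariance-formula Pearson correlation."""
    am, bm = a - np.mean(a), b - np.mean(b)
    return np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))


def oracle_dijkstra(lengths, source):
    """Plain-python Dijkstra over a dense length matrix."""
    n = lengths.shape[0]
    dist = {source: 0.0}
    visited = set()
    while len(visited) < n:
        candidates = {v: d for v, d in dist.items() if v not in visited}
        if not candidates:
            break
        u = min(candidates, key=candidates.get)
        visited.add(u)
        for v in range(n):
            if np.isfinite(lengths[u, v]) and lengths[u, v] > 0:
                nd = dist[u] + lengths[u, v]
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
    return dist


def oracle_graph_metrics(w):
    """Triangle enumeration + Dijkstra over 1/w lengths."""
    n = w.shape[0]
    strength = w.sum(axis=1)
    wmax = w.max()
    w_hat = w / wmax if wmax > 0 else w
    clustering = np.zeros(n)
    local_eff = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if w[i, j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        tri = 0.0
        for j, h in itertools.permutations(neigh, 2):
            tri += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        clustering[i] = tri / (k * (k - 1))
        sub = w[np.ix_(neigh, neigh)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, np.inf)
        eff = 0.0
        for a_ix, j in enumerate(neigh):
            dist = oracle_dijkstra(lengths, a_ix)
            for b_ix, h in enumerate(neigh):
                if a_ix == b_ix:
                    continue
                d = dist.get(b_ix, np.inf)
                if np.isfinite(d) and d > 0:
                    eff += (w[i, j] * w[i, h] / d) ** (1 / 3)
        local_eff[i] = eff / (k * (k - 1))
    return strength, clustering, local_eff


# --- CBF ---------------------------------------------------------------


class TestCbfSubtraction:
    def test_control_equals_label_gives_zero_map(self, rng):
        vol = rng.normal(size=(4, 4, 2))
        series = np.stack([vol] * 8, axis=-1)
        tags = ["label", "control"] * 4
        out = cbf_simple_subtraction(series, tags)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_constant_difference_recovered(self, rng):
        base = rng.normal(size=(3, 3, 2))
        vols = []
        tags = []
        for _ in range(30):
            vols += [base, base + 5.0]
            tags += ["label", "control"]
        out = cbf_simple_subtraction(np.stack(vols, axis=-1), tags)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-12)

    def test_random_series_matches_pairwise_loop_oracle(self, rng):
        series = rng.normal(size=(3, 2, 2, 8))
        tags = ["label", "control"] * 4
        out = cbf_simple_subtraction(series, tags)
        expected = np.zeros((3, 2, 2))
        for p in range(4):
            expected += series[..., 2 * p + 1] - series[..., 2 * p]
        np.testing.assert_allclose(out.values, expected / 4, atol=1e-10)

    def test_unbalanced_tags_rejected(self, rng):
        series = rng.normal(size=(2, 2, 2, 3))
        with pytest.raises(ValueError, match="unbalanced"):
            cbf_simple_subtraction(series, ["label", "label", "control"])


# --- ReHo --------------------------------------------------------------


class TestKendallsW:
    def test_identical_nonconstant_series_give_unity(self, rng):
        x = rng.normal(size=12)
        series = np.stack([x, x, x])
        assert kendalls_w(series) == pytest.approx(1.0, abs=1e-12)

    def test_reverse_ranked_pair_matches_rank_sum_oracle(self):
        series = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert kendalls_w(series) == pytest.approx(oracle_kendalls_w(series), abs=1e-12)
        assert kendalls_w(series) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_series_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        series = rng.normal(size=(3, 4))
        assert kendalls_w(series) == pytest.approx(oracle_kendalls_w(series), abs=1e-10)

    def test_ties_handled_with_midranks(self):
        series = np.array([[1.0, 1.0, 2.0, 3.0], [2.0, 2.0, 2.0, 5.0]])
        assert kendalls_w(series) == pytest.approx(oracle_kendalls_w(series), abs=1e-10)

    def test_fully_constant_neighborhood_is_masked(self):
        series = np.ones((3, 5))
        assert np.isnan(kendalls_w(series))

    @pytest.mark.parametrize("seed", range(3))
    def test_w_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        w = kendalls_w(rng.normal(size=(5, 8)))
        assert 0.0 <= w <= 1.0


class TestRehoMap:
    def test_matches_per_voxel_oracle_on_tiny_volume(self, rng):
        bold = rng.normal(size=(4, 3, 3, 6))
        out = reho_map(bold, neighborhood_size=27)
        nx, ny, nz, _ = bold.shape
        for x, y, z in [(0, 0, 0), (1, 1, 1), (3, 2, 2), (2, 0, 1)]:
            neigh = [
                bold[x + dx, y + dy, z + dz]
                for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3)
                if 0 <= x + dx < nx and 0 <= y + dy < ny and 0 <= z + dz < nz
            ]
            expected = oracle_kendalls_w(np.stack(neigh))
            assert out.values[x, y, z] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("size,count", [(7, 7), (19, 19), (27, 27)])
    def test_interior_neighborhood_sizes(self, size, count, rng):
        # implied by the offsets table; checked through the oracle at center
        bold = rng.normal(size=(3, 3, 3, 5))
        out = reho_map(bold, neighborhood_size=size)
        offsets = [
            o for o in itertools.product((-1, 0, 1), repeat=3)
            if abs(o[0]) + abs(o[1]) + abs(o[2]) <= {7: 1, 19: 2, 27: 3}[size]
        ]
        assert len(offsets) == count
        neigh = np.stack([bold[1 + dx, 1 + dy, 1 + dz] for dx, dy, dz in offsets])
        assert out.values[1, 1, 1] == pytest.approx(oracle_kendalls_w(neigh), abs=1e-10)


# --- fALFF -------------------------------------------------------------


class TestFalff:
    def test_pure_in_band_sinusoid_is_one(self):
        # bin-aligned ~0.0506 Hz avoids spectral leakage into the tails
        t = np.arange(178) * 2.0
        x = np.sin(2 * np.pi * (18 / 356) * t)
        out = falff_map(x.reshape(1, 1, 1, -1), tr_seconds=2.0)
        # detrending spreads a little amplitude into the sub-0.01 Hz bins
        assert out.values[0, 0, 0] > 0.9

    def test_pure_out_of_band_sinusoid_is_near_zero(self):
        t = np.arange(178) * 2.0
        x = np.sin(2 * np.pi * (71 / 356) * t)  # ~0.199 Hz
        out = falff_map(x.reshape(1, 1, 1, -1), tr_seconds=2.0)
        assert out.values[0, 0, 0] < 0.05

    @pytest.mark.parametrize("seed", range(3))
    def test_mixture_matches_direct_dft_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(64) * 2.0
        x = (np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.2 * t)
             + 0.3 * rng.normal(size=64))
        out = falff_map(x.reshape(1, 1, 1, -1), tr_seconds=2.0)
        assert out.values[0, 0, 0] == pytest.approx(
            oracle_dft_falff(x, 2.0), abs=1e-8)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            falff_map(np.zeros((1, 1, 1, 32)), tr_seconds=2.0, band=(0.01, 0.3))

    def test_zero_power_masked(self):
        out = falff_map(np.zeros((1, 1, 1, 32)), tr_seconds=2.0)
        assert np.isnan(out.values[0, 0, 0])


# --- ROI averaging -----------------------------------------------------


class TestRoiAverage:
    def test_constant_map(self):
        labels = np.array([[[1, 1], [2, 2]]])
        out = roi_average(VoxelMap(np.full((1, 2, 2), 3.5)), AtlasLabels(labels))
        assert out[1] == out[2] == 3.5

    def test_toy_two_roi_means(self):
        labels = np.array([[[1, 1], [1, 2]]])
        vals = np.array([[[1.0, 3.0], [2.0, 5.0]]])
        out = roi_average(VoxelMap(vals), AtlasLabels(labels))
        assert out[1] == pytest.approx(2.0)
        assert out[2] == pytest.approx(5.0)

    def test_matches_voxel_loop_oracle(self, rng):
        labels = rng.integers(0, 4, size=(5, 5, 5))
        vals = rng.normal(size=(5, 5, 5))
        out = roi_average(VoxelMap(vals), AtlasLabels(labels))
        for roi in (1, 2, 3):
            acc, cnt = 0.0, 0
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        if labels[i, j, k] == roi:
                            acc += vals[i, j, k]
                            cnt += 1
            assert out[roi] == pytest.approx(acc / cnt, abs=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            roi_average(VoxelMap(np.zeros((2, 2, 2))), AtlasLabels(np.zeros((3, 3, 3), dtype=int)))


# --- connectivity strength --------------------------------------------


class TestConnectivityStrength:
    def test_self_correlation_is_one(self, rng):
        a = rng.normal(size=10)
        assert connectivity_strength(a, a) == pytest.approx(1.0)

    def test_negated_series_is_minus_one(self, rng):
        a = rng.normal(size=10)
        assert connectivity_strength(a, -a) == pytest.approx(-1.0)

    def test_fixed_series_match_covariance_oracle(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        assert connectivity_strength(a, b) == pytest.approx(oracle_pearson(a, b), abs=1e-12)

    def test_constant_input_masked_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(connectivity_strength(np.ones(5), np.arange(5.0)))


class TestStrengthBlocks:
    def test_three_nodes_give_three_pairs(self, rng):
        ns = NodeSet(rng.normal(size=(20, 3)), rng.normal(size=(20, 2)))
        rr, rn, nn = build_strength_blocks(ns)
        assert len(rr.feature_names) == 3  # C(3,2)
        assert len(rn.feature_names) == 6
        assert len(nn.feature_names) == 1
        # values match the double loop
        for name, val in zip(rr.feature_names, rr.values[0]):
            i, j = int(name.split(":")[1].split("-")[0][1:]), int(name.split("-")[1][1:])
            expected = oracle_pearson(ns.roi_timecourses[:, i - 1],
                                      ns.roi_timecourses[:, j - 1])
            assert val == pytest.approx(expected, abs=1e-10)

    def test_rsn_pair_census_for_31_networks(self, rng):
        ns = NodeSet(rng.normal(size=(10, 2)), rng.normal(size=(10, 31)))
        _, _, nn = build_strength_blocks(ns)
        assert len(nn.feature_names) == 465  # C(31,2)

    def test_degenerate_node_masks_its_features(self, rng):
        roi = rng.normal(size=(15, 3))
        roi[:, 1] = 2.0
        ns = NodeSet(roi, rng.normal(size=(15, 2)))
        rr, _, _ = build_strength_blocks(ns)
        vals = dict(zip(rr.feature_names, rr.values[0]))
        assert np.isnan(vals["strength:R001-R002"])
        assert np.isfinite(vals["strength:R001-R003"])


# --- graph metrics -----------------------------------------------------


class TestGraphMetrics:
    def test_complete_unit_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        m = graph_node_metrics(threshold_weights(w, proportion=1.0))
        np.testing.assert_allclose(m["strength"], 2.0)
        np.testing.assert_allclose(m["clustering"], 1.0)
        np.testing.assert_allclose(m["local_efficiency"], 1.0)

    def test_path_graph_middle_node_has_zero_clustering(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[1, 2] = w[2, 1] = 0.6
        from ectpredict.features import WeightMatrix
        m = graph_node_metrics(WeightMatrix(w, {"name": "none"}))
        assert m.loc[1, "clustering"] == 0.0
        assert m.loc[0, "clustering"] == 0.0  # degree 1

    @pytest.mark.parametrize("seed", range(4))
    def test_random_weighted_graphs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        w = rng.uniform(0, 1, size=(n, n))
        w = (w + w.T) / 2
        w[rng.uniform(size=(n, n)) < 0.3] = 0.0
        w = np.triu(w, 1) + np.triu(w, 1).T
        from ectpredict.features import WeightMatrix
        m = graph_node_metrics(WeightMatrix(w, {"name": "none"}))
        s, c, e = oracle_graph_metrics(w)
        np.testing.assert_allclose(m["strength"], s, atol=1e-10)
        np.testing.assert_allclose(m["clustering"], c, atol=1e-10)
        np.testing.assert_allclose(m["local_efficiency"], e, atol=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_clustering_agrees_with_networkx_onnela(self, seed):
        import networkx as nx
        rng = np.random.default_rng(seed)
        n = 7
        w = rng.uniform(0, 1, size=(n, n))
        w = np.triu((w + w.T) / 2, 1)
        w[rng.uniform(size=w.shape) < 0.3] = 0.0
        w = w + w.T
        from ectpredict.features import WeightMatrix
        m = graph_node_metrics(WeightMatrix(w, {"name": "none"}))
        g = nx.from_numpy_array(w)
        ref = nx.clustering(g, weight="weight")
        np.testing.assert_allclose(
            m["clustering"], [ref[i] for i in range(n)], atol=1e-10)

    def test_permutation_equivariance(self, rng):
        n = 7
        w = rng.uniform(0, 1, size=(n, n))
        w = np.triu((w + w.T) / 2, 1)
        w = w + w.T
        from ectpredict.features import WeightMatrix
        base = graph_node_metrics(WeightMatrix(w, {"name": "none"}))
        perm = rng.permutation(n)
        permuted = graph_node_metrics(WeightMatrix(w[np.ix_(perm, perm)], {"name": "none"}))
        for col in ("strength", "clustering", "local_efficiency"):
            np.testing.assert_allclose(
                permuted[col].to_numpy(), base[col].to_numpy()[perm], atol=1e-12)

    def test_metrics_bounded_for_unit_weights(self, rng):
        w = rng.uniform(0, 1, size=(8, 8))
        w = np.triu((w + w.T) / 2, 1)
        w = w + w.T
        m = graph_node_metrics(threshold_weights(w, proportion=0.4))
        assert ((m["clustering"] >= 0) & (m["clustering"] <= 1)).all()
        assert ((m["local_efficiency"] >= 0) & (m["local_efficiency"] <= 1)).all()


class TestThresholdWeights:
    def test_keeps_strongest_proportion_and_drops_negatives(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(-1, 1, size=(10, 10))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        wm = threshold_weights(c, proportion=0.25)
        iu = np.triu_indices(10, k=1)
        n_edges = (wm.weights[iu] > 0).sum()
        assert n_edges == round(0.25 * len(iu[0]))
        assert wm.weights.min() >= 0
        np.testing.assert_array_equal(wm.weights, wm.weights.T)
        assert wm.threshold_policy["proportion"] == 0.25

    def test_retained_weights_unchanged(self):
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.9
        c[2, 3] = c[3, 2] = 0.4
        c[0, 2] = c[2, 0] = 0.2
        wm = threshold_weights(c, proportion=0.34)
        assert wm.weights[0, 1] == 0.9
        assert wm.weights[2, 3] == 0.4
        assert wm.weights[0, 2] == 0.0
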