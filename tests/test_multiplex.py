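import numpy as np
import pandas as pd
import pytest

from colonynet import multiplex
from colonynet.multiplex import (
    build_multiplex,
    interlayer_r2_network,
    random_intercept_fit,
    reduce_layer,
    select_expression_pc,
    similarity_layer,
    upper_quartile_edges,
)


class TestSimilarityLayer:
    def test_identical_profiles_zero_distance(self):
        p = pd.DataFrame([[1.0, 2.0]] * 3, index=list("abc"))
        d = similarity_layer(p)
        assert np.allclose(d, 0.0)

    def test_hand_pythagoras(self):
        p = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=list("ab"))
        assert similarity_layer(p).loc["a", "b"] == pytest.approx(5.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"))
        d = similarity_layer(p)
        perm = list("cabed")
        d2 = similarity_layer(p.loc[perm])
        pd.testing.assert_frame_equal(d2, d.loc[perm, perm])

    def test_missing_values_rejected(self):
        p = pd.DataFrame([[1.0, np.nan]], index=["a"])
        with pytest.raises(ValueError):
            similarity_layer(p)


def toy_weights(values):
    """4-node symmetric matrix with off-diagonal weights taken from
    ``values`` in upper-triangle order."""
    W = np.zeros((4, 4))
    W[np.triu_indices(4, 1)] = values
    W = W + W.T
    return pd.DataFrame(W, index=list("abcd"), columns=list("abcd"))


class TestUpperQuartileEdges:
    def test_interaction_threshold_hand_case(self):
        """Weights {1..6}: 75th percentile (linear interpolation) is 4.75,
        strictly exceeded by weights 5 and 6."""
        edges = upper_quartile_edges(toy_weights([1, 2, 3, 4, 5, 6]), "interaction")
        assert len(edges) == 2

    def test_distance_threshold_hand_case(self):
        """Distances {1..6}: 25th percentile is 2.25; pairs at 1 and 2 qualify."""
        edges = upper_quartile_edges(toy_weights([1, 2, 3, 4, 5, 6]), "distance")
        assert len(edges) == 2

    def test_all_equal_gives_empty_set(self):
        with pytest.warns(UserWarning, match="equal"):
            edges = upper_quartile_edges(toy_weights([3] * 6), "interaction")
        assert edges == []

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            upper_quartile_edges(toy_weights([1, 2, 3, 4, 5, 6]), "other")


class TestBuildMultiplex:
    def _layers(self, n=6):
        rng = np.random.default_rng(0)
        ids = [f"w{i}" for i in range(n)]
        layers = {}
        for name in multiplex.LAYER_ORDER:
            W = rng.random((n, n))
            W = W + W.T
            np.fill_diagonal(W, 0.0)
            layers[name] = pd.DataFrame(W, index=ids, columns=ids)
        return layers

    def test_interlayer_coupling_count(self):
        net = build_multiplex(self._layers())
        assert net.n_interlayer_edges == 4 * 6

    def test_layer_order(self):
        net = build_multiplex(self._layers())
        assert net.layer_names == multiplex.LAYER_ORDER

    def test_worker_mismatch_rejected(self):
        layers = self._layers()
        layers["behavior"] = layers["behavior"].iloc[:4, :4]
        with pytest.raises(ValueError, match="mismatch"):
            build_multiplex(layers)

    def test_flattened_graph_node_count(self):
        net = build_multiplex(self._layers())
        g = net.to_networkx()
        assert g.number_of_nodes() == 5 * 6


class TestReduceLayer:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=20)
        axis = np.array([3.0, -1.0, 2.0])
        profiles = pd.DataFrame(np.outer(t, axis))
        score = reduce_layer(profiles, 1)
        r = np.corrcoef(score, t)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=30)
        profiles = pd.DataFrame(np.outer(t, [1.0, 2.0]) + rng.normal(0, 0.01, (30, 2)))
        ref = pd.Series(-t, index=profiles.index)
        score = reduce_layer(profiles, 1, orient_to=ref)
        assert np.corrcoef(score, ref)[0, 1] > 0

    def test_closed_form_two_dimensional_projection(self):
        """Scores match projection onto the hand-computed leading eigenvector
        of a 2x2 covariance."""
        X = np.array([[2.0, 1.0], [-2.0, -1.0], [4.0, 2.0], [-4.0, -2.0]])
        profiles = pd.DataFrame(X)
        score = reduce_layer(profiles, 1)
        v = np.array([2.0, 1.0]) / np.sqrt(5.0)  # exact leading eigenvector
        expected = X @ v
        assert np.allclose(np.abs(score), np.abs(expected))

    def test_pc_index_beyond_rank_rejected(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError):
            reduce_layer(profiles, 4)


class TestSelectExpressionPC:
    def _pcs(self, batch_strength, bio_strength, seed=0, n=60):
        rng = np.random.default_rng(seed)
        batch = pd.Series(rng.integers(0, 3, n).astype(str))
        bio = pd.Series(rng.normal(size=n))
        shifts = {b: rng.normal(scale=batch_strength) for b in batch.unique()}
        pc1 = batch.map(shifts).astype(float) + rng.normal(0, 0.3, n)
        pc2 = bio_strength * bio + rng.normal(0, 0.3, n)
        pcs = pd.DataFrame({"PC1": pc1, "PC2": pc2})
        return pcs, batch, pd.DataFrame({"bio": bio})

    def test_batch_dominant_recommends_pc2(self):
        pcs, batch, bio = self._pcs(batch_strength=5.0, bio_strength=3.0)
        chosen, table = select_expression_pc(pcs, batch, bio)
        assert chosen == 2
        assert table.loc[1, "batch_r2"] > table.loc[1, "r2_bio"]

    def test_no_batch_effect_recommends_pc1(self):
        rng = np.random.default_rng(1)
        bio = pd.Series(rng.normal(size=60))
        pcs = pd.DataFrame(
            {"PC1": 3 * bio + rng.normal(0, 0.3, 60), "PC2": rng.normal(size=60)}
        )
        batch = pd.Series(rng.integers(0, 3, 60).astype(str))
        chosen, _ = select_expression_pc(pcs, batch, pd.DataFrame({"bio": bio}))
        assert chosen == 1

    def test_single_batch_treated_as_zero(self):
        rng = np.random.default_rng(2)
        bio = pd.Series(rng.normal(size=40))
        pcs = pd.DataFrame({"PC1": bio + rng.normal(0, 0.5, 40)})
        batch = pd.Series(["b1"] * 40)
        chosen, table = select_expression_pc(pcs, batch, pd.DataFrame({"bio": bio}))
        assert chosen == 1
        assert table.loc[1, "batch_r2"] == 0.0

    def test_fallback_to_pc1_with_warning(self):
        rng = np.random.default_rng(3)
        batch = pd.Series(rng.integers(0, 2, 40).astype(str))
        pcs = pd.DataFrame({"PC1": batch.map({"0": -1.0, "1": 1.0}) + rng.normal(0, 0.1, 40)})
        bio = pd.DataFrame({"bio": rng.normal(size=40) * 1e-9})
        with pytest.warns(UserWarning, match="batch"):
            chosen, _ = select_expression_pc(pcs, batch, bio)
        assert chosen == 1


class TestInterlayerR2:
    def test_exact_linear_relation(self):
        x = pd.Series(np.arange(10.0))
        scores = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.random.default_rng(0).normal(size=10)})
        net = interlayer_r2_network(scores)
        assert net.mean.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        net = interlayer_r2_network(scores)
        M = net.mean.to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert ((M >= 0) & (M <= 1)).all()

    def test_hand_pearson_value(self):
        scores = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 2, 4]})
        net = interlayer_r2_network(scores)
        assert net.mean.loc["x", "y"] == pytest.approx(0.853, abs=0.001)

    def test_constant_variable_zeroed_with_warning(self):
        scores = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            net = interlayer_r2_network(scores)
        assert net.mean.loc["x", "y"] == 0.0

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        net1 = interlayer_r2_network(scores)
        scores2 = scores.copy()
        scores2["b"] = -3.0 * scores2["b"] + 7.0
        net2 = interlayer_r2_network(scores2)
        pd.testing.assert_frame_equal(net1.mean, net2.mean)

    def test_across_colony_average_and_hub(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=40)
        scores = pd.DataFrame(
            {
                "a": t + rng.normal(0, 0.1, 40),
                "b": t + rng.normal(0, 0.8, 40),
                "c": t + rng.normal(0, 0.8, 40),
            }
        )
        colony = pd.Series(["c1"] * 20 + ["c2"] * 20, index=scores.index)
        net = interlayer_r2_network(scores, colony)
        assert set(net.per_colony) == {"c1", "c2"}
        expected = (net.per_colony["c1"] + net.per_colony["c2"]) / 2
        pd.testing.assert_frame_equal(net.mean, expected)
        assert net.hub == "a"


class TestRandomInterceptFit:
    def test_single_group_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 2.0 * x + rng.normal(0, 0.5, 50)
        fit = random_intercept_fit(x, y, np.zeros(50))
        from scipy import stats

        ols = stats.linregress(x, y)
        assert fit["slope"] == pytest.approx(ols.slope)
        assert fit["t"] == pytest.approx(ols.slope / ols.stderr)

    def test_no_group_variance_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(0, 1.0, 200)
        groups = np.repeat(list("abcd"), 50)
        fit = random_intercept_fit(x, y, groups)
        assert fit["sigma_group"] < 0.3

    def test_slope_recovery_over_simulations(self):
        """Mean estimated slope across 200 simulated datasets (4 groups x 50,
        true slope 0.5) is within +-0.05 of the truth."""
        rng = np.random.default_rng(2)
        slopes = []
        for _ in range(200):
            groups = np.repeat(list("abcd"), 50)
            u = dict(zip("abcd", rng.normal(0, 0.5, 4)))
            x = rng.normal(size=200)
            y = 0.5 * x + np.array([u[g] for g in groups]) + rng.normal(0, 0.7, 200)
            slopes.append(random_intercept_fit(x, y, groups)["slope"])
        assert np.mean(slopes) == pytest.approx(0.5, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            random_intercept_fit([1.0, np.nan], [0.0, 1.0], ["a", "a"])
        with pytest.raises(ValueError):
            random_intercept_fit([1.0, 1.0], [0.0, 1.0], ["a", "a"])
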