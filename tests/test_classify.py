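import numpy as np
import pandas as pd
import pytest

from somportrait import (
    bootstrap_stability,
    correlation_network,
    discover_classes,
    portrait_correlation_matrix,
    silhouette_scores,
)

from _oracles import pearson_oracle, silhouette_oracle
from conftest import make_model


def block_model(n_per_block=6, grid=(5, 5), noise=0.01, seed=0, n_blocks=2):
    """Samples form tight blocks of near-identical portraits."""
    rows, cols_ = grid
    n_nodes = rows * cols_
    rng = np.random.default_rng(seed)
    prototypes = rng.normal(size=(n_blocks, n_nodes)) * 2
    cols, labels = [], []
    for b in range(n_blocks):
        for _ in range(n_per_block):
            cols.append(prototypes[b] + rng.normal(scale=noise, size=n_nodes))
            labels.append(b)
    cb = np.column_stack(cols)
    return make_model(cb, rows, cols_), np.array(labels)


class TestCorrelationMatrix:
    def test_unit_diagonal_symmetry_and_negation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=9)
        cb = np.column_stack([base, -base, rng.normal(size=9)])
        model = make_model(cb, 3, 3)
        r = portrait_correlation_matrix(model)
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T)
        assert r.loc["s0", "s1"] == pytest.approx(-1.0)
        assert (r.to_numpy() >= -1).all() and (r.to_numpy() <= 1).all()

    def test_matches_hand_pearson_on_three_samples(self):
        cb = np.array([[1.0, 2, 1], [2, 1, 4], [3, 5, 2], [0, 1, 1]])
        model = make_model(cb, 2, 2)
        r = portrait_correlation_matrix(model)
        for i in range(3):
            for j in range(3):
                assert r.iloc[i, j] == pytest.approx(
                    pearson_oracle(cb[:, i], cb[:, j]), abs=1e-12
                )


class TestDiscoverClasses:
    def test_two_blocks_perfectly_partitioned_with_positive_s(self):
        model, truth = block_model()
        r = portrait_correlation_matrix(model)
        asg = discover_classes(r, model, k=2, seed=0)
        lab = asg.labels.to_numpy()
        assert (lab[truth == 0] == lab[truth == 0][0]).all()
        assert (lab[truth == 1] == lab[truth == 1][0]).all()
        assert lab[0] != lab[-1]
        assert (asg.silhouette > 0).all()

    def test_k_equal_to_sample_count_is_stable_singletons(self):
        rng = np.random.default_rng(1)
        cb = rng.normal(size=(16, 5))
        model = make_model(cb, 4, 4)
        r = portrait_correlation_matrix(model)
        asg = discover_classes(r, model, k=5, seed=0)
        assert sorted(asg.labels.unique()) == [0, 1, 2, 3, 4]
        # singleton centroids are the samples themselves; S is the gap to
        # the nearest other sample
        for i, sid in enumerate(asg.labels.index):
            own = 1.0
            others = [
                pearson_oracle(cb[:, i], cb[:, j]) for j in range(5) if j != i
            ]
            assert asg.silhouette[sid] == pytest.approx(own - max(others), abs=1e-9)

    def test_invalid_k_rejected(self):
        model, _ = block_model()
        r = portrait_correlation_matrix(model)
        with pytest.raises(ValueError):
            discover_classes(r, model, k=1)
        with pytest.raises(ValueError):
            discover_classes(r, model, k=len(r) + 1)

    def test_deterministic_given_seed(self):
        model, _ = block_model(noise=0.5, seed=3)
        r = portrait_correlation_matrix(model)
        a = discover_classes(r, model, k=3, seed=11)
        b = discover_classes(r, model, k=3, seed=11)
        pd.testing.assert_series_equal(a.labels, b.labels)
        pd.testing.assert_series_equal(a.silhouette, b.silhouette)

    def test_refinement_mean_s_monotone_and_terminates_on_fuzzed_instances(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(12, 60))
            cb = rng.normal(size=(16, n))
            # add a little structure so clusters are not pure noise
            cb[:, : n // 2] += rng.normal(size=(16, 1))
            model = make_model(cb, 4, 4)
            r = portrait_correlation_matrix(model)
            k = int(rng.integers(2, 6))
            asg = discover_classes(r, model, k=k, seed=seed)
            assert asg.iterations <= 100
            trace = np.array(asg.mean_s_trace)
            assert (np.diff(trace) >= -1e-12).all()
            # every class non-empty
            assert len(asg.labels.unique()) == k


class TestSilhouette:
    def test_boundary_and_perfect_fit_values(self):
        # two classes; one sample equally correlated with both centroids
        own = np.array([1.0, 0, 1, 0, 1, 0, 1, 0, 1])
        other = np.array([0.0, 1, 0, 1, 0, 1, 0, 1, 0])
        both = own + other
        cb = np.column_stack([own, own, other, other, both])
        model = make_model(cb, 3, 3)
        labels = pd.Series([0, 0, 1, 1, 0], index=model.sample_ids)
        cents = np.vstack([own, other])
        s = silhouette_scores(model, labels, centroids=cents)
        # sample identical to its centroid and negatively correlated with
        # the other centroid scores near 1 - (-1) = 2 bounded by construction
        assert s["s0"] == pytest.approx(1 - pearson_oracle(own, other))
        # the ambiguous sample is equally correlated with both centroids
        assert s["s4"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_toy(self):
        rng = np.random.default_rng(4)
        cb = rng.normal(size=(9, 8))
        model = make_model(cb, 3, 3)
        labels = np.array([0, 0, 0, 1, 1, 0, 1, 1])
        s = silhouette_scores(model, pd.Series(labels, index=model.sample_ids))
        expected = silhouette_oracle(cb.T, labels)
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-12)

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(5)
        cb = rng.normal(size=(9, 10))
        model = make_model(cb, 3, 3)
        labels = pd.Series([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], index=model.sample_ids)
        permuted = labels.map({0: 2, 1: 0, 2: 1})
        np.testing.assert_allclose(
            silhouette_scores(model, labels).to_numpy(),
            silhouette_scores(model, permuted).to_numpy(),
            atol=1e-12,
        )


class TestBootstrapStability:
    def test_separable_blocks_are_fully_stable(self):
        model, _ = block_model(n_per_block=10)
        stab = bootstrap_stability(model, k=2, b=20, seed=0)
        assert stab > 95.0

    def test_noise_is_less_stable_than_structure(self):
        rng = np.random.default_rng(6)
        noise_model = make_model(rng.normal(size=(16, 24)), 4, 4)
        structured, _ = block_model(n_per_block=12, grid=(4, 4), seed=7)
        noise_stab = bootstrap_stability(noise_model, k=2, b=20, seed=1)
        block_stab = bootstrap_stability(structured, k=2, b=20, seed=1)
        assert block_stab > noise_stab + 10.0

    def test_deterministic_given_seed(self):
        model, _ = block_model(noise=0.4, seed=8)
        assert bootstrap_stability(model, k=2, b=10, seed=5) == bootstrap_stability(
            model, k=2, b=10, seed=5
        )

    def test_too_few_replicates_rejected(self):
        model, _ = block_model()
        with pytest.raises(ValueError):
            bootstrap_stability(model, k=2, b=1, seed=0)


class TestCorrelationNetwork:
    def _r(self):
        rng = np.random.default_rng(9)
        cb = rng.normal(size=(9, 4))
        return portrait_correlation_matrix(make_model(cb, 3, 3))

    def test_threshold_extremes(self):
        r = self._r()
        assert correlation_network(r, "threshold", 1.0).number_of_edges() == 0
        full = correlation_network(r, "threshold", -1.0)
        assert full.number_of_edges() == 4 * 3 // 2

    def test_knn_one_matches_hand_ranked_correlations(self):
        r = self._r().iloc[:3, :3]
        g = correlation_network(r, "knn", 1)
        expected_edges = set()
        for i, sid in enumerate(r.index):
            row = r.loc[sid].drop(sid)
            expected_edges.add(frozenset((sid, row.idxmax())))
        assert {frozenset(e) for e in g.edges} == expected_edges

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            correlation_network(self._r(), "banana", 1)
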