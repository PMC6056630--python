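import numpy as np
import pandas as pd
import pytest

import somportrait as sp
from somportrait.spots import SpotSegmentation, segment_spots, sample_spot_activation

from conftest import make_model


def plateau_model():
    """12x12 grid with two disjoint high-variance plateaus.

    Codebook columns are crafted so that the two plateau regions have
    variance 100 across samples while the background stays near zero.
    """
    rows = cols = 12
    n_nodes = rows * cols
    cb = np.zeros((n_nodes, 4))
    plateau1 = [(1, 1), (1, 2), (2, 1), (2, 2)]
    plateau2 = [(8, 8), (8, 9), (9, 8), (9, 9)]
    for r, c in plateau1 + plateau2:
        cb[r * cols + c] = [10, -10, 10, -10]
    # genes: 3 in plateau1, 2 in plateau2, 1 outside
    bmu = np.array([1 * cols + 1, 1 * cols + 2, 2 * cols + 2, 8 * cols + 8, 9 * cols + 9, 0])
    model = make_model(cb, rows, cols, bmu=bmu, gene_ids=list("abcdef"))
    return model, plateau1, plateau2


class TestSegmentation:
    def test_two_plateaus_become_two_spots_with_their_pixels(self):
        model, p1, p2 = plateau_model()
        vmap = sp.variance_map(model)
        seg = segment_spots(model, vmap, percentile=90.0)
        assert len(seg) == 2
        pixel_sets = [set(s.pixels) for s in seg]
        assert set(p1) in pixel_sets and set(p2) in pixel_sets
        by_pixels = {frozenset(s.pixels): set(s.genes) for s in seg}
        assert by_pixels[frozenset(p1)] == {"a", "b", "c"}
        assert by_pixels[frozenset(p2)] == {"d", "e"}

    def test_single_suprathreshold_pixel_is_singleton_spot(self):
        cb = np.zeros((16, 3))
        cb[5] = [5, 0, -5]
        model = make_model(cb, 4, 4, bmu=np.array([5]), gene_ids=["g"])
        seg = segment_spots(model, sp.variance_map(model), percentile=93.0)
        assert len(seg) == 1
        assert seg.spots[0].pixels == [(1, 1)]
        assert seg.spots[0].genes == ["g"]

    def test_invalid_percentile_rejected(self):
        model, _, _ = plateau_model()
        vmap = sp.variance_map(model)
        for bad in (0.0, 100.0, -5.0):
            with pytest.raises(ValueError):
                segment_spots(model, vmap, percentile=bad)

    def test_raising_percentile_never_adds_pixels(self, small_analysis):
        _, m, _, _, model = small_analysis
        vmap = sp.variance_map(model)
        previous = None
        for pct in (60.0, 70.0, 80.0, 90.0, 95.0):
            seg = segment_spots(model, vmap, percentile=pct)
            pixels = set(p for s in seg for p in s.pixels)
            if previous is not None:
                assert pixels <= previous
            previous = pixels

    def test_spots_disjoint_connected_and_genes_inside(self, small_analysis):
        _, m, _, _, model = small_analysis
        vmap = sp.variance_map(model)
        for split in (False, True):
            seg = segment_spots(model, vmap, percentile=75.0, split_umap=split)
            seen = set()
            for s in seg:
                pix = set(s.pixels)
                assert not (pix & seen)
                seen |= pix
                # connectivity under 8-neighborhood: breadth-first flood
                todo, reached = [s.pixels[0]], {s.pixels[0]}
                while todo:
                    r, c = todo.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            q = (r + dr, c + dc)
                            if q in pix and q not in reached:
                                reached.add(q)
                                todo.append(q)
                assert reached == pix
                # every member gene's BMU lies inside the spot
                for g in s.genes:
                    i = model.gene_ids.index(g)
                    rc = np.unravel_index(model.bmu[i], (model.rows, model.cols))
                    assert (int(rc[0]), int(rc[1])) in pix
            all_genes = [g for s in seg for g in s.genes]
            assert len(all_genes) == len(set(all_genes)) <= len(model.gene_ids)

    def test_labels_follow_descending_total_variance(self, small_analysis):
        _, _, _, _, model = small_analysis
        seg = segment_spots(model, sp.variance_map(model), percentile=75.0)
        tv = [s.total_variance for s in seg]
        assert tv == sorted(tv, reverse=True)
        assert seg.labels() == [chr(ord("A") + i) for i in range(len(seg))]

    def test_frame_round_trip(self, small_analysis):
        _, _, _, _, model = small_analysis
        seg = segment_spots(model, sp.variance_map(model), percentile=75.0)
        back = SpotSegmentation.from_frame(seg.to_frame(), model.rows, model.cols)
        assert back.labels() == seg.labels()
        for a, b in zip(seg, back):
            assert a.pixels == b.pixels and a.genes == b.genes


class TestActivation:
    def test_uniform_portrait_activates_nothing(self):
        model, _, _ = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        assert sample_spot_activation(np.ones((12, 12)), seg, q=0.9) == set()

    def test_only_positive_spot_is_active(self):
        model, p1, p2 = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        portrait = np.zeros((12, 12))
        for r, c in p1:
            portrait[r, c] = 3.0
        for r, c in p2:
            portrait[r, c] = -3.0
        label1 = next(s.label for s in seg if set(s.pixels) == set(p1))
        assert sample_spot_activation(portrait, seg, q=0.9) == {label1}

    def test_three_spot_toy_matches_direct_computation(self):
        model, p1, p2 = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        rng = np.random.default_rng(0)
        portrait = rng.normal(scale=0.1, size=(12, 12))
        for r, c in p1:
            portrait[r, c] = 2.0
        for r, c in p2:
            portrait[r, c] = 0.05
        q = 0.9
        cutoff = np.quantile(portrait, q)
        expected = {
            s.label
            for s in seg
            if np.mean([portrait[r, c] for r, c in s.pixels]) > max(cutoff, 0)
        }
        assert sample_spot_activation(portrait, seg, q=q) == expected

    def test_bad_quantile_and_empty_segmentation_rejected(self):
        model, _, _ = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        with pytest.raises(ValueError):
            sample_spot_activation(np.zeros((12, 12)), seg, q=1.5)
        empty = SpotSegmentation(spots=[], rows=12, cols=12, percentile=90.0, split_umap=False)
        with pytest.raises(ValueError):
            sample_spot_activation(np.zeros((12, 12)), empty)


class TestSpotProfiles:
    def test_profile_examples(self):
        model, p1, p2 = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        m = pd.DataFrame(
            [[1.0, 3], [3, 5], [0, 0], [7, 9], [1, 1], [2, 2]],
            index=list("abcdef"),
            columns=["s0", "s1"],
        )
        lab1 = next(s.label for s in seg if set(s.genes) == {"a", "b", "c"})
        lab2 = next(s.label for s in seg if set(s.genes) == {"d", "e"})
        np.testing.assert_allclose(
            sp.spot_expression_profile(seg, lab2, m).to_numpy(), [4.0, 5.0]
        )
        np.testing.assert_allclose(
            sp.spot_expression_profile(seg, lab1, m).to_numpy(),
            m.loc[["a", "b", "c"]].mean(axis=0).to_numpy(),
        )

    def test_random_toys_equal_submatrix_column_means(self, small_analysis):
        _, m, _, _, model = small_analysis
        seg = segment_spots(model, sp.variance_map(model), percentile=75.0)
        for s in seg.spots[:3]:
            if s.genes:
                np.testing.assert_allclose(
                    sp.spot_expression_profile(seg, s.label, m).to_numpy(),
                    m.loc[s.genes].to_numpy().mean(axis=0),
                )


class TestFrequencyDistribution:
    def test_all_uniform_portraits_count_zero_and_histogram_conserves(self):
        model, _, _ = plateau_model()
        seg = segment_spots(model, sp.variance_map(model), percentile=90.0)
        portraits = {f"x{i}": np.full((12, 12), float(i)) for i in range(5)}
        groups = pd.Series(["a", "a", "b", "b", "b"], index=list(portraits))
        counts, hist = sp.spot_frequency_distribution(portraits, seg, q=0.9, groups=groups)
        assert (counts == 0).all()
        assert hist.to_numpy().sum() == 5

    def test_histogram_sums_to_sample_count_on_synthetic(self, small_analysis):
        _, m, ann, _, model = small_analysis
        seg = segment_spots(model, sp.variance_map(model), percentile=75.0)
        portraits = {s: sp.sample_portrait(model, s) for s in model.sample_ids}
        counts, hist = sp.spot_frequency_distribution(
            portraits, seg, q=0.95, groups=ann["group"]
        )
        assert hist.to_numpy().sum() == len(model.sample_ids) == len(counts)
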