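"""Quality-filter tests: k-means against an exhaustive bipartition oracle,
nuclear-cluster selection, mask construction, scoring, and the end-to-end
tile filter on generated slides."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from tileqc import qc, stain, synthetic
from tileqc.exceptions import DegenerateInputError, InvalidArgumentError
from tileqc.qc import (
    ClusterQualityFilter,
    FilterConfig,
    QualityScore,
    build_mask,
    classify_quality,
    filter_tiles,
    kmeans_pixels,
    score_tile,
    select_nuclear_cluster,
)

from conftest import oracle_min_inertia


def paint(palette, idx, shape):
    return np.asarray(palette)[list(idx)].reshape(*shape, 3).astype(np.uint8)


class TestKMeansPixels:
    def test_three_colors_three_clusters_perfect_partition(self):
        palette = [(250, 250, 250), (230, 140, 170), (90, 60, 150)]
        idx = [0, 1, 2] * 12
        img = paint(palette, idx, (6, 6))
        model = kmeans_pixels(img, 3, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-9)
        # assignments constant within each color
        flat = model.assignments.ravel()
        for c in range(3):
            members = flat[np.asarray(idx) == c]
            assert len(set(members.tolist())) == 1

    def test_two_color_images_match_exhaustive_minimum(self):
        """Every two-color pattern up to 2x3 (plus seeded larger ones)
        reaches the brute-force-optimal within-cluster sum of squares."""
        palette = np.array([[30, 40, 200], [220, 120, 150]])
        for h, w in [(1, 4), (2, 2), (2, 3)]:
            for bits in itertools.product([0, 1], repeat=h * w):
                if len(set(bits)) < 2:
                    continue
                img = paint(palette, bits, (h, w))
                model = kmeans_pixels(img, 2, seed=0)
                oracle = oracle_min_inertia(palette[list(bits)])
                assert model.inertia == pytest.approx(oracle, abs=1e-6)

    def test_random_three_color_images_match_oracle_with_restarts(self, rng):
        for _ in range(25):
            palette = rng.integers(0, 256, size=(3, 3))
            idx = rng.integers(0, 3, size=12)
            if len(np.unique(idx)) < 2:
                continue
            img = paint(palette, idx, (3, 4))
            model = kmeans_pixels(img, 2, seed=int(rng.integers(1000)), n_init=10)
            oracle = oracle_min_inertia(palette[idx].astype(float))
            assert model.inertia == pytest.approx(oracle, rel=1e-9, abs=1e-6)

    def test_more_clusters_than_colors_is_degenerate(self):
        img = paint([(0, 0, 0), (255, 255, 255)], [0, 1] * 8, (4, 4))
        with pytest.raises(DegenerateInputError):
            kmeans_pixels(img, 3, seed=0)

    def test_deterministic_given_seed(self, good_tile):
        a = kmeans_pixels(good_tile.image, 3, seed=7)
        b = kmeans_pixels(good_tile.image, 3, seed=7)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.inertia == b.inertia


class TestSelectNuclearCluster:
    def _model(self, centroids):
        cents = np.asarray(centroids, float)
        return qc.ClusterModel(k=len(cents), centroids=cents,
                               assignments=np.zeros((2, 2), int), inertia=0.0,
                               feature_space="original_rgb")

    def test_purple_cluster_wins_over_white_and_pink(self):
        model = self._model([(250, 250, 250), (230, 140, 170), (90, 60, 150)])
        assert select_nuclear_cluster(model) == [2]

    def test_equal_centroids_tie_broken_by_lowest_index(self):
        model = self._model([(100, 100, 100)] * 3)
        assert select_nuclear_cluster(model) == [0]

    def test_darker_purple_shade_wins_at_k4(self):
        model = self._model([(250, 250, 250), (230, 140, 170),
                             (120, 90, 170), (70, 40, 130)])
        assert select_nuclear_cluster(model) == [3]

    def test_min_conc_filters_out_stainless_tiles(self):
        model = self._model([(250, 250, 250), (240, 235, 240), (235, 230, 238)])
        assert select_nuclear_cluster(model, min_conc=0.25) == []


class TestMaskAndScore:
    def test_select_all_clusters_gives_full_mask(self, good_tile):
        model = kmeans_pixels(good_tile.image, 3, seed=0)
        mask = build_mask(model, [0, 1, 2])
        assert mask.all()

    def test_empty_selection_rejected(self, good_tile):
        model = kmeans_pixels(good_tile.image, 3, seed=0)
        with pytest.raises(InvalidArgumentError):
            build_mask(model, [])

    def test_out_of_range_selection_rejected(self, good_tile):
        model = kmeans_pixels(good_tile.image, 3, seed=0)
        with pytest.raises(InvalidArgumentError):
            build_mask(model, [5])

    def test_mask_partitions_pixels(self, good_tile):
        model = kmeans_pixels(good_tile.image, 3, seed=0)
        sel = select_nuclear_cluster(model)
        mask = build_mask(model, sel)
        inverse = build_mask(model, [i for i in range(3) if i not in sel])
        assert (mask ^ inverse).all()

    def test_score_values(self):
        assert score_tile(np.zeros((8, 8), bool)).non_white_fraction == 0.0
        assert score_tile(np.ones((8, 8), bool)).non_white_fraction == 1.0
        mask = np.zeros(256 * 256, bool)
        mask[:6554] = True
        frac = score_tile(mask.reshape(256, 256)).non_white_fraction
        assert frac == pytest.approx(0.1000, abs=1e-4)

    def test_mask_overlaps_generator_nuclei(self, good_tile):
        cfg = FilterConfig()
        feats = qc._tile_features(good_tile.image, cfg)
        model = kmeans_pixels(feats, 3, seed=0)
        mask = build_mask(model, select_nuclear_cluster(model, cfg.stains))
        truth = good_tile.nucleus_mask
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard >= 0.5


class TestClassifyQuality:
    def test_zero_score_is_poor(self):
        assert classify_quality(QualityScore(0.0), 0.05) == "poor"

    def test_boundary_score_is_good(self):
        assert classify_quality(QualityScore(0.05), 0.05) == "good"

    def test_good_count_non_increasing_in_threshold(self, small_slide):
        _, _, records = filter_tiles(small_slide[:20], FilterConfig(seed=0))
        scores = [r.non_white_fraction for r in records]
        counts = [sum(classify_quality(QualityScore(s), tau) == "good" for s in scores)
                  for tau in (0.01, 0.05, 0.1, 0.2, 0.5)]
        assert counts == sorted(counts, reverse=True)


class TestFilterTiles:
    def test_recovers_thirty_percent_poor_mixture(self):
        tiles = synthetic.generate_slide(
            synthetic.SlideSpec(n_tiles=100, fraction_poor=0.3, seed=21))
        good, poor, records = filter_tiles(tiles, FilterConfig(seed=1))
        assert len(poor) / len(records) == pytest.approx(0.30, abs=0.05)

    def test_all_blank_slide_flagged_entirely_poor(self):
        tiles = [synthetic.generate_tile(
            synthetic.TileSpec(artifact="blank", nuclear_density=0, seed=s))
            for s in range(5)]
        good, poor, records = filter_tiles(tiles, FilterConfig(seed=0))
        assert not good and len(poor) == 5
        assert all(r.non_white_fraction == 0.0 and r.reason for r in records)

    @pytest.mark.parametrize("k", [3, 4])
    def test_scores_track_ground_truth_density(self, small_slide, k):
        _, _, records = filter_tiles(small_slide, FilterConfig(k=k, seed=1))
        rho = spearmanr([r.non_white_fraction for r in records],
                        [t.true_nuclear_fraction for t in small_slide]).statistic
        assert rho >= 0.8

    def test_score_monotone_in_density_sweep(self):
        scores = []
        for density in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            tile = synthetic.generate_tile(
                synthetic.TileSpec(nuclear_density=density, seed=42))
            _, _, recs = filter_tiles([tile], FilterConfig(seed=0))
            scores.append(recs[0].non_white_fraction)
        assert scores == sorted(scores)

    def test_filter_is_pure_function_of_inputs(self, small_slide):
        out1 = filter_tiles(small_slide[:10], FilterConfig(seed=5))
        out2 = filter_tiles(small_slide[:10], FilterConfig(seed=5))
        assert out1[2] == out2[2]

    def test_tile_count_conserved(self, small_slide):
        good, poor, records = filter_tiles(small_slide, FilterConfig(seed=0))
        assert len(good) + len(poor) == len(small_slide) == len(records)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            filter_tiles([], FilterConfig())


class TestClusterQualityFilterEstimator:
    def test_sklearn_surface_and_agreement(self, small_slide):
        from sklearn.base import clone

        est = ClusterQualityFilter(k=3, seed=1)
        assert clone(est).get_params()["k"] == 3
        labels = est.fit().predict(small_slide[:12])
        _, _, records = filter_tiles(small_slide[:12], FilterConfig(k=3, seed=1))
        assert labels.tolist() == [r.label for r in records]

    def test_transform_returns_masks_matching_tiles(self, small_slide):
        masks = ClusterQualityFilter(seed=0).fit().transform(small_slide[:3])
        assert all(m.shape == t.image.shape[:2]
                   for m, t in zip(masks, small_slide[:3]))
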