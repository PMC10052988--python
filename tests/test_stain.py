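"""Stain math tests: OD transform exactness, Macenko stain-vector recovery
on forward-synthesized tiles, concentration solves against a brute-force
grid oracle, normalization behavior, and H-channel extraction."""

import numpy as np
import pytest

from tileqc import stain
from tileqc.exceptions import DegenerateInputError, InvalidArgumentError
from tileqc.stain import (
    DEFAULT_STAIN_MATRIX,
    MacenkoParams,
    NormalizationReference,
    ODImage,
    StainMatrix,
    StainNormalizer,
    compute_concentrations,
    estimate_stain_matrix,
    extract_h_channel,
    normalize_to_reference,
    od_to_rgb,
    rgb_to_od,
)


def angle_deg(a, b):
    return np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def synth_tile(seed, shape=(50, 100), stains=None):
    """Forward-synthesize an RGB tile from known stain vectors with mixed
    concentrations spanning pure-H to pure-E pixels."""
    S = (stains or DEFAULT_STAIN_MATRIX).vectors
    rng = np.random.default_rng(seed)
    n = shape[0] * shape[1]
    w = rng.beta(0.4, 0.4, size=n)
    scale = rng.uniform(0.2, 1.5, size=n)
    conc = np.column_stack([w * scale, (1 - w) * scale])
    od = (conc @ S.T).reshape(shape + (3,))
    return od_to_rgb(od), conc


class TestODTransform:
    def test_round_trip_exact_over_all_channel_values(self):
        values = np.arange(256, dtype=np.uint8).reshape(1, -1, 1).repeat(3, axis=2)
        back = od_to_rgb(rgb_to_od(values))
        assert np.array_equal(back, values)

    def test_od_nonnegative_and_zero_only_at_white(self):
        od = rgb_to_od(np.arange(256).reshape(1, -1, 1).repeat(3, 2).astype(np.uint8))
        assert od.od.min() >= 0
        assert np.flatnonzero(od.od[0, :, 0] == 0).tolist() == [255]

    def test_black_pixel_od_value(self):
        # darkest pixel: od = log10(256) ≈ 2.408
        od = rgb_to_od(np.zeros((1, 1, 3), np.uint8))
        assert od.od[0, 0, 0] == pytest.approx(np.log10(256), abs=1e-9)

    def test_od_strictly_decreasing_in_intensity(self):
        od = rgb_to_od(np.arange(256).reshape(1, -1, 1).repeat(3, 2).astype(np.uint8))
        assert (np.diff(od.od[0, :, 0]) < 0).all()

    def test_nonpositive_white_level_rejected(self):
        with pytest.raises(InvalidArgumentError):
            rgb_to_od(np.zeros((1, 1, 3), np.uint8), i0=0)


class TestStainMatrix:
    def test_unit_norm_and_nonnegativity_enforced(self):
        with pytest.raises(InvalidArgumentError):
            StainMatrix(np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]]))

    @pytest.mark.parametrize("seed", range(20))
    def test_recovery_within_two_degrees(self, seed):
        img, _ = synth_tile(seed)
        est = estimate_stain_matrix(rgb_to_od(img))
        assert angle_deg(est.hematoxylin, DEFAULT_STAIN_MATRIX.hematoxylin) < 2.0
        assert angle_deg(est.eosin, DEFAULT_STAIN_MATRIX.eosin) < 2.0

    def test_uniform_white_tile_is_degenerate(self):
        white = np.full((64, 64, 3), 250, np.uint8)
        with pytest.raises(DegenerateInputError):
            estimate_stain_matrix(rgb_to_od(white))

    def test_single_stain_tile_is_degenerate(self):
        rng = np.random.default_rng(0)
        conc = np.column_stack([rng.uniform(0.2, 1.5, 2500), np.zeros(2500)])
        od = (conc @ DEFAULT_STAIN_MATRIX.vectors.T).reshape(50, 50, 3)
        with pytest.raises(DegenerateInputError):
            estimate_stain_matrix(rgb_to_od(od_to_rgb(od)))

    def test_column_order_invariant_under_stain_role_swap(self):
        # synthesize with the two generating stains' roles exchanged
        swapped = StainMatrix(DEFAULT_STAIN_MATRIX.vectors[:, ::-1])
        img_a, _ = synth_tile(5)
        img_b, _ = synth_tile(5, stains=swapped)
        est_a = estimate_stain_matrix(rgb_to_od(img_a))
        est_b = estimate_stain_matrix(rgb_to_od(img_b))
        # hematoxylin (larger red OD) is first either way
        assert est_a.hematoxylin[0] > est_a.eosin[0]
        assert est_b.hematoxylin[0] > est_b.eosin[0]
        assert angle_deg(est_a.hematoxylin, est_b.hematoxylin) < 2.0


class TestConcentrations:
    def test_exact_recovery_on_noise_free_od(self, rng):
        S = DEFAULT_STAIN_MATRIX
        conc = rng.uniform(0, 2, size=(20, 30, 2))
        od = ODImage(conc @ S.vectors.T)
        out = compute_concentrations(od, S)
        assert np.abs(out - conc).max() < 1e-6

    def test_zero_od_gives_zero_concentration(self):
        out = compute_concentrations(ODImage(np.zeros((2, 2, 3))), DEFAULT_STAIN_MATRIX)
        assert (out == 0).all()

    def test_least_squares_matches_brute_force_grid(self, rng):
        """Grid-search oracle: minimize ||od - S c|| over a 0.01-step grid."""
        S = DEFAULT_STAIN_MATRIX
        grid = np.arange(0, 2.0, 0.01)
        cc = np.stack(np.meshgrid(grid, grid), axis=-1).reshape(-1, 2)
        candidates = cc @ S.vectors.T  # (G, 3)
        for _ in range(5):
            true_c = rng.uniform(0.05, 1.9, size=2)
            od_pix = S.vectors @ true_c
            best = cc[np.argmin(((candidates - od_pix) ** 2).sum(axis=1))]
            solved = compute_concentrations(
                ODImage(od_pix.reshape(1, 1, 3)), S).ravel()
            assert np.abs(solved - best).max() <= 0.01 + 1e-9

    def test_nonfinite_od_rejected(self):
        bad = np.full((2, 2, 3), np.nan)
        with pytest.raises(InvalidArgumentError):
            compute_concentrations(ODImage(bad), DEFAULT_STAIN_MATRIX)

    def test_reconstruction_residual_tiny_on_synthesized_od(self, rng):
        S = DEFAULT_STAIN_MATRIX
        conc = rng.uniform(0, 1.5, size=(10, 10, 2))
        od = conc @ S.vectors.T
        back = compute_concentrations(ODImage(od), S) @ S.vectors.T
        assert np.abs(back - od).max() < 1e-6


class TestNormalization:
    def test_self_normalization_is_near_identity(self):
        img, _ = synth_tile(2)
        od = rgb_to_od(img)
        est = estimate_stain_matrix(od)
        conc = compute_concentrations(od, est)
        ref = NormalizationReference(est, np.percentile(conc.reshape(-1, 2), 99, axis=0))
        out = normalize_to_reference(img, ref)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_normalization_reduces_intensity_difference(self):
        # same concentration field, globally different staining intensity
        S = DEFAULT_STAIN_MATRIX.vectors
        rng = np.random.default_rng(4)
        conc = np.column_stack([rng.uniform(0, 1, 2500), rng.uniform(0, 1, 2500)])
        light = od_to_rgb((0.7 * conc @ S.T).reshape(50, 50, 3))
        dark = od_to_rgb((1.4 * conc @ S.T).reshape(50, 50, 3))
        pre = np.abs(light.mean((0, 1)) - dark.mean((0, 1))).mean()
        nl = normalize_to_reference(light)
        nd = normalize_to_reference(dark)
        post = np.abs(nl.mean((0, 1)) - nd.mean((0, 1))).mean()
        assert post < pre

    def test_blank_background_stays_white(self, rng):
        # tile whose top half carries stain and bottom half is truly blank:
        # zero-concentration pixels are invariant under concentration
        # rescaling, so they must stay at the white level
        S = DEFAULT_STAIN_MATRIX
        conc = np.concatenate([
            np.column_stack([rng.uniform(0.1, 1.8, 2000),
                             rng.uniform(0.1, 1.0, 2000)]),
            np.zeros((2000, 2)),
        ])
        img = od_to_rgb((conc @ S.vectors.T).reshape(80, 50, 3))
        out = normalize_to_reference(img)
        assert np.abs(out[40:].astype(int) - 255).max() <= 3

    def test_unfitted_normalizer_raises(self):
        with pytest.raises(InvalidArgumentError):
            StainNormalizer().transform(np.zeros((4, 4, 3), np.uint8))

    def test_sklearn_surface(self):
        from sklearn.base import clone

        n = StainNormalizer(beta=0.2)
        assert clone(n).get_params()["beta"] == 0.2


class TestHChannelExtraction:
    def test_eosin_free_tile_reproduced(self, rng):
        S = DEFAULT_STAIN_MATRIX
        conc = np.column_stack([rng.uniform(0.2, 1.2, 2500), np.zeros(2500)])
        img = od_to_rgb((conc @ S.vectors.T).reshape(50, 50, 3))
        out = extract_h_channel(img, S)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_hematoxylin_free_tile_goes_white(self, rng):
        S = DEFAULT_STAIN_MATRIX
        conc = np.column_stack([np.zeros(2500), rng.uniform(0.2, 1.2, 2500)])
        img = od_to_rgb((conc @ S.vectors.T).reshape(50, 50, 3))
        out = extract_h_channel(img, S)
        assert np.abs(out.astype(int) - 255).max() <= 3

    def test_zero_od_pixel_maps_to_white(self):
        img = np.full((20, 20, 3), 255, np.uint8)
        out = extract_h_channel(img, DEFAULT_STAIN_MATRIX)
        assert (out == 255).all()
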