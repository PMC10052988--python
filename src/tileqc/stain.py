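"""Optical-density color math for H&E histology.

Hematoxylin and eosin absorb light multiplicatively, so in optical-density
(OD) space — the negative log of transmittance relative to the white level —
the two stains mix *additively* (Beer-Lambert).  That turns stain separation
into a linear problem: each pixel's OD vector is (approximately) a
nonnegative combination of two unit "stain vectors", and recovering the
per-pixel coefficients (concentrations) lets us renormalize staining
intensity against a reference or reconstruct the image from the hematoxylin
signal alone, which isolates nuclei.

Stain vectors are estimated from an image with the Macenko procedure:
project tissue-pixel OD onto its leading principal plane and take the
extreme-percentile angles of the projected point cloud as the two stains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "ODImage",
    "StainMatrix",
    "MacenkoParams",
    "NormalizationReference",
    "DEFAULT_STAIN_MATRIX",
    "DEFAULT_MAX_CONC",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "compute_concentrations",
    "normalize_to_reference",
    "extract_h_channel",
    "StainNormalizer",
]


@dataclass(frozen=True)
class ODImage:
    """H×W×3 nonnegative optical densities plus the white level they refer to."""

    od: np.ndarray
    i0: float = 255.0


@dataclass(frozen=True)
class StainMatrix:
    """Two unit-norm stain vectors in 3-dim OD space, hematoxylin first.

    ``vectors`` is a 3×2 array whose columns are the hematoxylin and eosin
    OD directions.  Hematoxylin is identified as the column with the larger
    red-channel OD component: blue-purple nuclei absorb red strongly, while
    pink eosin transmits it almost untouched.
    """

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 2):
            raise InvalidArgumentError(f"stain matrix must be 3x2, got {v.shape}")
        norms = np.linalg.norm(v, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidArgumentError("stain vectors must be unit norm")
        if np.any(v < -1e-9):
            raise InvalidArgumentError("stain vectors must be componentwise nonnegative")
        object.__setattr__(self, "vectors", v)

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.vectors[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.vectors[:, 1]


@dataclass(frozen=True)
class MacenkoParams:
    """Knobs of the stain-vector estimator.

    beta — OD threshold below which a pixel counts as transparent (no
    tissue) and is excluded; alpha_pct — percentile of projected angles
    taken as each stain's direction; i0 — illumination white level;
    min_angle_deg — estimates whose two stain vectors are closer than this
    are rejected as degenerate (effectively a single stain, so the
    unmixing would be ill-conditioned).
    """

    beta: float = 0.15
    alpha_pct: float = 1.0
    i0: float = 255.0
    min_angle_deg: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise InvalidArgumentError("beta must be in (0, 1)")
        if not 0 < self.alpha_pct < 50:
            raise InvalidArgumentError("alpha_pct must be in (0, 50)")
        if not 0 <= self.min_angle_deg < 90:
            raise InvalidArgumentError("min_angle_deg must be in [0, 90)")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


#: Conventional H&E stain vectors (unit-normalized) used when no reference
#: slide is supplied, with reference 99th-percentile concentrations.
DEFAULT_STAIN_MATRIX = StainMatrix(
    np.column_stack([_unit(np.array([0.65, 0.70, 0.29])),
                     _unit(np.array([0.07, 0.99, 0.11]))])
)
DEFAULT_MAX_CONC = np.array([1.9, 1.0])


@dataclass(frozen=True)
class NormalizationReference:
    """Target appearance for stain normalization: a stain matrix plus the
    reference 99th-percentile concentration of each stain."""

    stain_matrix: StainMatrix = DEFAULT_STAIN_MATRIX
    max_conc: np.ndarray = field(default_factory=lambda: DEFAULT_MAX_CONC.copy())

    def __post_init__(self) -> None:
        mc = np.asarray(self.max_conc, dtype=float)
        if mc.shape != (2,) or np.any(mc <= 0):
            raise InvalidArgumentError("max_conc must be 2 positive values")
        object.__setattr__(self, "max_conc", mc)


def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> ODImage:
    """Convert 8-bit RGB to optical density.

    Uses ``od = -log10((p + 1) / (i0 + 1))`` so that the white level maps
    exactly to OD 0, OD is nonnegative over the full 8-bit range, and the
    transform is exactly invertible (see :func:`od_to_rgb`).
    """
    if i0 <= 0:
        raise InvalidArgumentError("i0 must be positive")
    arr = np.asarray(image, dtype=np.float64)
    return ODImage(od=-np.log10((arr + 1.0) / (i0 + 1.0)), i0=float(i0))


def od_to_rgb(od: ODImage | np.ndarray, i0: float | None = None) -> np.ndarray:
    """Invert :func:`rgb_to_od`, rounding to the nearest 8-bit value."""
    if isinstance(od, ODImage):
        arr, level = od.od, od.i0
    else:
        arr, level = np.asarray(od, dtype=float), 255.0
    if i0 is not None:
        level = i0
    pix = (level + 1.0) * np.power(10.0, -arr) - 1.0
    return np.clip(np.rint(pix), 0, 255).astype(np.uint8)


def estimate_stain_matrix(od: ODImage, params: MacenkoParams | None = None) -> StainMatrix:
    """Estimate the two stain vectors of an image (Macenko procedure).

    Tissue pixels (OD magnitude ≥ beta; transparent pixels carry no stain
    information) are projected onto the two leading principal directions of
    their OD covariance; the alpha_pct and (100 − alpha_pct) percentile
    angles of the projected cloud, mapped back to 3-space, are the stain
    vectors.  Raises DegenerateInputError when fewer than 100 tissue pixels
    exist or the OD cloud is effectively one-dimensional (single stain /
    single color).
    """
    params = params or MacenkoParams()
    x = np.asarray(od.od, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("OD image contains non-finite values")
    tissue = x[np.linalg.norm(x, axis=1) >= params.beta]
    if tissue.shape[0] < 100:
        raise DegenerateInputError(
            f"only {tissue.shape[0]} tissue pixels above beta={params.beta}; "
            "need at least 100 for stain estimation"
        )

    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    # leading plane; eigh returns ascending order
    plane = evecs[:, [2, 1]]
    if evals[2] <= 0 or evals[1] / evals[2] < 1e-6:
        raise DegenerateInputError("OD cloud is rank-1 (single color); cannot separate two stains")
    # orient basis so tissue projections are mostly positive on axis 0
    if np.median(tissue @ plane[:, 0]) < 0:
        plane[:, 0] *= -1
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [params.alpha_pct, 100.0 - params.alpha_pct])

    def back(angle: float) -> np.ndarray:
        v = plane @ np.array([np.cos(angle), np.sin(angle)])
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise DegenerateInputError("degenerate extreme-angle stain vector")
        return v / n

    v1, v2 = back(lo), back(hi)
    sep = np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if sep < params.min_angle_deg:
        raise DegenerateInputError(
            f"estimated stain vectors only {sep:.1f} degrees apart "
            f"(< {params.min_angle_deg}); effectively a single stain")
    # hematoxylin absorbs red (appears blue): larger red-channel OD first
    cols = (v1, v2) if v1[0] >= v2[0] else (v2, v1)
    return StainMatrix(np.column_stack(cols))


def compute_concentrations(od: ODImage, stains: StainMatrix) -> np.ndarray:
    """Per-pixel least-squares stain concentrations, negatives clipped to 0.

    Solves ``od ≈ S @ c`` for each pixel (S the 3×2 stain matrix) and
    returns an H×W×2 nonnegative array.
    """
    arr = np.asarray(od.od, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("OD image contains non-finite values")
    flat = arr.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(stains.vectors).T
    return np.clip(conc, 0.0, None).reshape(arr.shape[:-1] + (2,))


def _source_max_conc(conc: np.ndarray) -> np.ndarray:
    mc = np.percentile(conc.reshape(-1, 2), 99, axis=0)
    return np.maximum(mc, 1e-6)


def normalize_to_reference(
    image: np.ndarray,
    ref: NormalizationReference | None = None,
    params: MacenkoParams | None = None,
) -> np.ndarray:
    """Normalize an H&E image's staining intensity to a reference.

    The image's own stain matrix is estimated, concentrations are rescaled
    so their 99th percentiles match ``ref.max_conc``, and the image is
    reconstructed through the reference stain matrix.
    """
    ref = ref or NormalizationReference()
    params = params or MacenkoParams()
    od = rgb_to_od(image, params.i0)
    stains = estimate_stain_matrix(od, params)
    conc = compute_concentrations(od, stains)
    conc = conc * (ref.max_conc / _source_max_conc(conc))
    od_new = conc.reshape(-1, 2) @ ref.stain_matrix.vectors.T
    return od_to_rgb(od_new.reshape(od.od.shape), i0=params.i0)


def extract_h_channel(
    image: np.ndarray,
    stains: StainMatrix | None = None,
    i0: float = 255.0,
) -> np.ndarray:
    """Reconstruct the image from hematoxylin concentration only.

    Eosin concentration is zeroed before reconstruction, so nuclei stay
    dark while eosin-only cytoplasm and background go to white.  When no
    stain matrix is given it is estimated from the image itself.
    """
    od = rgb_to_od(image, i0)
    if stains is None:
        stains = estimate_stain_matrix(od, MacenkoParams(i0=i0))
    conc = compute_concentrations(od, stains)
    od_h = conc[..., 0:1] * stains.hematoxylin.reshape(1, 1, 3)
    return od_to_rgb(od_h, i0=i0)


class StainNormalizer(BaseEstimator, TransformerMixin):
    """Stain-intensity normalizer with a scikit-learn transformer surface.

    Parameters
    ----------
    beta, alpha_pct, i0 : Macenko estimation parameters.
    reference : NormalizationReference or None
        Target appearance.  When None and ``fit`` receives a reference
        image, the target is estimated from that image; when None and
        ``fit`` receives no image, the conventional published H&E vectors
        are used.

    Attributes
    ----------
    reference_ : NormalizationReference
        The fitted normalization target.
    """

    def __init__(self, beta: float = 0.15, alpha_pct: float = 1.0,
                 i0: float = 255.0, reference: NormalizationReference | None = None):
        self.beta = beta
        self.alpha_pct = alpha_pct
        self.i0 = i0
        self.reference = reference

    def _params(self) -> MacenkoParams:
        return MacenkoParams(beta=self.beta, alpha_pct=self.alpha_pct, i0=self.i0)

    def fit(self, X: np.ndarray | None = None, y=None) -> "StainNormalizer":
        """Fit the normalization target from a reference image (or defaults)."""
        if self.reference is not None:
            self.reference_ = self.reference
        elif X is None:
            self.reference_ = NormalizationReference()
        else:
            od = rgb_to_od(X, self.i0)
            stains = estimate_stain_matrix(od, self._params())
            conc = compute_concentrations(od, stains)
            self.reference_ = NormalizationReference(stains, _source_max_conc(conc))
        return self

    def transform(self, X) -> np.ndarray | list[np.ndarray]:
        """Normalize one image (H×W×3) or a list of images."""
        if not hasattr(self, "reference_"):
            raise InvalidArgumentError("StainNormalizer is not fitted; call fit() first")
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return normalize_to_reference(X, self.reference_, self._params())
        return [normalize_to_reference(img, self.reference_, self._params()) for img in X]
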