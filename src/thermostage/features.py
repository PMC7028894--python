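"""Fixed-length texture descriptors of the preprocessed thigh region.

The headline descriptor is the histogram of oriented gradients (HOG) with a
48x48-pixel cell: on the standard 210x240 ROI this yields 4x5 cells, 3x4
overlapping 2x2-cell blocks, and 9 unsigned orientation bins — 432 features.
Five simpler extractors (intensity statistics, contour geometry, uniform
rotation-invariant LBP, PCA projections and per-stage Euclidean template
distances) share a common interface so the classifier grid can sweep them.

Extractors that require fitting (PCA, EucDist templates) are fitted on the
training partition only; the fitted state is then applied to any image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from skimage import measure
from skimage.feature import hog as _skimage_hog
from skimage.feature import local_binary_pattern
from skimage.filters import threshold_otsu
from sklearn.decomposition import PCA as _SKPCA

from .io import STAGES
from .preprocess import ROIImage

logger = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """A named fixed-length descriptor of one image."""

    values: np.ndarray
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.method}: non-finite feature values")
        self.values = v

    @property
    def length(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class HOGConfig:
    """HOG layout: cell size in pixels, block size/stride in cells, bins."""

    cell_size: int = 48
    block_size: int = 2
    orientations: int = 9
    block_stride: int = 1
    block_norm: str = "L2"

    def n_cells(self, height: int, width: int) -> tuple[int, int]:
        return height // self.cell_size, width // self.cell_size

    def n_features(self, height: int, width: int) -> int:
        """Descriptor length for an image of the given size.

        D = (floor(H/c) - b + 1) * (floor(W/c) - b + 1) * b^2 * orientations
        with blocks advancing one cell at a time.
        """
        cr, cc = self.n_cells(height, width)
        br = (cr - self.block_size) // self.block_stride + 1
        bc = (cc - self.block_size) // self.block_stride + 1
        if br < 1 or bc < 1:
            raise ValueError(
                f"image {height}x{width} too small: needs at least "
                f"{self.block_size * self.cell_size} px a side"
            )
        return br * bc * self.block_size**2 * self.orientations


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, ROIImage):
        return image.pixels
    return np.asarray(image, dtype=float)


def hog_features(image, config: HOGConfig = HOGConfig()) -> FeatureVector:
    """Histogram of oriented gradients over unsigned orientations [0, 180).

    Per-cell magnitude-weighted orientation histograms, 2x2-cell blocks at
    1-cell stride, L2 block normalisation with an epsilon guard (a constant
    image therefore maps to the zero vector).
    """
    px = _as_pixels(image)
    expected = config.n_features(*px.shape)  # raises if too small
    if config.block_stride != 1:
        raise NotImplementedError("only 1-cell block stride is supported")
    vec = _skimage_hog(
        px,
        orientations=config.orientations,
        pixels_per_cell=(config.cell_size, config.cell_size),
        cells_per_block=(config.block_size, config.block_size),
        block_norm=config.block_norm,
        feature_vector=True,
    )
    assert vec.size == expected, f"HOG returned {vec.size}, expected {expected}"
    return FeatureVector(values=vec, method="hog")


def stat_features(image) -> FeatureVector:
    """First-order intensity statistics.

    [mean, variance, skewness, kurtosis (excess), median, p10, p90,
    entropy of the 64-bin intensity histogram] — length 8.  Skewness and
    kurtosis are defined as 0 for a zero-variance image.
    """
    px = _as_pixels(image).ravel()
    if px.size == 0:
        raise ValueError("stat_features: empty image")
    var = px.var()
    if var > 0:
        skew = sstats.skew(px)
        kurt = sstats.kurtosis(px)
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(px, bins=64, range=(0.0, 1.0))
    p = hist[hist > 0] / px.size
    entropy = float(-(p * np.log2(p)).sum())
    vals = [
        px.mean(), var, skew, kurt,
        np.median(px), np.percentile(px, 10), np.percentile(px, 90), entropy,
    ]
    return FeatureVector(values=np.array(vals), method="stat")


def _boundary_length(mask: np.ndarray) -> float:
    """Perimeter via the marching-squares boundary polygon, simplified with
    Douglas-Peucker at 1-px tolerance.  The simplification removes the
    staircase bias of pixel-chain estimators, so discs and axis-aligned
    rectangles both come out within ~1% of their true perimeter."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return 0.0
    poly = measure.approximate_polygon(max(contours, key=len), tolerance=1.0)
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def contour_features(image) -> FeatureVector:
    """Geometry of the dominant bright region.

    Otsu-binarise, keep the largest 8-connected component, and report
    [perimeter, area, area/perimeter^2, eccentricity, solidity] — length 5.
    An empty foreground yields the zero vector.
    """
    px = _as_pixels(image)
    zero = FeatureVector(values=np.zeros(5), method="cont")
    if px.max() - px.min() <= 0:
        logger.warning("contour_features: flat image, empty foreground")
        return zero
    mask = px > threshold_otsu(px)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    if not props:
        logger.warning("contour_features: empty foreground")
        return zero
    region = max(props, key=lambda p: p.area)
    perim = _boundary_length(labels == region.label)
    area = float(region.area)
    compact = area / perim**2 if perim > 0 else 0.0
    vals = [perim, area, compact, region.eccentricity, region.solidity]
    return FeatureVector(values=np.array(vals), method="cont")


def lbp_features(image) -> FeatureVector:
    """Uniform rotation-invariant local binary patterns (P=8, R=1).

    Normalised 10-bin histogram: bins 0..8 count uniform patterns by their
    number of set bits (bin 8 is the flat pattern: all neighbours at or
    above the centre), bin 9 collects non-uniform patterns.  Sums to 1.
    The 1-px image border is excluded: its codes would mix in out-of-image
    neighbours.
    """
    px = _as_pixels(image)
    if px.dtype != np.uint8:
        # quantise to 256 grey levels: neighbour comparisons on raw floats
        # are sensitive to sub-quantum numerical noise
        px = np.clip(np.round(px * 255), 0, 255).astype(np.uint8)
    codes = local_binary_pattern(px, P=8, R=1, method="uniform")[1:-1, 1:-1]
    hist, _ = np.histogram(codes, bins=np.arange(11) - 0.5)
    return FeatureVector(values=hist / codes.size, method="lbp")


class PCAFeatures:
    """PCA projection features, fitted on the training partition only.

    Images are flattened (210x240 -> 50,400 raw intensities) and
    mean-centred; the descriptor is the image's coefficients on the top-k
    principal directions.  k is capped at n_train - 1.
    """

    def __init__(self, k: int = 40):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._pca: _SKPCA | None = None

    def fit(self, train_images) -> "PCAFeatures":
        X = np.stack([_as_pixels(im).ravel() for im in train_images])
        if X.shape[0] < 2:
            raise ValueError("PCA needs at least 2 training images")
        k = min(self.k, X.shape[0] - 1)
        if k < self.k:
            logger.warning("PCA: k reduced from %d to n_train-1 = %d", self.k, k)
        self._pca = _SKPCA(n_components=k, svd_solver="full").fit(X)
        return self

    def transform(self, image) -> FeatureVector:
        if self._pca is None:
            raise RuntimeError("PCAFeatures must be fitted before use")
        x = _as_pixels(image).ravel()[None, :]
        return FeatureVector(values=self._pca.transform(x)[0], method="pca")

    @property
    def mean_image(self) -> np.ndarray:
        return self._pca.mean_

    def reconstruction_error(self, images) -> float:
        X = np.stack([_as_pixels(im).ravel() for im in images])
        Z = self._pca.transform(X)
        return float(np.mean((X - self._pca.inverse_transform(Z)) ** 2))


class EucDistFeatures:
    """Euclidean distances to per-stage mean-image templates (length 4).

    Templates are the per-stage means of the flattened training ROIs.  A
    stage absent from training gets a +inf sentinel so it can never be the
    nearest template.
    """

    def __init__(self):
        self.templates: dict[int, np.ndarray] = {}

    def fit(self, train_images, train_stages) -> "EucDistFeatures":
        X = np.stack([_as_pixels(im).ravel() for im in train_images])
        y = np.asarray(train_stages, dtype=int)
        if X.shape[0] != y.size:
            raise ValueError("images and stage labels differ in length")
        for s in STAGES:
            if np.any(y == s):
                self.templates[s] = X[y == s].mean(axis=0)
            else:
                logger.warning("EucDist: stage %d absent from training set", s)
        if not self.templates:
            raise ValueError("no training stages available")
        return self

    def transform(self, image) -> FeatureVector:
        if not self.templates:
            raise RuntimeError("EucDistFeatures must be fitted before use")
        x = _as_pixels(image).ravel()
        d = np.full(len(STAGES), np.finfo(float).max)
        for s, t in self.templates.items():
            d[s] = np.linalg.norm(x - t)
        return FeatureVector(values=d, method="eucdist")


EXTRACTORS = ("hog", "lbp", "stat", "cont", "pca", "eucdist")

#: Extractors that require fitting on the training partition.
FITTED_EXTRACTORS = ("pca", "eucdist")


def build_extractor(method: str, train_images=None, train_stages=None,
                    hog_config: HOGConfig = HOGConfig(), pca_k: int = 40):
    """Return a callable image -> FeatureVector for the named method.

    PCA and EucDist are fitted here on the supplied training partition; the
    stateless methods ignore it.
    """
    method = method.lower()
    if method == "hog":
        return lambda im: hog_features(im, hog_config)
    if method == "lbp":
        return lbp_features
    if method == "stat":
        return stat_features
    if method == "cont":
        return contour_features
    if method == "pca":
        if train_images is None:
            raise ValueError("pca extractor requires training images")
        return PCAFeatures(k=pca_k).fit(train_images).transform
    if method == "eucdist":
        if train_images is None or train_stages is None:
            raise ValueError("eucdist extractor requires training images and stages")
        return EucDistFeatures().fit(train_images, train_stages).transform
    raise ValueError(f"unknown feature method {method!r}; choose from {EXTRACTORS}")


def feature_matrix(images, extractor) -> np.ndarray:
    """Stack an extractor's outputs over a list of images into (n, d)."""
    return np.stack([extractor(im).values for im in images])
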