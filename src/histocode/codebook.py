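"""Two-level bag-of-visual-words coding.

Level 1 (L1): 32x32-pixel patch descriptors from the whole training set are
pooled (up to 1000 random valid patches per image), z-scored, and clustered
with k-means into K1 codewords; every patch of every image is then recoded
as the index of its nearest codeword.

Level 2 (L2): a 15x15-patch neighbourhood (480x480 pixels) is described by
the relative frequencies of the L1 codes it contains.  Two class-specific
codebooks of K2 codewords each are fitted (up to 500 random windows per
training image, pooled within class), and an image is finally summarised as
the histogram over the concatenated 2*K2 codeword set, positive-class block
first, computed on the non-overlapping 15x15 window tiling.

Validity propagates through both levels: a patch with more than half
background pixels is excluded, and a window with more than half invalid
member patches is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from histocode.extract import ImageFeatures

__all__ = [
    "CodebookL1",
    "CodeGrid",
    "CodebookPairL2",
    "UnusableImageError",
    "sample_patch_descriptors",
    "fit_l1",
    "encode_l1",
    "l2_descriptor",
    "window_validity",
    "sample_l2_descriptors",
    "fit_l2_pair",
    "encode_image",
    "window_codes",
]

INVALID_CODE = 0  # sentinel for excluded patches / windows
WINDOW_PATCHES = 15


class UnusableImageError(RuntimeError):
    """Raised when an image yields no valid coding unit at some level."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _fit_kmeans(points: np.ndarray, k: int, seed: int | None, restarts: int) -> np.ndarray:
    if points.shape[0] < k:
        raise ValueError(f"need at least {k} points, got {points.shape[0]}")
    n_distinct = np.unique(points, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"need at least {k} distinct points, got {n_distinct}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, max_iter=300, tol=1e-4, random_state=seed)
    km.fit(points)
    return km.cluster_centers_


@dataclass
class CodebookL1:
    """K1 patch-descriptor codewords in z-scored descriptor space."""

    centroids: np.ndarray  # (k1, 96)
    mean: np.ndarray  # standardizer, fitted on the pooled training sample
    sd: np.ndarray
    k1: int

    def standardize(self, descriptors: np.ndarray) -> np.ndarray:
        return (descriptors - self.mean) / self.sd


@dataclass
class CodeGrid:
    """Per-image grid of 1-based L1 codes; 0 marks excluded patches."""

    codes: np.ndarray  # (n_rows, n_cols) int
    k1: int
    image_id: str = ""


@dataclass
class CodebookPairL2:
    """Class-specific L2 codebooks over L1 code-frequency vectors.

    The concatenated codeword index space is 1..2*k2 with the positive-class
    block first.
    """

    positive: np.ndarray  # (k2, k1)
    negative: np.ndarray  # (k2, k1)
    k2: int

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack([self.positive, self.negative])


def sample_patch_descriptors(
    feats: ImageFeatures, n: int = 1000, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Uniform sample without replacement of valid patch descriptors from one
    image; all of them if fewer than ``n`` are valid."""
    rng = _as_rng(rng)
    pool = feats.descriptors[feats.valid]
    if pool.shape[0] == 0:
        warnings.warn(f"image {feats.image_id!r} has no valid patch; skipped", stacklevel=2)
        return pool.reshape(0, feats.descriptors.shape[-1])
    if pool.shape[0] <= n:
        return pool
    idx = rng.choice(pool.shape[0], size=n, replace=False)
    return pool[idx]


def fit_l1(
    descriptors: np.ndarray, k1: int = 128, rng_seed: int | None = None, restarts: int = 5
) -> CodebookL1:
    """k-means codebook over the pooled descriptor sample, fitted in z-scored
    space (mean/variance descriptor entries live on very different scales)."""
    descriptors = np.asarray(descriptors, dtype=np.float64)
    if k1 < 2:
        raise ValueError("k1 must be >= 2")
    mean = descriptors.mean(axis=0)
    sd = descriptors.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (descriptors - mean) / sd
    centroids = _fit_kmeans(z, k1, rng_seed, restarts)
    return CodebookL1(centroids=centroids, mean=mean, sd=sd, k1=k1)


def encode_l1(feats: ImageFeatures, cb: CodebookL1) -> CodeGrid:
    """Assign each valid patch its nearest codeword (1-based, ties to the
    lowest index); invalid patches get the sentinel 0."""
    nr, nc, d = feats.descriptors.shape
    if d != cb.centroids.shape[1]:
        raise ValueError("descriptor dimension does not match codebook")
    codes = np.full((nr, nc), INVALID_CODE, dtype=np.int32)
    if feats.valid.any():
        z = cb.standardize(feats.descriptors[feats.valid])
        d2 = cdist(z, cb.centroids, metric="sqeuclidean")
        codes[feats.valid] = np.argmin(d2, axis=1) + 1
    return CodeGrid(codes=codes, k1=cb.k1, image_id=feats.image_id)


def _window_freq(members: np.ndarray, k1: int) -> np.ndarray | None:
    valid = members[members != INVALID_CODE]
    if valid.size <= members.size / 2:  # > 50% invalid members
        return None
    counts = np.bincount(valid, minlength=k1 + 1)[1:]
    return counts / valid.size


def l2_descriptor(
    grid: CodeGrid, window_row: int, window_col: int, window_patches: int = WINDOW_PATCHES
) -> np.ndarray | None:
    """Frequency vector of L1 codes over the window's valid member patches
    (sums to 1), or ``None`` when more than half the members are invalid.

    ``window_row``/``window_col`` index the top-left patch of the window.
    """
    nr, nc = grid.codes.shape
    if window_row < 0 or window_col < 0 or window_row + window_patches > nr or window_col + window_patches > nc:
        raise ValueError("window out of bounds")
    members = grid.codes[window_row : window_row + window_patches, window_col : window_col + window_patches]
    return _window_freq(members.ravel(), grid.k1)


def window_validity(grid: CodeGrid, window_patches: int = WINDOW_PATCHES, stride: int = 1) -> np.ndarray:
    """Validity of every window top-left position at the given stride, via a
    summed-area table over the invalid-patch indicator."""
    invalid = (grid.codes == INVALID_CODE).astype(np.int64)
    nr, nc = invalid.shape
    w = window_patches
    if nr < w or nc < w:
        return np.zeros((0, 0), dtype=bool)
    sat = np.zeros((nr + 1, nc + 1), dtype=np.int64)
    sat[1:, 1:] = invalid.cumsum(0).cumsum(1)
    r = np.arange(0, nr - w + 1, stride)
    c = np.arange(0, nc - w + 1, stride)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    n_invalid = sat[rr + w, cc + w] - sat[rr, cc + w] - sat[rr + w, cc] + sat[rr, cc]
    return n_invalid <= (w * w) / 2.0  # invalid when strictly more than half


def sample_l2_descriptors(
    grid: CodeGrid,
    n: int = 500,
    rng: np.random.Generator | int | None = None,
    window_patches: int = WINDOW_PATCHES,
) -> np.ndarray:
    """Up to ``n`` L2 frequency vectors at uniformly sampled valid window
    positions (stride 1)."""
    rng = _as_rng(rng)
    ok = window_validity(grid, window_patches=window_patches, stride=1)
    pos = np.argwhere(ok)
    if pos.shape[0] == 0:
        warnings.warn(f"image {grid.image_id!r} has no valid window; skipped", stacklevel=2)
        return np.zeros((0, grid.k1))
    if pos.shape[0] > n:
        pos = pos[rng.choice(pos.shape[0], size=n, replace=False)]
    out = np.empty((pos.shape[0], grid.k1))
    for i, (r, c) in enumerate(pos):
        out[i] = l2_descriptor(grid, int(r), int(c), window_patches=window_patches)
    return out


def fit_l2_pair(
    pos_descriptors: np.ndarray,
    neg_descriptors: np.ndarray,
    k2: int = 128,
    rng_seed: int | None = None,
    restarts: int = 5,
) -> CodebookPairL2:
    """Fit the two class-specific L2 codebooks independently.  Frequency
    vectors are already commensurate, so no standardization is applied."""
    positive = _fit_kmeans(np.asarray(pos_descriptors, dtype=np.float64), k2, rng_seed, restarts)
    negative = _fit_kmeans(np.asarray(neg_descriptors, dtype=np.float64), k2, rng_seed, restarts)
    return CodebookPairL2(positive=positive, negative=negative, k2=k2)


def window_codes(
    grid: CodeGrid, pair: CodebookPairL2, window_patches: int = WINDOW_PATCHES
) -> np.ndarray:
    """Codeword assignment (1..2*k2; 0 = invalid window) for the
    non-overlapping window tiling anchored at patch (0, 0)."""
    nr, nc = grid.codes.shape
    w = window_patches
    wr, wc = nr // w, nc // w
    out = np.zeros((wr, wc), dtype=np.int32)
    stacked = pair.stacked
    for i in range(wr):
        for j in range(wc):
            freq = l2_descriptor(grid, i * w, j * w, window_patches=w)
            if freq is None:
                continue
            d2 = cdist(freq[None, :], stacked, metric="sqeuclidean")[0]
            out[i, j] = int(np.argmin(d2)) + 1
    return out


def encode_image(
    grid: CodeGrid, pair: CodebookPairL2, window_patches: int = WINDOW_PATCHES
) -> np.ndarray:
    """Final image representation: relative frequency histogram of codeword
    assignments over the non-overlapping window tiling (length 2*k2)."""
    codes = window_codes(grid, pair, window_patches=window_patches)
    valid = codes[codes != INVALID_CODE]
    if valid.size == 0:
        raise UnusableImageError(f"image {grid.image_id!r} has no valid 15x15 window")
    counts = np.bincount(valid, minlength=2 * pair.k2 + 1)[1:]
    return counts / valid.size
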