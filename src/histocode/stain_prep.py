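"""Stain separation and spatial preprocessing of RGB tissue images.

An H&E-stained section transmits light according to the Beer-Lambert law:
per-pixel optical density (OD = -log10(I/I0)) is, to good approximation,
a non-negative linear combination of the OD "colour" vectors of the two
dyes.  Colour deconvolution inverts that mixture, yielding one intensity
channel per stain — haematoxylin (nuclei) and eosin (cytoplasm/stroma).
All texture analysis downstream operates on these two channels at an
equivalent 5x magnification; 20x input is block-averaged down by 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RUIFROK_HE",
    "StainPair",
    "default_stain_matrix",
    "rgb_to_od",
    "deconvolve_stains",
    "downscale",
    "downscale_mask",
    "patch_is_valid",
    "background_mask_from_rgb",
]

#: Ruifrok-Johnston optical-density vectors for haematoxylin and eosin.
RUIFROK_HE = np.array(
    [
        [0.650, 0.704, 0.286],  # haematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)

#: RGB channel values at or above this are treated as background when no
#: tumour mask is supplied (slide glass is near-white).
WHITE_BACKGROUND_LEVEL = 240


def default_stain_matrix() -> np.ndarray:
    """3x3 stain matrix: unit-norm OD rows for H, E and a residual channel.

    The residual row is the unit cross-product of the H and E vectors, the
    conventional completion when only two stains are modelled.
    """
    h = RUIFROK_HE[0] / np.linalg.norm(RUIFROK_HE[0])
    e = RUIFROK_HE[1] / np.linalg.norm(RUIFROK_HE[1])
    r = np.cross(h, e)
    r /= np.linalg.norm(r)
    return np.vstack([h, e, r])


@dataclass
class StainPair:
    """Per-image haematoxylin and eosin OD-scale intensity channels."""

    h_channel: np.ndarray
    e_channel: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.h_channel.shape != self.e_channel.shape:
            raise ValueError("h and e channels must have identical shapes")
        if self.mask is not None and self.mask.shape != self.h_channel.shape:
            raise ValueError("mask shape must match channel shape")


def rgb_to_od(image: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert transmitted-light RGB to optical density, channel-wise.

    Intensities are floored at 1 so fully absorbed pixels stay finite.
    """
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    arr = np.maximum(np.asarray(image, dtype=np.float64), 1.0)
    return -np.log10(arr / i0)


def deconvolve_stains(
    image: np.ndarray,
    stain_matrix: np.ndarray | None = None,
    i0: float = 255.0,
    mask: np.ndarray | None = None,
) -> StainPair:
    """Unmix an RGB image into haematoxylin and eosin concentration channels.

    ``stain_matrix`` rows are the unit OD vectors of (H, E, residual); the
    per-pixel OD vector is solved against it, the residual discarded, and
    negative concentrations clipped to zero (they are physical quantities).
    """
    if stain_matrix is None:
        stain_matrix = default_stain_matrix()
    stain_matrix = np.asarray(stain_matrix, dtype=np.float64)
    if stain_matrix.shape != (3, 3):
        raise ValueError("stain matrix must be 3x3")
    if abs(np.linalg.det(stain_matrix)) < 1e-8:
        raise ValueError("stain matrix is singular")
    od = rgb_to_od(image, i0=i0)
    # od[pix] = conc[pix] @ stain_matrix  =>  conc = od @ inv(stain_matrix)
    conc = od.reshape(-1, 3) @ np.linalg.inv(stain_matrix)
    conc = np.clip(conc, 0.0, None).reshape(image.shape[:2] + (3,))
    return StainPair(h_channel=conc[..., 0], e_channel=conc[..., 1], mask=mask)


def _block_reduce_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Mean over ``factor`` x ``factor`` blocks; partial edge blocks use the
    mean of the pixels they actually contain."""
    h, w = arr.shape[:2]
    oh = -(-h // factor)
    ow = -(-w // factor)
    ph, pw = oh * factor - h, ow * factor - w
    pad_width = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    padded = np.pad(arr.astype(np.float64), pad_width, mode="constant")
    counts = np.pad(np.ones((h, w)), [(0, ph), (0, pw)], mode="constant")
    shape = (oh, factor, ow, factor) + arr.shape[2:]
    sums = padded.reshape(shape).sum(axis=(1, 3))
    ns = counts.reshape(oh, factor, ow, factor).sum(axis=(1, 3))
    return sums / ns.reshape(ns.shape + (1,) * (arr.ndim - 2))


def downscale(image_or_channel: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downscaling; factor 4 maps 20x input to the 5x working scale."""
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError(f"downscale factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return np.asarray(image_or_channel, dtype=np.float64).copy()
    return _block_reduce_mean(np.asarray(image_or_channel), int(factor))


def downscale_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Downscale a binary tissue mask: a low-resolution pixel is tissue when
    at least half of its source block is tissue."""
    frac = downscale(mask.astype(np.float64), factor)
    return frac >= 0.5


def patch_is_valid(mask_patch: np.ndarray) -> bool:
    """A patch is usable unless *more than* 50% of its pixels are background.

    ``mask_patch`` is binary with 1 = tissue; exactly half background is
    still valid (the exclusion rule is strict).
    """
    m = np.asarray(mask_patch)
    if m.size == 0:
        return False
    background_fraction = 1.0 - m.astype(bool).mean()
    return background_fraction <= 0.5


def background_mask_from_rgb(image: np.ndarray) -> np.ndarray:
    """Tissue mask for images that come without one: near-white pixels
    (all channels >= 240) are background."""
    arr = np.asarray(image)
    return ~np.all(arr >= WHITE_BACKGROUND_LEVEL, axis=-1)
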