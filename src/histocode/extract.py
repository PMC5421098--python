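"""Per-image feature extraction: RGB image -> patch descriptor grid.

Glue between stain separation and texture description.  All analysis runs
at the 5x working magnification; 20x input is block-averaged by 4 first,
then deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from histocode.gabor_features import GaborBank, build_bank, filter_channel, patch_descriptors, patch_validity
from histocode.stain_prep import background_mask_from_rgb, deconvolve_stains, downscale, downscale_mask

__all__ = ["ImageFeatures", "compute_image_features", "features_to_table", "features_from_table"]

MAG_FACTORS = {"20x": 4, "5x": 1}


@dataclass
class ImageFeatures:
    """Patch-descriptor grid of one image plus the patch validity grid."""

    image_id: str
    descriptors: np.ndarray  # (n_rows, n_cols, 96)
    valid: np.ndarray  # (n_rows, n_cols) bool
    label: int | None = None

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def compute_image_features(
    rgb: np.ndarray,
    mask: np.ndarray | None = None,
    in_mag: str = "5x",
    bank: GaborBank | None = None,
    image_id: str = "",
    label: int | None = None,
    patch_px: int = 32,
    i0: float = 255.0,
    stain_matrix: np.ndarray | None = None,
) -> ImageFeatures:
    """Full per-image path: downscale (if 20x), deconvolve, filter, describe."""
    if in_mag not in MAG_FACTORS:
        raise ValueError(f"in_mag must be one of {sorted(MAG_FACTORS)}, got {in_mag!r}")
    if mask is None:
        mask = background_mask_from_rgb(rgb)
    factor = MAG_FACTORS[in_mag]
    if factor > 1:
        rgb = downscale(rgb, factor)
        mask = downscale_mask(mask, factor)
    if bank is None:
        bank = build_bank()
    pair = deconvolve_stains(rgb, stain_matrix=stain_matrix, i0=i0, mask=mask)
    # float32 responses: halves filtering cost, descriptor stats accumulate in float64
    h_resp = filter_channel(pair.h_channel.astype(np.float32), bank)
    e_resp = filter_channel(pair.e_channel.astype(np.float32), bank)
    desc = patch_descriptors(h_resp, e_resp, patch_px=patch_px)
    valid = patch_validity(mask, patch_px=patch_px)
    return ImageFeatures(image_id=image_id, descriptors=desc, valid=valid, label=label)


def features_to_table(feats: ImageFeatures) -> pd.DataFrame:
    """Flatten a descriptor grid into the delimited-table layout
    (patch_row, patch_col, valid, v1..v96)."""
    nr, nc, d = feats.descriptors.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    data = {
        "patch_row": rows.ravel(),
        "patch_col": cols.ravel(),
        "valid": feats.valid.ravel().astype(int),
    }
    flat = feats.descriptors.reshape(-1, d)
    for j in range(d):
        data[f"v{j + 1}"] = flat[:, j]
    return pd.DataFrame(data)


def features_from_table(table: pd.DataFrame, image_id: str = "", label: int | None = None) -> ImageFeatures:
    nr = int(table["patch_row"].max()) + 1
    nc = int(table["patch_col"].max()) + 1
    vcols = [c for c in table.columns if c.startswith("v")]
    d = len(vcols)
    desc = np.zeros((nr, nc, d))
    valid = np.zeros((nr, nc), dtype=bool)
    r = table["patch_row"].to_numpy()
    c = table["patch_col"].to_numpy()
    desc[r, c] = table[vcols].to_numpy()
    valid[r, c] = table["valid"].to_numpy().astype(bool)
    return ImageFeatures(image_id=image_id, descriptors=desc, valid=valid, label=label)
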