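"""Gabor filter-bank texture descriptors of stain channels.

Each filter is the real part of a Gaussian-modulated complex sinusoid

    G(x, y; nu, theta, sigma) = exp(-(x^2 + y^2) / (2 sigma^2))
                                * cos(2 pi nu (x cos theta + y sin theta))

with spatial frequency ``nu`` (cycles/pixel), orientation ``theta`` and
isotropic Gaussian bandwidth ``sigma``.  The default bank crosses
sigma in {1, 2*sqrt(2)}, theta in {0, pi/4, pi/2, 3pi/4} and
nu in {3/4, 3/8, 3/16} — 24 filters.  A 32x32-pixel patch is described by
the mean and (population) variance of each filter response over the patch,
for the H and then the E channel: a 96-value descriptor laid out as
[H means (24), H variances (24), E means (24), E variances (24)].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_SIGMAS",
    "DEFAULT_THETAS",
    "DEFAULT_NUS",
    "GaborParams",
    "GaborBank",
    "make_kernel",
    "default_support",
    "build_bank",
    "filter_channel",
    "patch_descriptors",
    "patch_descriptor",
    "patch_validity",
]

DEFAULT_SIGMAS: tuple[float, ...] = (1.0, 2.0 * np.sqrt(2.0))
DEFAULT_THETAS: tuple[float, ...] = tuple(k * np.pi / 4 for k in range(4))
DEFAULT_NUS: tuple[float, ...] = (3 / 4, 3 / 8, 3 / 16)

DESCRIPTOR_LENGTH = 96
PATCH_PX = 32


class GaborParams(NamedTuple):
    nu: float
    theta: float
    sigma: float


def default_support(sigma: float) -> int:
    """Smallest odd kernel side covering 3 Gaussian standard deviations
    each way (>= 99.7% of the envelope mass)."""
    s = int(np.ceil(6.0 * sigma + 1.0))
    return s if s % 2 == 1 else s + 1


def make_kernel(p: GaborParams, support: int | None = None) -> np.ndarray:
    """Evaluate the real Gabor kernel on an odd ``support`` x ``support`` grid.

    ``x`` is the column offset and ``y`` the row offset from the centre.
    """
    if p.nu <= 0 or p.sigma <= 0:
        raise ValueError("nu and sigma must be positive")
    if support is None:
        support = default_support(p.sigma)
    if support < 3 or support % 2 == 0:
        raise ValueError(f"support must be an odd integer >= 3, got {support}")
    r = support // 2
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * p.sigma**2))
    carrier = np.cos(2.0 * np.pi * p.nu * (x * np.cos(p.theta) + y * np.sin(p.theta)))
    return envelope * carrier


@dataclass
class GaborBank:
    """Ordered filter bank: sigma-major, then theta, then nu."""

    kernels: list[np.ndarray]
    params: list[GaborParams]

    def __len__(self) -> int:
        return len(self.kernels)

    @property
    def max_support(self) -> int:
        return max(k.shape[0] for k in self.kernels)


def build_bank(
    sigma_set: Sequence[float] = DEFAULT_SIGMAS,
    theta_set: Sequence[float] = DEFAULT_THETAS,
    nu_set: Sequence[float] = DEFAULT_NUS,
) -> GaborBank:
    if not (len(sigma_set) and len(theta_set) and len(nu_set)):
        raise ValueError("parameter sets must be non-empty")
    kernels, params = [], []
    for sigma in sigma_set:
        support = default_support(sigma)
        for theta in theta_set:
            for nu in nu_set:
                p = GaborParams(nu=nu, theta=theta, sigma=sigma)
                params.append(p)
                kernels.append(make_kernel(p, support))
    return GaborBank(kernels=kernels, params=params)


def filter_channel(channel: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Correlate a channel with every kernel of the bank (mirror-reflected
    borders); returns a (n_filters, H, W) stack, same dtype as the input
    (float32 unless float64 is passed).

    The real Gabor kernel splits into two separable terms,
    cos(ax + by) = cos(ax) cos(by) - sin(ax) sin(by) under a separable
    Gaussian envelope, so each response needs at most four 1-D correlations;
    the sine term vanishes for axis-aligned orientations.
    """
    channel = np.asarray(channel)
    if channel.dtype != np.float64:
        channel = channel.astype(np.float32)
    h, w = channel.shape
    if h < bank.max_support or w < bank.max_support:
        raise ValueError("channel smaller than the largest kernel support")
    out = np.empty((len(bank), h, w), dtype=channel.dtype)
    for i, p in enumerate(bank.params):
        r = bank.kernels[i].shape[0] // 2
        u = np.arange(-r, r + 1, dtype=np.float64)
        envelope = np.exp(-(u**2) / (2.0 * p.sigma**2))
        a = 2.0 * np.pi * p.nu * np.cos(p.theta)  # along x (columns)
        b = 2.0 * np.pi * p.nu * np.sin(p.theta)  # along y (rows)
        wx_cos = (envelope * np.cos(a * u)).astype(channel.dtype)
        wy_cos = (envelope * np.cos(b * u)).astype(channel.dtype)
        resp = ndimage.correlate1d(channel, wx_cos, axis=1, mode="mirror")
        resp = ndimage.correlate1d(resp, wy_cos, axis=0, mode="mirror")
        wx_sin = envelope * np.sin(a * u)
        wy_sin = envelope * np.sin(b * u)
        if np.abs(wx_sin).max() > 1e-15 and np.abs(wy_sin).max() > 1e-15:
            s = ndimage.correlate1d(channel, wx_sin.astype(channel.dtype), axis=1, mode="mirror")
            s = ndimage.correlate1d(s, wy_sin.astype(channel.dtype), axis=0, mode="mirror")
            resp = resp - s
        out[i] = resp
    return out


def patch_descriptors(
    h_resp: np.ndarray, e_resp: np.ndarray, patch_px: int = PATCH_PX
) -> np.ndarray:
    """Per-patch mean/variance descriptors over a non-overlapping patch grid
    anchored at pixel (0, 0); returns (n_rows, n_cols, 4 * n_filters).

    Variance is the population variance of the filter response within the
    patch window.
    """
    if h_resp.shape != e_resp.shape:
        raise ValueError("H and E response stacks must be aligned")
    nf, h, w = h_resp.shape
    nr, nc = h // patch_px, w // patch_px
    if nr < 1 or nc < 1:
        raise ValueError("image smaller than one patch")

    def stats(resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        blocks = resp[:, : nr * patch_px, : nc * patch_px].reshape(nf, nr, patch_px, nc, patch_px)
        n = patch_px * patch_px
        # reduce the contiguous axis first; accumulate in float64
        s1 = blocks.sum(axis=4, dtype=np.float64).sum(axis=2)
        s2 = (blocks.astype(np.float64) ** 2).sum(axis=4).sum(axis=2)
        mean = s1 / n
        var = s2 / n - mean**2
        return mean, np.clip(var, 0.0, None)

    hm, hv = stats(h_resp)
    em, ev = stats(e_resp)
    # layout: [H means, H variances, E means, E variances], filter-ordered
    return np.concatenate([hm, hv, em, ev], axis=0).transpose(1, 2, 0)


def patch_descriptor(
    h_resp: np.ndarray,
    e_resp: np.ndarray,
    patch_row: int,
    patch_col: int,
    patch_px: int = PATCH_PX,
) -> np.ndarray:
    """Descriptor of a single patch (bounds-checked)."""
    nf, h, w = h_resp.shape
    r0, c0 = patch_row * patch_px, patch_col * patch_px
    if patch_row < 0 or patch_col < 0 or r0 + patch_px > h or c0 + patch_px > w:
        raise ValueError(f"patch ({patch_row}, {patch_col}) out of bounds for {h}x{w} image")
    out = np.empty(4 * nf)
    for offset, resp in ((0, h_resp), (2 * nf, e_resp)):
        win = resp[:, r0 : r0 + patch_px, c0 : c0 + patch_px].astype(np.float64)
        out[offset : offset + nf] = win.mean(axis=(1, 2))
        out[offset + nf : offset + 2 * nf] = win.var(axis=(1, 2))
    return out


def patch_validity(mask: np.ndarray, patch_px: int = PATCH_PX) -> np.ndarray:
    """Boolean validity grid: a patch is invalid when more than half of its
    pixels are background (mask == 0)."""
    m = np.asarray(mask, dtype=bool)
    nr, nc = m.shape[0] // patch_px, m.shape[1] // patch_px
    tissue = m[: nr * patch_px, : nc * patch_px].reshape(nr, patch_px, nc, patch_px)
    tissue_frac = tissue.mean(axis=(1, 3))
    return (1.0 - tissue_frac) <= 0.5
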