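"""Synthetic pseudo-H&E cohorts with controllable two-scale texture.

Real slides are not redistributable, so pipeline behaviour is exercised on
generated mosaics: each image is a white-background frame enclosing a grid
of 480-px motif tiles (the footprint of one L2 window), every tile drawn
from its class's motif mixture.  Within-tile texture (oriented gratings,
band-pass noise, blob fields, with frequencies inside the Gabor bank's
sensitive range) drives L1 coding; the between-tile composition drives L2
coding.  A ``divergence`` knob interpolates the two class mixtures from
identical (no signal) to disjoint motif supports (strong signal).  Stain
concentration fields are pushed through the exact forward of the
deconvolution model (Beer-Lambert with the same stain matrix), plus
optional Gaussian pixel noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from histocode.extract import ImageFeatures, compute_image_features
from histocode.gabor_features import GaborBank
from histocode.stain_prep import default_stain_matrix

__all__ = [
    "Motif",
    "CohortSpec",
    "SyntheticImage",
    "Cohort",
    "default_motifs",
    "render_motif_tile",
    "od_to_rgb",
    "forward_stain",
    "generate_cohort",
    "cohort_features",
    "save_cohort",
]


@dataclass(frozen=True)
class Motif:
    """One local texture pattern with its stain loadings."""

    id: int
    kind: str  # "grating" | "bandpass" | "blobs"
    theta: float = 0.0  # orientation (gratings), radians
    nu: float = 0.375  # spatial frequency, cycles/pixel at the 5x scale
    blob_radius: float = 4.0
    amplitude: float = 0.9  # peak optical-density-scale concentration
    h_weight: float = 1.0
    e_weight: float = 0.3


def default_motifs() -> list[Motif]:
    """Eight motifs; the first four form the positive-class support at full
    divergence, the last four the negative-class support.  Orientations and
    frequencies sit on the Gabor bank's grid so both coding levels see them."""
    return [
        Motif(0, "grating", theta=0.0, nu=3 / 8, h_weight=1.0, e_weight=0.2),
        Motif(1, "grating", theta=np.pi / 4, nu=3 / 4, h_weight=0.3, e_weight=1.0),
        Motif(2, "blobs", blob_radius=3.0, amplitude=1.1, h_weight=1.0, e_weight=0.5),
        Motif(3, "bandpass", nu=3 / 8, h_weight=0.8, e_weight=0.8),
        Motif(4, "grating", theta=np.pi / 2, nu=3 / 8, h_weight=0.2, e_weight=1.0),
        Motif(5, "grating", theta=3 * np.pi / 4, nu=3 / 16, h_weight=1.0, e_weight=0.4),
        Motif(6, "blobs", blob_radius=6.0, amplitude=1.0, h_weight=0.4, e_weight=1.0),
        Motif(7, "bandpass", nu=3 / 16, h_weight=1.0, e_weight=0.2),
    ]


def render_motif_tile(m: Motif, tile_px: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render one motif tile as non-negative (h, e) concentration fields."""
    if tile_px < 32:
        raise ValueError("tile_px must be >= 32")
    if m.kind == "grating":
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y, x = np.mgrid[0:tile_px, 0:tile_px].astype(np.float64)
        base = 0.5 * (1.0 + np.cos(2.0 * np.pi * m.nu * (x * np.cos(m.theta) + y * np.sin(m.theta)) + phase))
    elif m.kind == "bandpass":
        noise = rng.standard_normal((tile_px, tile_px))
        fy = np.fft.fftfreq(tile_px)[:, None]
        fx = np.fft.fftfreq(tile_px)[None, :]
        radius = np.hypot(fy, fx)
        ring = np.exp(-((radius - m.nu) ** 2) / (2 * (m.nu / 4) ** 2))
        filtered = np.fft.ifft2(np.fft.fft2(noise) * ring).real
        sd = filtered.std()
        z = filtered / sd if sd > 0 else filtered
        base = np.clip(0.5 + 0.25 * z, 0.0, 1.0)
    elif m.kind == "blobs":
        density = 1.0 / (12.0 * m.blob_radius**2)  # keeps blobs resolvable
        impulses = (rng.random((tile_px, tile_px)) < density).astype(np.float64)
        fieldv = ndimage.gaussian_filter(impulses, sigma=m.blob_radius, mode="wrap")
        top = fieldv.max()
        base = fieldv / top if top > 0 else fieldv
    else:
        raise ValueError(f"unknown motif kind {m.kind!r}")
    base = m.amplitude * base
    return base * m.h_weight, base * m.e_weight


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of the OD transform: transmitted intensity, rounded to uint8."""
    trans = i0 * np.power(10.0, -np.asarray(od, dtype=np.float64))
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)


def forward_stain(
    h_field: np.ndarray,
    e_field: np.ndarray,
    stain_matrix: np.ndarray | None = None,
    i0: float = 255.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Exact forward of the deconvolution model: OD = h*H_vec + e*E_vec,
    RGB = round(i0 * 10^-OD) plus optional Gaussian pixel noise."""
    if (np.asarray(h_field) < 0).any() or (np.asarray(e_field) < 0).any():
        raise ValueError("concentration fields must be non-negative")
    m = default_stain_matrix() if stain_matrix is None else np.asarray(stain_matrix, dtype=np.float64)
    od = h_field[..., None] * m[0] + e_field[..., None] * m[1]
    trans = i0 * np.power(10.0, -od)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        trans = trans + rng.normal(0.0, noise_sd, size=trans.shape)
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Prevalence defaults to the 20.3% positive fraction of the reference
    cohort; the tile size equals the L2 window footprint so class signal
    exists at exactly the scale the second coding level captures.
    """

    n_images: int = 60
    prevalence: float = 0.203
    image_px: tuple[int, int] = (960, 720)
    motif_tile_px: int = 480
    divergence: float = 1.0
    background_margin_px: int = 48
    noise_sd: float = 2.0
    seed: int = 0
    motifs: list[Motif] = field(default_factory=default_motifs)
    n_positive_specific: int = 4  # first k motifs are the positive support

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must lie in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")

    def class_mixtures(self) -> tuple[np.ndarray, np.ndarray]:
        """Motif mixtures: (1-d) * uniform-over-all + d * uniform-over-support."""
        n = len(self.motifs)
        base = np.full(n, 1.0 / n)
        pos_specific = np.zeros(n)
        pos_specific[: self.n_positive_specific] = 1.0 / self.n_positive_specific
        neg_specific = np.zeros(n)
        neg_specific[self.n_positive_specific :] = 1.0 / (n - self.n_positive_specific)
        d = self.divergence
        return (1 - d) * base + d * pos_specific, (1 - d) * base + d * neg_specific


@dataclass
class SyntheticImage:
    image_id: str
    rgb: np.ndarray  # uint8 (H, W, 3)
    mask: np.ndarray  # bool (H, W)
    label: int
    motif_grid: np.ndarray  # tile motif ids


@dataclass
class Cohort:
    images: list[SyntheticImage]
    manifest: dict

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images], dtype=int)


def _render_image(spec: CohortSpec, index: int, label: int) -> SyntheticImage:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, index]))
    h_px, w_px = spec.image_px
    margin = spec.background_margin_px
    tile = spec.motif_tile_px
    ih, iw = h_px - 2 * margin, w_px - 2 * margin
    if ih <= 0 or iw <= 0:
        raise ValueError("margins leave no tissue interior")
    ntr, ntc = -(-ih // tile), -(-iw // tile)
    pos_mix, neg_mix = spec.class_mixtures()
    mix = pos_mix if label == 1 else neg_mix
    motif_grid = rng.choice(len(spec.motifs), size=(ntr, ntc), p=mix)

    h_field = np.zeros((h_px, w_px))
    e_field = np.zeros((h_px, w_px))
    for i in range(ntr):
        for j in range(ntc):
            th, te = render_motif_tile(spec.motifs[int(motif_grid[i, j])], tile, rng)
            r0, c0 = margin + i * tile, margin + j * tile
            r1, c1 = min(r0 + tile, h_px - margin), min(c0 + tile, w_px - margin)
            h_field[r0:r1, c0:c1] = th[: r1 - r0, : c1 - c0]
            e_field[r0:r1, c0:c1] = te[: r1 - r0, : c1 - c0]
    rgb = forward_stain(h_field, e_field, noise_sd=spec.noise_sd, rng=rng)
    mask = np.zeros((h_px, w_px), dtype=bool)
    mask[margin : h_px - margin, margin : w_px - margin] = True
    rgb[~mask] = 255  # white background frame
    return SyntheticImage(
        image_id=f"synth_{index:04d}", rgb=rgb, mask=mask, label=int(label), motif_grid=motif_grid
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labelled cohort; fully reproducible from the manifest."""
    label_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    labels = (label_rng.random(spec.n_images) < spec.prevalence).astype(int)
    images = [_render_image(spec, i, int(labels[i])) for i in range(spec.n_images)]
    manifest = {
        "seed": spec.seed,
        "n_images": spec.n_images,
        "prevalence": spec.prevalence,
        "image_px": list(spec.image_px),
        "motif_tile_px": spec.motif_tile_px,
        "divergence": spec.divergence,
        "background_margin_px": spec.background_margin_px,
        "noise_sd": spec.noise_sd,
        "images": [
            {
                "image_id": im.image_id,
                "label": im.label,
                "motif_grid": im.motif_grid.tolist(),
                "sha256": hashlib.sha256(im.rgb.tobytes()).hexdigest(),
            }
            for im in images
        ],
    }
    return Cohort(images=images, manifest=manifest)


def cohort_features(
    cohort: Cohort, bank: GaborBank | None = None, patch_px: int = 32
) -> list[ImageFeatures]:
    """Patch-descriptor grids for every image of a cohort (5x scale as-is)."""
    return [
        compute_image_features(
            im.rgb, mask=im.mask, in_mag="5x", bank=bank, image_id=im.image_id, label=im.label, patch_px=patch_px
        )
        for im in cohort.images
    ]


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write images and masks as TIFF plus a labels table and the manifest."""
    import pandas as pd
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in cohort.images:
        tifffile.imwrite(out / f"{im.image_id}.tif", im.rgb)
        tifffile.imwrite(out / f"{im.image_id}_mask.tif", im.mask.astype(np.uint8) * 255)
        rows.append({"image_id": im.image_id, "label": im.label})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
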