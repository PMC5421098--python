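"""Desk-scale study configurations.

The reference configuration (291 slides, K1 = K2 = 128, 10-fold outer CV)
needs a slide archive; the desk-scale preset exercises the identical
pipeline on synthetic cohorts small enough for a single CPU: 60 images of
960x960 px (a 2x2 mosaic of 480-px motif tiles inside a white frame, hence
four L2 windows per image), K1 = K2 = 16 codewords, subset grid
{8, 16, 24, 32}, 3-fold outer cross-validation, and a coarsened (step-4
exponent) hyperparameter lattice.  Everything else — patch and window
geometry, sampling counts, validity rules, RFE, class weighting — is the
reference configuration unchanged.
"""

from __future__ import annotations

from histocode.config import PipelineConfig
from histocode.synthetic import CohortSpec

__all__ = ["desk_scale_config", "desk_scale_spec", "DESK_OUTER_FOLDS"]

DESK_OUTER_FOLDS = 3


def desk_scale_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        k1=16,
        k2=16,
        subset_sizes=(8, 16, 24, 32),
        outer_folds=DESK_OUTER_FOLDS,
        c_grid=tuple(float(2.0**e) for e in range(-5, 16, 4)),
        gamma_grid=tuple(float(2.0**e) for e in range(-15, 4, 4)),
        seed=seed,
    )


def desk_scale_spec(seed: int = 0, divergence: float = 1.0, n_images: int = 60) -> CohortSpec:
    return CohortSpec(n_images=n_images, divergence=divergence, seed=seed, image_px=(960, 720))
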