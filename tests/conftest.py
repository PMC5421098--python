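"""Shared fixtures: a small synthetic cohort reused across test modules.

The mini cohort (15 images, 1024x1024 px, a 2x2 mosaic of 480-px motif
tiles inside a 32-px white frame, disjoint class motif supports) is
expensive enough to build once per session; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from histocode.config import PipelineConfig
from histocode.gabor_features import build_bank
from histocode.synthetic import CohortSpec, cohort_features, generate_cohort

MINI_SEED = 29  # yields 4 positives of 15 at the default prevalence


@pytest.fixture(scope="session")
def bank():
    return build_bank()


@pytest.fixture(scope="session")
def mini_spec() -> CohortSpec:
    return CohortSpec(
        n_images=15,
        image_px=(1024, 1024),  # 2x2 motif tiles inside a 32-px white frame
        background_margin_px=32,
        divergence=1.0,
        seed=MINI_SEED,
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_spec):
    return generate_cohort(mini_spec)


@pytest.fixture(scope="session")
def mini_features(mini_cohort, bank):
    return cohort_features(mini_cohort, bank=bank)


@pytest.fixture(scope="session")
def mini_config() -> PipelineConfig:
    return PipelineConfig(
        k1=8,  # at least one code per motif kind
        k2=4,
        subset_sizes=(4, 8),
        outer_folds=3,
        inner_folds=2,
        c_grid=tuple(float(2.0**e) for e in range(-5, 16, 4)),
        gamma_grid=tuple(float(2.0**e) for e in range(-15, 4, 4)),
        seed=MINI_SEED,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
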