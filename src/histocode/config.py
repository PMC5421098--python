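"""Pipeline configuration: every tunable named by the method, with the
reference defaults, YAML round-tripping and a stable content hash."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "DEFAULT_C_GRID", "DEFAULT_GAMMA_GRID"]

DEFAULT_C_GRID: tuple[float, ...] = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass
class PipelineConfig:
    """All parameters of the coding + classification pipeline.

    The defaults are the reference configuration: 32-px patches, 15x15-patch
    windows, K1 = K2 = 128 codewords, 1000/500 sampled descriptors per image
    at the two levels, feature-subset grid 30..130, 10-fold outer and 5-fold
    inner stratified cross-validation.
    """

    patch_px: int = 32
    window_patches: int = 15
    k1: int = 128
    k2: int = 128
    l1_samples: int = 1000
    l2_samples: int = 500
    kmeans_restarts: int = 5
    subset_sizes: tuple[int, ...] = (30, 50, 70, 90, 110, 130)
    outer_folds: int = 10
    inner_folds: int = 5
    rfe_step: int = 5
    rfe_c: float = 1.0
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    threshold: float = 0.0
    i0: float = 255.0
    sigma_set: tuple[float, ...] = (1.0, float(2.0 * np.sqrt(2.0)))
    theta_set: tuple[float, ...] = tuple(float(k * np.pi / 4) for k in range(4))
    nu_set: tuple[float, ...] = (0.75, 0.375, 0.1875)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.subset_sizes)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("subset_sizes must be strictly increasing")
        if sizes and sizes[-1] > 2 * self.k2:
            raise ValueError("largest subset size exceeds the feature count 2*k2")
        if not (0 < self.patch_px and 0 < self.window_patches):
            raise ValueError("patch_px and window_patches must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
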