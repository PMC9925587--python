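"""Run configuration: YAML-backed settings for the whole pipeline.

One master seed expands to per-stage seeds through a fixed tag scheme
(:func:`derive_seed`), so toggling one stage never reshuffles another's
randomness.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .registration import CpdConfig

# fixed stage tags for seed derivation
SEED_TAGS = {
    "subsample_pass1": 11,
    "subsample_pass2": 12,
    "generator": 21,
    "noise": 22,
    "perturbation": 23,
}


def derive_seed(master_seed: int, tag: str, index: int = 0) -> int:
    """Derive a per-stage 31-bit seed from the master seed and a fixed tag."""
    if tag not in SEED_TAGS:
        raise ParameterError(f"unknown seed tag '{tag}'")
    ss = np.random.SeedSequence([int(master_seed), SEED_TAGS[tag], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CropSettings:
    depth_mm: float = 15.0
    axis_point: list | None = None       # 6-number user override: point + direction
    axis_direction: list | None = None
    mask_band_mm: float = 2.0            # cut-edge exclusion band for masked stats

    def __post_init__(self):
        if self.depth_mm <= 0:
            raise ParameterError("crop depth_mm must be positive")
        if self.mask_band_mm < 0:
            raise ParameterError("mask_band_mm must be non-negative")


@dataclass
class CorrespondenceSettings:
    mode: str = "surface"                # "surface" | "vertex"
    exclusion_spheres: list = field(default_factory=list)  # [{center:[x,y,z], radius}]

    def __post_init__(self):
        if self.mode not in ("surface", "vertex"):
            raise ParameterError(f"unknown correspondence mode '{self.mode}'")


@dataclass
class RunConfig:
    mirror_side: str = "left"
    mirror_plane: list | None = None     # 6-number override: point + normal
    registration: CpdConfig = field(default_factory=CpdConfig)
    crop: CropSettings = field(default_factory=CropSettings)
    correspondence: CorrespondenceSettings = field(default_factory=CorrespondenceSettings)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mirror_side not in ("left", "right"):
            raise ParameterError("mirror_side must be 'left' or 'right'")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "registration" in d and isinstance(d["registration"], dict):
            d["registration"] = CpdConfig(**d["registration"])
        if "crop" in d and isinstance(d["crop"], dict):
            d["crop"] = CropSettings(**d["crop"])
        if "correspondence" in d and isinstance(d["correspondence"], dict):
            d["correspondence"] = CorrespondenceSettings(**d["correspondence"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
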