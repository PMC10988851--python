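"""Run configuration: YAML round trip and deterministic seed fan-out."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Child seed for a named stage: reproducible, decorrelated, < 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs; defaults are the study design.

    The acquisition defaults (25 directions, shells 0/400/800 s/mm²) and
    the cohort defaults (4 groups x 6 timepoints x 6 subjects) match the
    emulated study; ``seed`` fans out deterministically to every
    stochastic stage via :func:`stage_seed`.
    """

    seed: int = 0
    n_directions: int = 25
    shells: tuple = (0.0, 400.0, 800.0)
    scheme_seed: int | None = None  # defaults to stage_seed(seed, "scheme")
    phantom_shape: tuple = (20, 20, 10)
    margins: tuple = (1, 2, 1)
    region_boxes: dict | None = None
    s0: float = 1000.0
    snr: float = 25.0
    estimator: str = "wls"
    quadrature: str = "sphere"
    n_subjects: int = 6
    rater_sd_fraction: float = 0.2
    fibrosis_r: float = 0.687
    slice_axis: int = 1
    n_slices: int = 3
    out_dir: str = "renodki_run"

    def __post_init__(self) -> None:
        if self.estimator.lower() not in ("ols", "wls"):
            raise ConfigError(f"estimator must be 'ols' or 'wls', got {self.estimator!r}")
        if self.quadrature not in ("sphere", "acquisition"):
            raise ConfigError(
                f"quadrature must be 'sphere' or 'acquisition', got {self.quadrature!r}"
            )
        if self.snr <= 0:
            raise ConfigError("snr must be positive")

    @property
    def rician_sigma(self) -> float:
        return self.s0 / self.snr

    def seed_for(self, stage: str) -> int:
        if stage == "scheme" and self.scheme_seed is not None:
            return self.scheme_seed
        return stage_seed(self.seed, stage)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shells", "phantom_shape", "margins"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self
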