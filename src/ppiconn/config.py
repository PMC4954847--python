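"""Run configuration: one structured YAML file governing every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import MissingInputError
from .tfce import TFCEParams


@dataclass
class RunConfig:
    """All pipeline knobs with their paradigm defaults.

    Paths are resolved relative to the config file's directory when loaded
    from YAML.  A single ``rng_seed`` drives every stochastic stage through
    derived per-stage streams, making a rerun with the same config
    bit-identical.
    """

    manifest: str
    brain_mask: str
    reference_mask: str
    out_dir: str
    seed_masks: dict[str, str] = field(default_factory=dict)
    # behavior scoring
    startle_mv_threshold: float = 30.0
    ppi_pct_threshold: float = 15.0
    # imaging
    fwhm_mm: float = 1.5
    ttest_on_smoothed: bool = False
    smooth_seed_extract: bool = True
    sign_convention: str = "ppi_minus_background"
    # inference
    tfce_h: float = 2.0
    tfce_e: float = 0.5
    tfce_dh: float = 0.1
    connectivity: int = 26
    n_perm: int = 1000
    alpha_corrected: float = 0.01
    alpha_uncorrected: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.startle_mv_threshold <= 0 or self.ppi_pct_threshold <= 0:
            raise ValueError("behavioral thresholds must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        for alpha in (self.alpha_corrected, self.alpha_uncorrected):
            if not 0.0 < alpha < 1.0:
                raise ValueError("significance levels must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.tfce_params  # validate

    @property
    def tfce_params(self) -> TFCEParams:
        return TFCEParams(
            H=self.tfce_h, E=self.tfce_e, dh=self.tfce_dh, connectivity=self.connectivity
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = {"manifest", "brain_mask", "reference_mask", "out_dir"} - set(raw)
        if missing:
            raise MissingInputError(f"config missing required keys: {sorted(missing)}")
        return cls(**dict(raw))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise MissingInputError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        config = cls.from_dict(raw)
        # resolve relative paths against the config file location
        base = path.parent
        for attr in ("manifest", "brain_mask", "reference_mask", "out_dir"):
            setattr(config, attr, str((base / getattr(config, attr)).resolve()))
        config.seed_masks = {
            name: str((base / p).resolve()) for name, p in config.seed_masks.items()
        }
        return config
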