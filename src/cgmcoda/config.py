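"""Pipeline configuration with defaults matching the study settings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .coordinates import DEFAULT_SBP, validate_sbp


@dataclass
class ZeroConfig:
    method: str = "lrem"            # or "multiplicative"
    dl_fraction: float | list = 1.0  # fraction of the 5-min cadence, scalar or 5-vector
    delta_frac: float = 0.65
    tol: float = 1e-8
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.method not in ("lrem", "multiplicative"):
            raise ValueError("zeros.method must be 'lrem' or 'multiplicative'")


@dataclass
class PipelineConfig:
    """Settings for the full extraction/categorization pipeline.

    Defaults reproduce the study conditions: consensus range boundaries
    54/70/180/250 mg/dL, anchors every 6 h, a 70% per-block validity
    threshold, the clinical SBP, and 25 random k-means restarts.
    """

    boundaries: tuple = (54.0, 70.0, 180.0, 250.0)
    anchors: tuple = ("00:00", "06:00", "12:00", "18:00")
    validity_threshold: float = 0.70
    cadence: int = 5
    zeros: ZeroConfig = field(default_factory=ZeroConfig)
    sbp: list = field(default_factory=lambda: DEFAULT_SBP.tolist())
    k_24h: int = 4
    k_6h: int = 4
    n_init: int = 25
    seed: int | None = None
    priors: str = "empirical"

    def __post_init__(self) -> None:
        validate_sbp(np.asarray(self.sbp))
        if not 0 < self.validity_threshold <= 1:
            raise ValueError("validity_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "zeros" in d:
            d["zeros"] = ZeroConfig(**d["zeros"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["boundaries"] = list(self.boundaries)
        d["anchors"] = list(self.anchors)
        return d

    @property
    def hash(self) -> str:
        """Short digest identifying the configuration in output artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
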