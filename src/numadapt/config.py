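"""Resolved pipeline configuration: thresholds, model mode, HRF, seeds.

The analysis thresholds default to the protocol's printed values
(eccentricity below 1 deg, monotonic-analysis variance explained at least
0.1, tuned-analysis variance explained at least 0.2, map-example variance
explained 0.1) and every run logs the fully resolved configuration and a
short hash of it, which is stamped into all output tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .hrf import HrfSpec
from .synth import GroundTruthConfig

__all__ = ["Thresholds", "BehaviorConfig", "PipelineConfig"]


@dataclass
class Thresholds:
    ecc_max_deg: float = 1.0
    monotonic_r2: float = 0.1
    tuned_r2: float = 0.2
    map_example_r2: float = 0.1


@dataclass
class BehaviorConfig:
    n_participants: int = 10
    n_trials: int = 100
    observer_sigma: float = 1.5
    between_sd: float = 0.5
    pse_means: dict = field(
        default_factory=lambda: {"low_adaptor": 12.0, "no_adaptor": 10.0,
                                 "high_adaptor": 8.0}
    )
    placement: str = "staircase"


@dataclass
class PipelineConfig:
    mode: str = "log_power"  # or "log_numerosity"
    power_method: str = "amplitude"  # Fourier aggregation; or "energy"
    thresholds: Thresholds = field(default_factory=Thresholds)
    hrf: HrfSpec = field(default_factory=HrfSpec)
    synth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("log_power", "log_numerosity"):
            raise ValueError(f"unknown model mode {self.mode!r}")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "hrf" in kwargs:
            h = dict(kwargs["hrf"])
            if h.get("user_kernel") is not None:
                h["user_kernel"] = tuple(h["user_kernel"])
            kwargs["hrf"] = HrfSpec(**h)
        if "synth" in kwargs:
            s = dict(kwargs["synth"])
            for k in ("hemispheres", "maps", "ecc_range"):
                if k in s and s[k] is not None:
                    s[k] = tuple(s[k])
            if s.get("condition_gains") is not None:
                s["condition_gains"] = {
                    m: tuple(g) for m, g in s["condition_gains"].items()
                }
            if "runs_per_condition" in s:
                s["runs_per_condition"] = dict(s["runs_per_condition"])
            kwargs["synth"] = GroundTruthConfig(**s)
        if "behavior" in kwargs:
            kwargs["behavior"] = BehaviorConfig(**kwargs["behavior"])
        return cls(**kwargs)

    def provenance(self) -> dict:
        from . import __version__

        return {"numadapt_version": __version__, "config_hash": self.hash(),
                "seed": self.seed}
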