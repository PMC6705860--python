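"""Run configuration: defaults, YAML loading, validation.

Every analysis default that the measurement protocol fixes is encoded here:
11-point / 3rd-order sliding polynomial smoothing, 30-s curvature low-pass,
70-80 grayscale ruffle band, 10-point boxcar, 15-s frame interval.  Other
defaults are artifact choices, flagged as such in the audit log.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError
from .synthetic import MotilityParams, WaveParams

__all__ = ["AcquisitionConfig", "TrackingConfig", "WavesConfig",
           "CorrelationConfig", "RunConfig"]

log = logging.getLogger(__name__)

# default -> provenance ("protocol" = stated by the measurement procedure,
# "artifact" = implementation choice)
_DEFAULT_SOURCES = {
    "acquisition.frame_interval_s": "protocol (15-s time-lapse interval)",
    "acquisition.pixel_size_um": "artifact default",
    "tracking.window": "protocol (11-point sliding window)",
    "tracking.order": "protocol (3rd-order polynomial)",
    "tracking.cutoff_s": "protocol (30-s curvature low-pass)",
    "tracking.threshold": "artifact default (per-frame Otsu)",
    "waves.band_low": "protocol (grayscale 70)",
    "waves.band_high": "protocol (grayscale 80)",
    "waves.boxcar_n": "protocol (10-point boxcar)",
    "correlation.max_lag_min": "artifact default",
    "correlation.detrend": "artifact default",
}


@dataclass
class AcquisitionConfig:
    pixel_size_um: float = 0.5
    frame_interval_s: float = 15.0

    def validate(self):
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("acquisition metadata must be positive")


@dataclass
class TrackingConfig:
    threshold: float | None = None  # None -> per-frame Otsu
    window: int = 11
    order: int = 3
    cutoff_s: float = 30.0
    noise_floor_factor: float = 1.5
    k_min: float = 0.03
    alpha_min: float = 3.0

    def validate(self):
        if self.window % 2 == 0 or self.window < 3 or self.order >= self.window:
            raise ParameterError("need odd window >= 3 and order < window")
        if self.cutoff_s <= 0:
            raise ParameterError("cutoff_s must be > 0")


@dataclass
class WavesConfig:
    band_low: float = 70.0
    band_high: float = 80.0
    boxcar_n: int = 10
    line: tuple | None = None      # ((x0,y0),(x1,y1)) um
    roi: tuple | None = None       # (x0,y0,x1,y1) um
    min_prominence: float = 0.1

    def validate(self):
        if self.band_low > self.band_high:
            raise ParameterError("band_low must not exceed band_high")
        if self.boxcar_n < 1:
            raise ParameterError("boxcar_n must be >= 1")


@dataclass
class CorrelationConfig:
    max_lag_min: float = 10.0
    detrend: str = "none"
    detrend_param: float | None = None

    def validate(self):
        if self.max_lag_min <= 0:
            raise ParameterError("max_lag_min must be > 0")
        if self.detrend not in ("none", "linear", "boxcar_subtract"):
            raise ParameterError(f"unknown detrend mode {self.detrend!r}")


@dataclass
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    waves: WavesConfig = field(default_factory=WavesConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    motility: MotilityParams = field(default_factory=MotilityParams)
    wave_params: WaveParams = field(default_factory=WaveParams)
    input_stack: str | None = None  # path; None -> simulate
    seed: int = 0
    output_dir: str = "gliawave_out"

    def validate(self):
        for sub in (self.acquisition, self.tracking, self.waves, self.correlation):
            sub.validate()
        # dataclass __post_init__ already validated motility/wave params
        return self

    def audit_defaults(self) -> None:
        """Log every default with its provenance, once per run."""
        for key, src in _DEFAULT_SOURCES.items():
            section, name = key.split(".")
            attr = {"acquisition": self.acquisition, "tracking": self.tracking,
                    "waves": self.waves, "correlation": self.correlation}[section]
            log.info("default %s = %r  [%s]", key, getattr(attr, name), src)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        kwargs = {}
        for name, sub_cls in (
            ("acquisition", AcquisitionConfig), ("tracking", TrackingConfig),
            ("waves", WavesConfig), ("correlation", CorrelationConfig),
            ("motility", MotilityParams), ("wave_params", WaveParams),
        ):
            if name in d:
                block = d.pop(name)
                if not isinstance(block, dict):
                    raise ParameterError(f"config section {name!r} must be a mapping")
                valid = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(block) - valid
                if unknown:
                    raise ParameterError(f"unknown keys in {name}: {sorted(unknown)}")
                kwargs[name] = sub_cls(**block)
        valid_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid_top
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
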