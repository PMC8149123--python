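"""Run configuration: defaults, YAML loading, validation.

Defaults mirror the constants the analysis is defined with: measurement plane
0.9 um below the apical surface, 30 s rolling window for expansion rates,
8 um^2 punctum gate, 10 shared pixels for a colocalization call, Costes
PSF = 3 px with 10 randomizations.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


def _from_dict(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} in section '{path}'")
    return cls(**data)


@dataclass(frozen=True)
class SegmentationConfig:
    plane_offset_um: float = 0.9       # measurement plane below apical surface
    detect_factor: float = 2.0         # foreground/background ratio for plane detection
    use_projection: bool = False       # max-project the offset plane +/- 1
    background_percentile: float = 5.0
    smooth_sigma_px: float = 1.0
    min_area_um2: float = 2.0
    max_displacement_um: float = 2.0
    max_gap_frames: int = 1

    def validate(self) -> None:
        if self.plane_offset_um < 0:
            raise ConfigError("segmentation.plane_offset_um must be >= 0")
        if not 0 <= self.background_percentile < 50:
            raise ConfigError("segmentation.background_percentile must be in [0, 50)")
        if self.smooth_sigma_px < 0 or self.min_area_um2 < 0:
            raise ConfigError("segmentation smoothing/min-area must be >= 0")
        if self.max_displacement_um <= 0 or self.max_gap_frames < 0:
            raise ConfigError("segmentation tracking limits out of range")


@dataclass(frozen=True)
class DynamicsConfig:
    window_s: float = 30.0             # rolling expansion-rate window
    lookback_s: float = 180.0          # alignment: initiation is anchor - lookback
    theta_grow: float = 0.01           # normalized rate threshold, expansion
    theta_stab: float = 0.005          # |rate| threshold, stabilization
    theta_ecc: float = 0.6             # eccentricity threshold, elongation
    theta_het: float = 0.75            # heterogeneity fraction of running max, fragmentation
    fit_span_s: float = 60.0           # expansion-fit span
    x_unit: str = "frame"              # growth-fit X unit: "frame" (5 s) or "s"

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("dynamics.window_s must be > 0")
        if self.lookback_s < 0 or self.fit_span_s <= 0:
            raise ConfigError("dynamics lookback/fit span out of range")
        if not (0 < self.theta_ecc < 1 and 0 < self.theta_het < 1):
            raise ConfigError("dynamics.theta_ecc and theta_het must be in (0, 1)")
        if self.theta_grow <= 0 or self.theta_stab < 0:
            raise ConfigError("dynamics rate thresholds out of range")
        if self.x_unit not in ("frame", "s"):
            raise ConfigError("dynamics.x_unit must be 'frame' or 's'")


@dataclass(frozen=True)
class FrapConfig:
    rescale_prebleach: bool = False
    min_samples: int = 8

    def validate(self) -> None:
        if self.min_samples < 4:
            raise ConfigError("frap.min_samples must be >= 4")


@dataclass(frozen=True)
class ColocConfig:
    min_area_um2: float = 8.0          # strict punctum gate
    min_shared_px: int = 10            # colocalization call
    psf_px: int = 3                    # Costes block size
    n_randomizations: int = 10

    def validate(self) -> None:
        if self.min_area_um2 < 0:
            raise ConfigError("coloc.min_area_um2 must be >= 0")
        if self.min_shared_px < 1:
            raise ConfigError("coloc.min_shared_px must be >= 1")
        if self.psf_px < 1 or self.n_randomizations < 1:
            raise ConfigError("coloc.psf_px and n_randomizations must be >= 1")


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    equal_var: bool = True             # Student's (pooled) t by default; False = Welch

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("stats.alpha must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, grouped by stage, plus the run seed."""

    seed: int = 0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    frap: FrapConfig = field(default_factory=FrapConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> "RunConfig":
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        for section in (self.segmentation, self.dynamics, self.frap, self.coloc, self.stats):
            section.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "dynamics": DynamicsConfig,
    "frap": FrapConfig,
    "coloc": ColocConfig,
    "stats": StatsConfig,
}


def config_from_dict(data: dict | None) -> RunConfig:
    """Build a validated RunConfig from a (possibly partial) nested dict."""
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    if "seed" in data:
        kwargs["seed"] = data["seed"]
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section '{name}' must be a mapping")
        kwargs[name] = _from_dict(cls, section, name)
    return RunConfig(**kwargs).validate()


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file, merge with defaults, and validate.

    An empty or missing-path (None) config yields all defaults. Unknown keys
    and out-of-range values raise :class:`ConfigError` naming the key.
    """
    if path is None:
        return RunConfig().validate()
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root of {path} must be a mapping")
    return config_from_dict(data)
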