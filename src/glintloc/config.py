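"""Experiment configuration: schema, defaults, YAML loading and validation.

A single structured file captures every tunable of a simulation run: the
direction-grid size, flutter rates, echo strengths, noise levels, call
duration, Monte-Carlo realizations, glint-spacing modes, the synthetic-beam
and pinna-motion parameters, and the root seed.  Unknown keys are rejected
and violations are reported by key name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .noise import NoiseSpec

__all__ = ["BeamConfig", "PinnaConfig", "ExperimentConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class BeamConfig:
    """Parametric directivity defaults for emission and the two ears.

    Ear boresights are offset laterally (mirrored in azimuth) and slightly
    upward so the two ears' gain fields differ — binaural disparity is what
    carries azimuth information.
    """

    emission_beamwidth_deg: float = 60.0
    ear_beamwidth_deg: float = 60.0
    ear_boresight_az_deg: float = 20.0
    ear_boresight_el_deg: float = 10.0
    sidelobe_level_db: float | None = None
    sidelobe_offset_deg: float = 60.0

    def __post_init__(self) -> None:
        if self.emission_beamwidth_deg <= 0:
            raise ValueError("emission_beamwidth_deg must be positive")
        if self.ear_beamwidth_deg <= 0:
            raise ValueError("ear_beamwidth_deg must be positive")
        if self.sidelobe_level_db is not None and self.sidelobe_level_db > 0:
            raise ValueError("sidelobe_level_db must be <= 0")


@dataclass(frozen=True)
class PinnaConfig:
    """Pinna-stroke arc (degrees), stroke resolution and azimuth phase pairing."""

    arc_az_deg: float = 15.0
    arc_el_deg: float = 15.0
    n_positions: int = 100
    azimuth_phase: str = "anti"

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.azimuth_phase not in ("anti", "in"):
            raise ValueError("azimuth_phase must be 'anti' or 'in'")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full run configuration with desk-scale defaults.

    Defaults: 500-direction grid, flutter rates 20-200 Hz, echo strengths
    0-70 dB in 10 dB steps, noise channels sigma = 1.5 / 3.0 / 6.0 dB
    (dominant-glint, intermediate, whole-echo), 50 ms call, 20 Monte-Carlo
    realizations per cell.
    """

    grid_size: int = 500
    flutter_rates_hz: tuple[float, ...] = (20.0, 40.0, 60.0, 100.0, 150.0, 200.0)
    echo_strengths_db: tuple[float, ...] = tuple(float(a) for a in range(0, 71, 10))
    sigma_levels_db: tuple[float, ...] = (1.5, 3.0, 6.0)
    call_duration_s: float = 0.050
    n_realizations: int = 20
    modes: tuple[str, ...] = ("regular",)
    seed: int = 0
    sigma_db: float = 1.5
    rho_lr: float = 0.9
    floor_db: float = 0.0
    low_sigma_db: float = 1.5
    high_sigma_db: float = 6.0
    map_echo_strength_db: float = 30.0
    central_region_deg: float = 30.0
    f_base_hz: float = 200.0
    beams: BeamConfig = field(default_factory=BeamConfig)
    pinnae: PinnaConfig = field(default_factory=PinnaConfig)

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for name in ("flutter_rates_hz", "echo_strengths_db", "sigma_levels_db", "modes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(f <= 0 for f in self.flutter_rates_hz):
            raise ValueError("flutter_rates_hz must be positive")
        if self.call_duration_s <= 0:
            raise ValueError("call_duration_s must be positive")
        if self.sigma_db < 0 or any(s < 0 for s in self.sigma_levels_db):
            raise ValueError("sigma must be non-negative")
        if not (0.0 <= self.rho_lr < 1.0):
            raise ValueError("rho_lr must lie in [0, 1)")
        for m in self.modes:
            if m not in ("regular", "random"):
                raise ValueError(f"modes entries must be 'regular' or 'random', got {m!r}")

    def noise(self, sigma_db: float | None = None) -> NoiseSpec:
        """NoiseSpec for a given channel sigma (default: the configured one)."""
        return NoiseSpec(
            sigma_db=self.sigma_db if sigma_db is None else sigma_db,
            rho_lr=self.rho_lr,
            floor_db=self.floor_db,
        )


_NESTED = {"beams": BeamConfig, "pinnae": PinnaConfig}
_LIST_KEYS = {"flutter_rates_hz", "echo_strengths_db", "sigma_levels_db", "modes"}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML configuration; missing keys take defaults, unknown keys raise.

    An empty (or absent) file yields the default configuration.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"configuration root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _NESTED:
            if not isinstance(value, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            cls = _NESTED[key]
            bad = set(value) - set(cls.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"invalid value in section {key!r}: {exc}") from exc
        elif key in _LIST_KEYS:
            kwargs[key] = tuple(value) if isinstance(value, (list, tuple)) else (value,)
        else:
            kwargs[key] = value
    try:
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def dump_config(cfg: ExperimentConfig) -> dict:
    """Configuration as a plain, YAML-serializable dict (normalized form)."""
    d = asdict(cfg)
    for key in _LIST_KEYS:
        d[key] = list(d[key])
    return d
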