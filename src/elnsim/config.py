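"""Simulation configuration: all model parameters with their defaults.

Units are minutes and micrometers throughout (all rates in the reference
parameter table are per-minute).  Parameters the table does not fix --
the time step, the Gaussian width of an RFC chemokine source, the APC_M
activation capacity, the half-saturation of the ELN bias, the inactive-T
flee-bias mode and scale, the APC_M dispersal halo, the optional
tumor-bias range/decay, and the far-field removal horizon -- are
gap-filling defaults; their values and the calibration that froze them
are documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SimConfig", "load_config"]


@dataclass(frozen=True)
class SimConfig:
    # tumor growth (µm/min; kill rate µm/min per TIL)
    growth_rate: float = 0.2
    kill_rate: float = 0.0015
    initial_radius: float = 200.0

    # motility (µm/min)
    apc_off_kinetic_speed: float = 12.0
    apc_off_tactic_speed: float = 4.0
    apc_m_kinetic_speed: float = 20.0
    apc_m_tactic_speed: float = 10.0
    t_kinetic_speed: float = 10.0
    t_tactic_speed: float = 100.0

    # influx (cells/min) and initial counts
    influx_rate_apc: float = 0.84
    influx_rate_t: float = 0.1
    initial_apc: int = 10
    initial_t: int = 30
    influx_mode: str = "poisson"  # or "deterministic"

    # interaction geometry (µm) and lifetimes (min)
    activation_distance: float = 15.0
    til_lifespan_min: float = 1440.0
    annulus_inner_offset: float = -500.0
    annulus_outer_offset: float = 1500.0

    # ELN patch and chemokine field
    rfc_count: int = 0
    rfc_patch_radius: float = 750.0
    tumor_eln_distance: float = 2000.0
    gaussian_sigma: float = 1000.0
    gaussian_amplitude: float = 1.0
    eln_bias_khalf: float | None = None  # default: |grad| at 1 sigma
    apc_m_capacity: int = 3
    inactive_t_bias: str = "away_from_tumor"  # or "none"
    inactive_t_bias_scale: float = 0.5  # flee-bias scale in [0, 1]
    away_bias_margin_um: float | None = 12500.0  # APC_M flee range; None = everywhere
    toward_bias_offset_um: float = 1500.0
    toward_bias_decay_um: float | None = None  # None = no decay

    # far-field removal horizon for outward-drifting cells (µm)
    escape_radius_um: float | None = 60000.0

    # numerics
    dt_min: float = 1.0
    total_time_min: float = 43200.0  # 30 days
    record_every_min: float = 60.0
    field_grid_spacing: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("growth_rate", "kill_rate", "initial_radius",
                     "apc_off_kinetic_speed", "apc_off_tactic_speed",
                     "apc_m_kinetic_speed", "apc_m_tactic_speed",
                     "t_kinetic_speed", "t_tactic_speed",
                     "influx_rate_apc", "influx_rate_t",
                     "activation_distance", "til_lifespan_min",
                     "rfc_patch_radius", "tumor_eln_distance",
                     "gaussian_sigma", "gaussian_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.annulus_outer_offset <= self.annulus_inner_offset:
            raise ValueError("annulus outer offset must exceed inner offset")
        if self.dt_min <= 0 or self.total_time_min <= 0:
            raise ValueError("dt_min and total_time_min must be positive")
        if self.initial_apc < 0 or self.initial_t < 0 or self.rfc_count < 0:
            raise ValueError("cell counts must be non-negative")
        if self.apc_m_capacity < 1:
            raise ValueError("apc_m_capacity must be at least 1")
        if self.influx_mode not in ("poisson", "deterministic"):
            raise ValueError("influx_mode must be 'poisson' or 'deterministic'")
        if self.inactive_t_bias not in ("none", "away_from_tumor"):
            raise ValueError(
                "inactive_t_bias must be 'none' or 'away_from_tumor'")
        if not 0.0 <= self.inactive_t_bias_scale <= 1.0:
            raise ValueError("inactive_t_bias_scale must lie in [0, 1]")
        if (self.escape_radius_um is not None and self.escape_radius_um
                < 2 * (self.tumor_eln_distance + self.rfc_patch_radius)):
            raise ValueError("escape_radius_um must sit well beyond the ELN patch")
        for name in ("toward_bias_decay_um", "away_bias_margin_um"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive or null")
        if self.toward_bias_offset_um < 0:
            raise ValueError("toward_bias_offset_um must be non-negative")

    @property
    def khalf(self) -> float:
        """ELN-bias half-saturation gradient magnitude.

        Defaults to the gradient magnitude one sigma away from a single
        source: A * exp(-1/2) / sigma.
        """
        if self.eln_bias_khalf is not None:
            return self.eln_bias_khalf
        return self.gaussian_amplitude * math.exp(-0.5) / self.gaussian_sigma

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def replace(self, **updates) -> "SimConfig":
        return dataclasses.replace(self, **updates)

    def with_overrides(self, pairs: list[str]) -> "SimConfig":
        """Apply ``key=value`` strings (the CLI ``--set`` flag)."""
        updates = {}
        fields = {f.name: f for f in dataclasses.fields(self)}
        for pair in pairs:
            if "=" not in pair:
                raise ValueError(f"override must look like key=value: {pair!r}")
            key, raw = pair.split("=", 1)
            key = key.strip()
            if key not in fields:
                raise ValueError(f"unknown config key: {key}")
            updates[key] = _coerce(raw.strip(), getattr(self, key))
        return self.replace(**updates)

    def digest(self) -> str:
        """Short stable hash of the full configuration."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:10]


def _coerce(raw: str, current):
    if isinstance(current, bool):
        return raw.lower() in ("true", "1", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float) or current is None:
        return float(raw)
    return raw


def load_config(path: str | Path | None = None,
                overrides: list[str] | None = None) -> SimConfig:
    cfg = SimConfig.from_yaml(path) if path else SimConfig()
    if overrides:
        cfg = cfg.with_overrides(list(overrides))
    return cfg
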