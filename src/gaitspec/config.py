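"""Run configuration: defaults, YAML round-trip, and schema validation.

The defaults reproduce the study settings end to end: an 80 Hz hip-worn
device, 10 s non-overlapping windows, a 0-39.9 Hz spectral grid at 0.1 Hz,
cadence search in 1.2-4.0 Hz, a 546-point order grid on [0.3, 5.75], a
harmonic Gaussian basis at multiples 0.5-5.5 of the cadence, and penalty
weight a = 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError


@dataclass
class PreprocessConfig:
    """Constants of the spectral pre-processing stage."""

    fs: float = 80.0            # sampling frequency, Hz
    window_s: float = 10.0      # non-overlapping window length, s
    freq_max: float = 39.9      # top of the spectral grid, Hz
    freq_step: float = 0.1      # spectral grid spacing, Hz
    smin: float = 1.2           # cadence search lower bound, Hz
    smax: float = 4.0           # cadence search upper bound, Hz
    order_min: float = 0.3      # order-grid lower endpoint (cadence multiples)
    order_max: float = 5.75     # order-grid upper endpoint
    order_points: int = 546     # order-grid size
    scale_method: str = "grid"  # "grid": value nearest order 1.0; "local_max": peak near 1.0


@dataclass
class BasisConfig:
    """Harmonic Gaussian basis and decomposition penalty."""

    center_min: float = 0.5
    center_max: float = 5.5
    center_step: float = 0.5
    sd: float = 0.08            # Gaussian sd in order units; near-orthogonal columns
    a: float = 2.0              # penalty weight off the informative subspace
    orth_threshold: float = 0.05


@dataclass
class SimulateConfig:
    """Synthetic cohort defaults (sizes match the study cohort)."""

    n_subjects: int = 46
    duration_s: float = 60.0
    cadence_min: float = 1.6
    cadence_max: float = 2.5
    noise_sd: float = 0.05
    sigma_eps: float = 0.5
    beta_bump_center: float = 2.5
    beta_bump_height: float = 50.0
    half_harmonics: bool = True


@dataclass
class RunConfig:
    """Aggregate configuration for the simulate -> preprocess -> fit chain."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    basis: BasisConfig = field(default_factory=BasisConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def validate(self) -> "RunConfig":
        p = self.preprocess
        if p.fs <= 0 or p.window_s <= 0:
            raise ConfigError("fs and window_s must be positive")
        if not (0 < p.smin < p.smax):
            raise ConfigError("need 0 < smin < smax")
        if not (0 < p.order_min < p.order_max):
            raise ConfigError("need 0 < order_min < order_max")
        if p.order_points < 2:
            raise ConfigError("order_points must be at least 2")
        if p.scale_method not in ("grid", "local_max"):
            raise ConfigError(f"unknown scale_method {p.scale_method!r}")
        if self.basis.sd <= 0:
            raise ConfigError("basis sd must be positive")
        if self.basis.a <= 0:
            raise ConfigError("penalty weight a must be positive")
        if self.simulate.n_subjects < 1:
            raise ConfigError("n_subjects must be at least 1")
        return self


def _from_mapping(cls, data: dict[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, rejecting unknown keys; ``None`` gives defaults."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {"preprocess", "basis", "simulate", "seed", "verbosity"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg = RunConfig(
        preprocess=_from_mapping(PreprocessConfig, raw.get("preprocess", {}), "preprocess"),
        basis=_from_mapping(BasisConfig, raw.get("basis", {}), "basis"),
        simulate=_from_mapping(SimulateConfig, raw.get("simulate", {}), "simulate"),
        seed=int(raw.get("seed", 0)),
        verbosity=int(raw.get("verbosity", 1)),
    )
    return cfg.validate()
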