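"""Run configuration: one validated object covering every pipeline stage.

Configs load from nested dicts (YAML-friendly); unknown keys anywhere are
rejected with the offending names, and each threshold is checked against
its documented domain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .synthetic_data import ScenarioConfig
from .types import ConfigurationError


@dataclass
class ScreeningConfig:
    tol_ppm: float = 5.0
    isofit_min: float = 50.0       # isotope-pattern fit threshold, percent
    polarity: str = "positive"     # selects [M+H]+ or [M-H]-

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ConfigurationError("tol_ppm must be positive")
        if not (0.0 <= self.isofit_min <= 100.0):
            raise ConfigurationError("isofit_min must lie in [0, 100]")
        if self.polarity not in ("positive", "negative"):
            raise ConfigurationError(
                "polarity must be 'positive' or 'negative'")


@dataclass
class ClusteringConfig:
    k: int = 3
    log_transform: bool = False
    nondetect_policy: str = "exclude"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.nondetect_policy not in ("exclude", "half_loq", "zero"):
            raise ConfigurationError(
                f"unknown nondetect_policy {self.nondetect_policy!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class NontargetConfig:
    min_intensity: float = 1.0e5
    isofit_min: float = 0.90       # isotope similarity, fraction
    alpha: float = 0.05
    match_min: float = 70.0
    tol_ppm: float = 5.0

    def __post_init__(self) -> None:
        if self.min_intensity <= 0:
            raise ConfigurationError("min_intensity must be positive")
        if not (0.0 < self.isofit_min <= 1.0):
            raise ConfigurationError("isofit_min must lie in (0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not (0.0 <= self.match_min <= 100.0):
            raise ConfigurationError("match_min must lie in [0, 100]")
        if self.tol_ppm <= 0:
            raise ConfigurationError("tol_ppm must be positive")


@dataclass
class KineticsConfig:
    min_pairs: int = 5
    min_r2: float = 0.90
    intercept: bool = True

    def __post_init__(self) -> None:
        if self.min_pairs < 2:
            raise ConfigurationError("min_pairs must be >= 2")
        if not (0.0 <= self.min_r2 < 1.0):
            raise ConfigurationError("min_r2 must lie in [0, 1)")


@dataclass
class RiskConfig:
    aggregation: str = "max_endpoint"
    n_draws: int = 500

    def __post_init__(self) -> None:
        if self.aggregation not in ("max_endpoint", "total"):
            raise ConfigurationError(
                f"unknown aggregation {self.aggregation!r}")
        if self.n_draws < 100:
            raise ConfigurationError("n_draws must be >= 100")


@dataclass
class RunConfig:
    seed: int = 0
    simulate: ScenarioConfig = field(default_factory=ScenarioConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    nontarget: NontargetConfig = field(default_factory=NontargetConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)

    def hash(self) -> str:
        """Stable hash of the full parameter set."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, path="")


def _build(dc_type, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path or 'config'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        where = f" in {path}" if path else ""
        raise ConfigurationError(f"unknown config keys{where}: {unknown}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _SUBCONFIGS.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, path=f"{path}.{name}".strip("."))
        else:
            kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc


_SUBCONFIGS = {
    "simulate": ScenarioConfig,
    "screening": ScreeningConfig,
    "clustering": ClusteringConfig,
    "nontarget": NontargetConfig,
    "kinetics": KineticsConfig,
    "risk": RiskConfig,
}
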