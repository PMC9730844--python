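"""Domain types shared across the streamscreen pipeline.

Lightweight validated dataclasses; tabular payloads (measurements, feature
intensities, discharge series) live in pandas DataFrames and are documented
in the functions that produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


class StreamScreenError(Exception):
    """Base class for streamscreen errors."""


class InvalidArgument(StreamScreenError, ValueError):
    """A function argument violates its documented domain."""


class ConfigurationError(StreamScreenError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class InsufficientData(StreamScreenError):
    """Too few observations to carry out an estimate."""


class SingularFit(StreamScreenError):
    """Regression design is degenerate (zero predictor variance)."""


@dataclass(frozen=True)
class WatershedSite:
    """One stream site with the watershed attribute vector used as
    clustering covariates.

    Attributes are the anthropogenic descriptors of the drained watershed:
    percent agricultural and developed land use, septic-system density
    (count/km^2), number of concentrated animal feeding operations (CAFOs),
    summed municipal wastewater treatment plant capacity (m^3/d), road
    density (km/km^2), runoff propensity index, and population density
    (persons/km^2).
    """

    site_id: str
    ag_pct: float
    dev_pct: float
    septic_density: float
    cafo_count: int
    wwtp_capacity: float
    road_density: float
    rpi: float
    pop_density: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ag_pct <= 100.0 and 0.0 <= self.dev_pct <= 100.0):
            raise InvalidArgument("land-use percentages must lie in [0, 100]")
        if self.ag_pct + self.dev_pct > 100.0 + 1e-9:
            raise InvalidArgument("ag_pct + dev_pct must not exceed 100")
        for name in ("septic_density", "cafo_count", "wwtp_capacity",
                     "road_density", "rpi", "pop_density"):
            if getattr(self, name) < 0:
                raise InvalidArgument(f"{name} must be nonnegative")


#: Attribute columns of the site table, in canonical order.
ATTRIBUTE_COLUMNS = (
    "ag_pct", "dev_pct", "septic_density", "cafo_count",
    "wwtp_capacity", "road_density", "rpi", "pop_density",
)

#: Attributes that define the agricultural source signature (cluster A).
AGRICULTURAL_ATTRIBUTES = ("ag_pct", "cafo_count", "rpi")
#: Attributes that define the developed/septic source signature (cluster B).
DEVELOPED_ATTRIBUTES = ("septic_density", "dev_pct", "road_density", "pop_density")
#: Attribute that defines the wastewater source signature (cluster C).
WASTEWATER_ATTRIBUTES = ("wwtp_capacity",)


@dataclass(frozen=True)
class DeploymentWindow:
    """Passive-sampler deployment interval in integer days."""

    site_id: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day - self.start_day <= 0:
            raise InvalidArgument("deployment duration must be positive")

    @property
    def duration(self) -> int:
        return self.end_day - self.start_day


@dataclass
class GroundTruth:
    """Everything the synthetic generator knows that the analysis must
    recover: source-cluster membership, true sampling rates, the latent
    water-concentration field, planted nontarget feature ids, effect sizes
    and noise scales."""

    source_cluster: dict[str, str] = field(default_factory=dict)
    true_r_s: dict[str, float] = field(default_factory=dict)
    # site -> compound -> daily c_w series (list of ng/L)
    c_w: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    planted_nontarget_ids: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)
    indicator_compounds: list[str] = field(default_factory=list)
    alpha_log10: dict[str, float] = field(default_factory=dict)
    loq_ng_per_l: dict[str, float] = field(default_factory=dict)
    compound_formula: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [c for c, r in self.true_r_s.items() if r <= 0]
        if bad:
            raise InvalidArgument(f"true sampling rates must be positive: {bad}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SuspectCompound:
    """Entry of the suspect database used for exact-mass matching."""

    name: str
    formula: str
    monoisotopic_mass: float
    compound_class: str = "PHAR"   # PHAR | PEST | PCHI | TP
    is_indicator: bool = False

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise InvalidArgument("monoisotopic mass must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Internal-standard calibration: area ratio = slope * conc + intercept."""

    compound: str
    internal_standard: str
    levels: tuple  # ((concentration, area_ratio), ...)
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.levels) < 3:
            raise InvalidArgument("calibration needs at least 3 levels")
        if self.slope <= 0:
            raise InvalidArgument("calibration slope must be positive")


@dataclass(frozen=True)
class SamplingRateEstimate:
    """Field sampling rate of one compound from cross-site regression of
    POCIS daily accumulated mass on grab concentration."""

    compound: str
    r_s: float                 # L/d
    se_r_s: float              # L/d
    r_squared: float
    n_pairs: int
    intercept: float = 0.0
    with_intercept: bool = True
    valid: bool = True


@dataclass(frozen=True)
class TwaConcentration:
    """Time-weighted average water concentration over a deployment."""

    site_id: str
    compound: str
    c_twa: float               # ng/L
    sd: float                  # ng/L

    def __post_init__(self) -> None:
        if self.c_twa < 0:
            raise InvalidArgument("TWA concentration must be nonnegative")


@dataclass(frozen=True)
class LoadEstimate:
    """Daily average in-stream load of one compound at one site."""

    site_id: str
    compound: str
    method: str                # "TWA" | "grab"
    start_day: int
    end_day: int
    load: float                # g/d
    sd: float = 0.0            # g/d

    def __post_init__(self) -> None:
        if self.load < 0:
            raise InvalidArgument("load must be nonnegative")


@dataclass
class RiskResult:
    """Site-level screening mixture risk under concentration addition
    (cumulative exposure-activity ratio) and response addition
    (multi-substance potentially affected fraction)."""

    site_id: str
    sum_ear: float
    mspaf: float
    ear_contributions: dict[str, float] = field(default_factory=dict)
    paf_contributions: dict[str, float] = field(default_factory=dict)
    sum_ear_sd: float = 0.0
    mspaf_sd: float = 0.0
    ear_flag: bool = False     # sum_ear >= 0.001
    mspaf_flag: bool = False   # mspaf >= 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.mspaf <= 1.0):
            raise InvalidArgument("msPAF must lie in [0, 1]")
        if self.sum_ear < 0:
            raise InvalidArgument("cumulative EAR must be nonnegative")
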