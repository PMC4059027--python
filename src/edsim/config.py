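"""ED environment configuration: schema, validation, and packaged profiles.

An :class:`EDConfig` fully parameterizes one emergency-department
environment: bed counts by treatment area (Main Treatment Area with a
reservable trauma subset, plus an optional Fast Track), provider and nurse
staffing (constant counts or an optional per-hour duty schedule),
acuity-resolved arrival intensities, Gamma duration specifications for every
process step, per-acuity waiting tolerances (left-without-being-seen
thresholds), a patient complexity model (test-ordering probabilities,
order-review cycles, admit rates), and the boarding-delay distribution.

Two calibrated profiles ship with the package:

``national``
    A nationally average U.S. ED: 32 MTA beds, no Fast Track, 3 physicians,
    8 nurses, 155 arrivals/day, 12.8% admit rate, 1.63 h mean boarding.
``academic``
    An average U.S. academic ED: 41 MTA + 6 FT beds, 4 physicians, 1 PA,
    13 nurses, 195 arrivals/day, a more acute patient mix, 25.8% admit rate,
    4.43 h mean boarding, and longer lab/imaging turnaround.

Configs are stored as YAML; ``serialize`` produces a canonical form (sorted
keys) that round-trips losslessly through :func:`load_config`.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ACUITIES",
    "ConfigError",
    "DurationSpec",
    "ArrivalProfile",
    "AcuityComplexity",
    "ComplexityModel",
    "EDConfig",
    "load_config",
    "loads_config",
    "builtin_profile",
    "validate_config",
    "serialize_config",
]

#: ESI acuity levels; 1 is the highest acuity and the ordering is total.
ACUITIES = (1, 2, 3, 4, 5)

#: Provider classes that travel between rooms.
PROVIDER_CLASSES = ("physician", "pa", "nurse")


class ConfigError(ValueError):
    """Raised for schema violations; the message names the offending field."""


@dataclass(frozen=True)
class DurationSpec:
    """Mean/variance (minutes, minutes^2) of a Gamma-distributed duration.

    The pair fully determines the Gamma distribution via
    shape = mean^2/variance and scale = variance/mean.  ``variance == 0``
    denotes a degenerate point mass at the mean (used by deterministic test
    fixtures); ``mean == 0`` denotes an instantaneous step.
    """

    mean: float
    variance: float

    def __post_init__(self):
        if not (self.mean >= 0) and not math.isinf(self.mean):
            raise ConfigError(f"duration mean must be >= 0, got {self.mean}")
        if not (self.variance >= 0):
            raise ConfigError(f"duration variance must be >= 0, got {self.variance}")

    @classmethod
    def from_mean_cv(cls, mean: float, cv: float) -> "DurationSpec":
        """Build a spec from a mean and coefficient of variation."""
        return cls(mean=mean, variance=(cv * mean) ** 2)

    def scaled(self, factor: float) -> "DurationSpec":
        """Scale the mean by ``factor`` keeping the coefficient of variation."""
        return DurationSpec(self.mean * factor, self.variance * factor**2)


@dataclass(frozen=True)
class ArrivalProfile:
    """Hourly arrival intensities (arrivals/hour), one 24-vector per acuity."""

    hourly_rate: dict  # acuity -> np.ndarray of 24 rates

    def rate_for(self, esi: int) -> np.ndarray:
        return self.hourly_rate[esi]

    @property
    def daily_total(self) -> float:
        """Expected arrivals per day, integrating the step intensity."""
        return float(sum(r.sum() for r in self.hourly_rate.values()))

    @classmethod
    def from_shape(cls, daily_mean, acuity_fractions, hourly_shape) -> "ArrivalProfile":
        shape = np.asarray(hourly_shape, dtype=float)
        if shape.size != 24:
            raise ConfigError("arrivals.hourly_shape must have 24 entries")
        if np.any(shape < 0) or shape.sum() <= 0:
            raise ConfigError("arrivals.hourly_shape must be nonnegative, nonzero")
        shape = shape / shape.sum()
        rates = {
            a: daily_mean * float(acuity_fractions[a]) * shape for a in ACUITIES
        }
        return cls(hourly_rate=rates)


@dataclass(frozen=True)
class AcuityComplexity:
    """Per-acuity treatment complexity and disposition parameters."""

    p_lab: float
    p_imaging: float
    cycle_continuation: float  # geometric continuation prob for extra cycles
    max_cycles: int
    admit_rate: float


@dataclass(frozen=True)
class ComplexityModel:
    """Acuity-resolved complexity, with a declared overall admit rate.

    The acuity-weighted mean of the per-acuity admit rates (weights = the
    arrival acuity fractions) must reproduce ``overall_admit_rate``.
    """

    overall_admit_rate: float
    per_acuity: dict  # acuity -> AcuityComplexity


@dataclass
class EDConfig:
    """Complete parameterization of one ED environment."""

    name: str
    mta_beds: int
    trauma_beds: int  # subset of the MTA, reservable for ESI-1 with preemption
    ft_beds: int
    physicians: int
    pas: int
    nurses: int
    physician_schedule: list | None  # optional 24-vector of on-duty counts
    pa_schedule: list | None
    nurse_schedule: list | None
    nurse_ratio: dict  # acuity -> patients per nurse
    daily_mean_arrivals: float
    acuity_fractions: dict  # acuity -> fraction of arrivals
    hourly_shape: list  # 24 relative weights of the diurnal arrival pattern
    esi2_bypass_fraction: float
    boarding_nurse_factor: float  # fraction of nursing a boarded patient holds
    triage_duration: DurationSpec
    nurse_assessment: DurationSpec
    physician_assessment: DurationSpec
    review_assessment: DurationSpec
    lab_tat: DurationSpec
    imaging_tat: DurationSpec
    discharge_instruction_delay: DurationSpec
    boarding_delay: DurationSpec
    lwbs_tolerance: dict  # acuity -> DurationSpec
    travel_time_mean: dict  # provider class -> minutes
    complexity: ComplexityModel
    arrival_profile: ArrivalProfile = field(init=False, repr=False)

    def __post_init__(self):
        self.arrival_profile = ArrivalProfile.from_shape(
            self.daily_mean_arrivals, self.acuity_fractions, self.hourly_shape
        )

    # -- staffing -----------------------------------------------------------
    def schedule_for(self, provider_class: str) -> np.ndarray:
        """On-duty head count per hour-of-day for a provider class."""
        base = {"physician": self.physicians, "pa": self.pas, "nurse": self.nurses}
        sched = {
            "physician": self.physician_schedule,
            "pa": self.pa_schedule,
            "nurse": self.nurse_schedule,
        }[provider_class]
        if sched is None:
            return np.full(24, base[provider_class], dtype=int)
        return np.asarray(sched, dtype=int)

    def staffed_hours_per_day(self, provider_class: str) -> float:
        return float(self.schedule_for(provider_class).sum())

    def nurse_demand(self, esi: int) -> float:
        """Fraction of one nurse a bedded patient of this acuity occupies."""
        return 1.0 / float(self.nurse_ratio[esi])

    @property
    def total_beds(self) -> int:
        return self.mta_beds + self.ft_beds

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def dspec(d: DurationSpec) -> dict:
            return {"mean": float(d.mean), "variance": float(d.variance)}

        return {
            "name": self.name,
            "beds": {
                "mta": self.mta_beds,
                "trauma": self.trauma_beds,
                "ft": self.ft_beds,
            },
            "staff": {
                "physicians": self.physicians,
                "pas": self.pas,
                "nurses": self.nurses,
                "physician_schedule": _maybe_list(self.physician_schedule),
                "pa_schedule": _maybe_list(self.pa_schedule),
                "nurse_schedule": _maybe_list(self.nurse_schedule),
            },
            "nurse_ratio": {a: float(self.nurse_ratio[a]) for a in ACUITIES},
            "arrivals": {
                "daily_mean": float(self.daily_mean_arrivals),
                "acuity_fractions": {
                    a: float(self.acuity_fractions[a]) for a in ACUITIES
                },
                "hourly_shape": [float(x) for x in self.hourly_shape],
            },
            "esi2_bypass_fraction": float(self.esi2_bypass_fraction),
            "boarding_nurse_factor": float(self.boarding_nurse_factor),
            "durations": {
                "triage": dspec(self.triage_duration),
                "nurse_assessment": dspec(self.nurse_assessment),
                "physician_assessment": dspec(self.physician_assessment),
                "review_assessment": dspec(self.review_assessment),
                "lab_tat": dspec(self.lab_tat),
                "imaging_tat": dspec(self.imaging_tat),
                "discharge_delay": dspec(self.discharge_instruction_delay),
                "boarding": dspec(self.boarding_delay),
            },
            "lwbs_tolerance": {a: dspec(self.lwbs_tolerance[a]) for a in ACUITIES},
            "travel_time_mean": {
                c: float(self.travel_time_mean[c]) for c in PROVIDER_CLASSES
            },
            "complexity": {
                "overall_admit_rate": float(self.complexity.overall_admit_rate),
                "per_acuity": {
                    a: {
                        "p_lab": float(c.p_lab),
                        "p_imaging": float(c.p_imaging),
                        "cycle_continuation": float(c.cycle_continuation),
                        "max_cycles": int(c.max_cycles),
                        "admit_rate": float(c.admit_rate),
                    }
                    for a, c in (
                        (a, self.complexity.per_acuity[a]) for a in ACUITIES
                    )
                },
            },
        }

    def copy(self) -> "EDConfig":
        return loads_config(serialize_config(self))


def _maybe_list(x):
    return None if x is None else [int(v) for v in x]


# ---------------------------------------------------------------------------
# Loading and strict schema checking
# ---------------------------------------------------------------------------

_DURATION_KEYS = (
    "triage",
    "nurse_assessment",
    "physician_assessment",
    "review_assessment",
    "lab_tat",
    "imaging_tat",
    "discharge_delay",
    "boarding",
)


def _require(mapping: dict, keys, section: str) -> None:
    missing = [k for k in keys if k not in mapping]
    extra = [k for k in mapping if k not in keys]
    if missing:
        raise ConfigError(f"{section}: missing field(s) {missing}")
    if extra:
        raise ConfigError(f"{section}: unknown field(s) {extra}")


def _acuity_map(raw: dict, section: str) -> dict:
    try:
        out = {int(k): raw[k] for k in raw}
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{section}: acuity keys must be integers") from e
    if sorted(out) != list(ACUITIES):
        raise ConfigError(f"{section}: must map exactly acuities 1..5")
    return out


def _duration(raw: dict, section: str) -> DurationSpec:
    _require(raw, ("mean", "variance"), section)
    try:
        return DurationSpec(float(raw["mean"]), float(raw["variance"]))
    except ConfigError as e:
        raise ConfigError(f"{section}: {e}") from e


def _count(value, section: str) -> int:
    iv = int(value)
    if iv != value or iv < 0:
        raise ConfigError(f"{section}: must be a nonnegative integer, got {value}")
    return iv


def loads_config(text: str) -> "EDConfig":
    """Parse an ED configuration from YAML text (strict schema)."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _require(
        raw,
        (
            "name",
            "beds",
            "staff",
            "nurse_ratio",
            "arrivals",
            "esi2_bypass_fraction",
            "boarding_nurse_factor",
            "durations",
            "lwbs_tolerance",
            "travel_time_mean",
            "complexity",
        ),
        "config",
    )
    _require(raw["beds"], ("mta", "trauma", "ft"), "beds")
    _require(
        raw["staff"],
        (
            "physicians",
            "pas",
            "nurses",
            "physician_schedule",
            "pa_schedule",
            "nurse_schedule",
        ),
        "staff",
    )
    _require(raw["arrivals"], ("daily_mean", "acuity_fractions", "hourly_shape"), "arrivals")
    _require(raw["durations"], _DURATION_KEYS, "durations")
    _require(raw["complexity"], ("overall_admit_rate", "per_acuity"), "complexity")

    for cls in ("physician", "pa", "nurse"):
        if cls not in raw["travel_time_mean"]:
            raise ConfigError(f"travel_time_mean: missing class '{cls}'")

    per_ac = _acuity_map(raw["complexity"]["per_acuity"], "complexity.per_acuity")
    complexity = ComplexityModel(
        overall_admit_rate=float(raw["complexity"]["overall_admit_rate"]),
        per_acuity={
            a: AcuityComplexity(
                p_lab=float(c["p_lab"]),
                p_imaging=float(c["p_imaging"]),
                cycle_continuation=float(c["cycle_continuation"]),
                max_cycles=int(c["max_cycles"]),
                admit_rate=float(c["admit_rate"]),
            )
            for a, c in per_ac.items()
        },
    )

    def sched(key):
        s = raw["staff"][key]
        if s is None:
            return None
        s = list(s)
        if len(s) != 24:
            raise ConfigError(f"staff.{key}: schedule must have 24 entries")
        return [_count(v, f"staff.{key}") for v in s]

    cfg = EDConfig(
        name=str(raw["name"]),
        mta_beds=_count(raw["beds"]["mta"], "beds.mta"),
        trauma_beds=_count(raw["beds"]["trauma"], "beds.trauma"),
        ft_beds=_count(raw["beds"]["ft"], "beds.ft"),
        physicians=_count(raw["staff"]["physicians"], "staff.physicians"),
        pas=_count(raw["staff"]["pas"], "staff.pas"),
        nurses=_count(raw["staff"]["nurses"], "staff.nurses"),
        physician_schedule=sched("physician_schedule"),
        pa_schedule=sched("pa_schedule"),
        nurse_schedule=sched("nurse_schedule"),
        nurse_ratio=_acuity_map(raw["nurse_ratio"], "nurse_ratio"),
        daily_mean_arrivals=float(raw["arrivals"]["daily_mean"]),
        acuity_fractions=_acuity_map(raw["arrivals"]["acuity_fractions"], "arrivals.acuity_fractions"),
        hourly_shape=[float(x) for x in raw["arrivals"]["hourly_shape"]],
        esi2_bypass_fraction=float(raw["esi2_bypass_fraction"]),
        boarding_nurse_factor=float(raw["boarding_nurse_factor"]),
        triage_duration=_duration(raw["durations"]["triage"], "durations.triage"),
        nurse_assessment=_duration(raw["durations"]["nurse_assessment"], "durations.nurse_assessment"),
        physician_assessment=_duration(raw["durations"]["physician_assessment"], "durations.physician_assessment"),
        review_assessment=_duration(raw["durations"]["review_assessment"], "durations.review_assessment"),
        lab_tat=_duration(raw["durations"]["lab_tat"], "durations.lab_tat"),
        imaging_tat=_duration(raw["durations"]["imaging_tat"], "durations.imaging_tat"),
        discharge_instruction_delay=_duration(raw["durations"]["discharge_delay"], "durations.discharge_delay"),
        boarding_delay=_duration(raw["durations"]["boarding"], "durations.boarding"),
        lwbs_tolerance={
            a: _duration(d, f"lwbs_tolerance.{a}")
            for a, d in _acuity_map(raw["lwbs_tolerance"], "lwbs_tolerance").items()
        },
        travel_time_mean={c: float(raw["travel_time_mean"][c]) for c in PROVIDER_CLASSES},
        complexity=complexity,
    )
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("; ".join(violations))
    return cfg


def load_config(path) -> "EDConfig":
    """Load and validate an ED configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def serialize_config(cfg: EDConfig) -> str:
    """Serialize a config to its canonical YAML form (sorted keys)."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True, default_flow_style=False)


def canonical_form(text: str) -> str:
    """Canonical YAML form of raw config text (for round-trip checks)."""
    return yaml.safe_dump(yaml.safe_load(text), sort_keys=True, default_flow_style=False)


def builtin_profile(name: str) -> "EDConfig":
    """Return one of the packaged, calibrated environment profiles.

    ``"national"`` is the nationally average ED; ``"academic"`` the average
    academic ED.
    """
    if name not in ("national", "academic"):
        raise KeyError(f"unknown builtin profile {name!r}; use 'national' or 'academic'")
    text = (
        importlib.resources.files("edsim") / "profiles" / f"{name}.yaml"
    ).read_text(encoding="utf-8")
    return loads_config(text)


# ---------------------------------------------------------------------------
# Validation (violations are returned, not raised)
# ---------------------------------------------------------------------------

def validate_config(cfg: EDConfig) -> list[str]:
    """Check every EDConfig invariant; returns a list of violation strings."""
    v: list[str] = []

    def prob(x, name):
        if not (0.0 <= x <= 1.0):
            v.append(f"{name}: probability {x} outside [0, 1]")

    for fname in ("mta_beds", "trauma_beds", "ft_beds", "physicians", "pas", "nurses"):
        if getattr(cfg, fname) < 0:
            v.append(f"{fname}: negative count")
    if cfg.trauma_beds > cfg.mta_beds:
        v.append(f"trauma_beds: {cfg.trauma_beds} exceeds mta_beds {cfg.mta_beds}")
    if cfg.ft_beds > 0:
        pa_cap = cfg.staffed_hours_per_day("pa")
        if pa_cap <= 0:
            v.append("ft_beds: Fast Track enabled but no PA staffing (FT is PA-staffed)")

    prob(cfg.esi2_bypass_fraction, "esi2_bypass_fraction")
    prob(cfg.boarding_nurse_factor, "boarding_nurse_factor")

    fr_sum = sum(cfg.acuity_fractions[a] for a in ACUITIES)
    if abs(fr_sum - 1.0) > 1e-9:
        v.append(f"arrivals.acuity_fractions: sum {fr_sum} != 1")
    for a in ACUITIES:
        if cfg.acuity_fractions[a] < 0:
            v.append(f"arrivals.acuity_fractions.{a}: negative")
        if cfg.nurse_ratio[a] <= 0:
            v.append(f"nurse_ratio.{a}: must be positive")

    total = cfg.arrival_profile.daily_total
    if abs(total - cfg.daily_mean_arrivals) > 1e-9:
        v.append(
            f"arrival_profile: daily integral {total} != declared mean "
            f"{cfg.daily_mean_arrivals}"
        )

    weighted = sum(
        cfg.acuity_fractions[a] * cfg.complexity.per_acuity[a].admit_rate
        for a in ACUITIES
    )
    if abs(weighted - cfg.complexity.overall_admit_rate) > 1e-6:
        v.append(
            "complexity: acuity-weighted admit rate "
            f"{weighted:.8f} != declared overall {cfg.complexity.overall_admit_rate}"
        )
    for a in ACUITIES:
        c = cfg.complexity.per_acuity[a]
        prob(c.p_lab, f"complexity.{a}.p_lab")
        prob(c.p_imaging, f"complexity.{a}.p_imaging")
        prob(c.cycle_continuation, f"complexity.{a}.cycle_continuation")
        prob(c.admit_rate, f"complexity.{a}.admit_rate")
        if c.max_cycles < 0:
            v.append(f"complexity.{a}.max_cycles: negative")

    for cls in PROVIDER_CLASSES:
        if cfg.travel_time_mean[cls] < 0:
            v.append(f"travel_time_mean.{cls}: negative")

    for key, sched in (
        ("physician_schedule", cfg.physician_schedule),
        ("pa_schedule", cfg.pa_schedule),
        ("nurse_schedule", cfg.nurse_schedule),
    ):
        if sched is not None and len(sched) != 24:
            v.append(f"staff.{key}: must have 24 entries")

    return v
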