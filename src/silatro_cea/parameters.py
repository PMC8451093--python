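"""Parameter ledger for the recurrent acute throat infection (ATI) model.

The decision model is driven entirely by a structured configuration file that
encodes, for each age group (children 6 to <12 years; adolescents/adults 12+),
every input of the analysis: unit costs in 2019 euros, per-cycle transition
probabilities, conditional ATI event intensities, one-way sensitivity bounds,
and the sampling distribution each parameter takes in probabilistic
sensitivity analysis (PSA).

Distribution kinds
------------------
``fixed``  degenerate (no PSA uncertainty)
``beta``   Beta(alpha, beta_param), support [0, 1] — probabilities
``gamma``  Gamma(shape=alpha, rate=rate), mean alpha/rate — costs, intensities
``pert``   (modified) PERT on [min, max] with most-likely value ``mode`` and
           shape constant ``shape_pert`` (default 4); sampled as a scaled Beta

The shipped default configuration reproduces the published input ledger for
both age groups.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ARMS",
    "AGE_GROUPS",
    "ARM_SPECIFIC",
    "REQUIRED_PARAMETERS",
    "ConfigError",
    "ValidationError",
    "DistributionSpec",
    "ModelParameter",
    "CalibrationConstants",
    "EconomicSettings",
    "ParameterSet",
    "dist_mean",
    "dist_sample",
    "owsa_range",
    "load_config",
    "load_parameters",
    "load_settings",
    "save_config",
    "default_config_path",
]

ARMS = ("intervention", "usual_care")
AGE_GROUPS = ("children", "adults_adolescents")

_ARM_SUFFIX = {"intervention": "int", "usual_care": "uc"}

#: ledger entries that exist once per arm; stored under ``<name>_int`` / ``<name>_uc``
ARM_SPECIFIC = ("p_ati", "n_ati_given_ati", "p_antibiotics", "days_out_per_cycle")

PROBABILITY_PARAMETERS = frozenset(
    {
        "p_ati_int",
        "p_ati_uc",
        "p_antibiotics_int",
        "p_antibiotics_uc",
        "p_surgery_if_eligible",
        "p_death_cycle",
        "p_death_surgery",
    }
)

NONNEGATIVE_PARAMETERS = frozenset(
    {
        "therapy_cost_month",
        "surgery_cost",
        "antibiotics_course_cost",
        "dispensing_fee",
        "gp_consult_cost",
        "daily_productivity_cost",
        "gp_travel_hours",
        "hospital_travel_hours",
        "days_out_per_cycle_int",
        "days_out_per_cycle_uc",
        "discount_costs",
        "discount_outcomes",
        "prior_atis",
        "n_ati_given_ati_int",
        "n_ati_given_ati_uc",
    }
)

REQUIRED_PARAMETERS = tuple(sorted(PROBABILITY_PARAMETERS | NONNEGATIVE_PARAMETERS))

_DIST_KINDS = ("fixed", "beta", "gamma", "pert")

#: relative gap between a PSA distribution's analytic mean and the deterministic
#: value above which a warning is emitted (some published rows are slightly off)
MEAN_CONSISTENCY_TOL = 0.02


class ConfigError(ValueError):
    """Malformed configuration file (parse/schema problem, names the key)."""


class ValidationError(ValueError):
    """A parameter violates an invariant; message lists offending parameters."""


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling law attached to one model parameter."""

    kind: str = "fixed"
    value: float | None = None
    alpha: float | None = None
    beta_param: float | None = None
    rate: float | None = None
    min: float | None = None
    mode: float | None = None
    max: float | None = None
    shape_pert: float = 4.0

    def validate(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "fixed":
            if self.value is None:
                raise ValidationError("fixed distribution requires 'value'")
        elif self.kind == "beta":
            if not (self.alpha and self.alpha > 0 and self.beta_param and self.beta_param > 0):
                raise ValidationError("beta requires alpha > 0 and beta_param > 0")
        elif self.kind == "gamma":
            if not (self.alpha and self.alpha > 0 and self.rate and self.rate > 0):
                raise ValidationError("gamma requires alpha > 0 and rate > 0")
        elif self.kind == "pert":
            if self.min is None or self.mode is None or self.max is None:
                raise ValidationError("pert requires min, mode and max")
            if not (self.min < self.mode < self.max):
                raise ValidationError("pert requires min < mode < max")
            if self.shape_pert <= 0:
                raise ValidationError("pert shape constant must be > 0")

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        self.validate()
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "beta":
            return self.alpha / (self.alpha + self.beta_param)
        if self.kind == "gamma":
            return self.alpha / self.rate
        # pert
        return (self.min + self.shape_pert * self.mode + self.max) / (self.shape_pert + 2.0)

    def _pert_shapes(self) -> tuple[float, float]:
        span = self.max - self.min
        a = 1.0 + self.shape_pert * (self.mode - self.min) / span
        b = 1.0 + self.shape_pert * (self.max - self.mode) / span
        return a, b

    def sample(self, rng: np.random.Generator) -> float:
        """One draw; support respected (beta in [0,1], gamma >= 0, pert in [min, max])."""
        if self.kind == "fixed":
            return float(self.value)
        if self.kind == "beta":
            return float(rng.beta(self.alpha, self.beta_param))
        if self.kind == "gamma":
            return float(rng.gamma(self.alpha, 1.0 / self.rate))
        a, b = self._pert_shapes()
        return float(self.min + (self.max - self.min) * rng.beta(a, b))

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        for key in ("value", "alpha", "beta_param", "rate", "min", "mode", "max"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        if self.kind == "pert" and self.shape_pert != 4.0:
            d["shape_pert"] = self.shape_pert
        return d


def dist_mean(dist: DistributionSpec) -> float:
    """Analytic mean of a :class:`DistributionSpec`."""
    return dist.mean()


def dist_sample(dist: DistributionSpec, rng: np.random.Generator) -> float:
    """One reproducible draw from ``dist`` using the supplied generator."""
    return dist.sample(rng)


@dataclass(frozen=True)
class ModelParameter:
    """One ledger row: deterministic value, one-way bounds, PSA distribution."""

    name: str
    value: float
    low: float | None = None
    high: float | None = None
    dist: DistributionSpec | None = None
    units: str = ""
    source: str = ""

    @property
    def is_probability(self) -> bool:
        return self.name in PROBABILITY_PARAMETERS

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid); warn on
        mild PSA-mean inconsistency."""
        problems = []
        if self.is_probability and not 0.0 <= self.value <= 1.0:
            problems.append(f"{self.name}: probability {self.value} outside [0, 1]")
        if self.name in NONNEGATIVE_PARAMETERS and self.value < 0:
            problems.append(f"{self.name}: negative value {self.value}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.value <= self.high):
                problems.append(
                    f"{self.name}: value {self.value} outside bounds [{self.low}, {self.high}]"
                )
        if self.dist is not None:
            try:
                self.dist.validate()
            except ValidationError as exc:
                problems.append(f"{self.name}: {exc}")
            else:
                if self.dist.kind != "fixed" and self.value != 0:
                    gap = abs(self.dist.mean() - self.value) / abs(self.value)
                    if gap > MEAN_CONSISTENCY_TOL:
                        warnings.warn(
                            f"{self.name}: PSA distribution mean {self.dist.mean():.5g} "
                            f"deviates {gap:.1%} from deterministic value {self.value:.5g}",
                            stacklevel=2,
                        )
        return problems


def owsa_range(p: ModelParameter) -> tuple[float, float]:
    """One-way sensitivity bounds: the ledger's printed bounds when present,
    otherwise +/-50% of the deterministic value; probabilities clamped to [0, 1]."""
    if p.low is not None and p.high is not None:
        lo, hi = float(p.low), float(p.high)
    else:
        lo, hi = 0.5 * p.value, 1.5 * p.value
    if p.is_probability:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


@dataclass(frozen=True)
class CalibrationConstants:
    """Accrual constants that are not printed as ledger rows.

    ``gp_visits_per_ati`` and ``gp_baseline_visits_per_cycle`` are calibration:
    they are fixed so that both arms' GP-consultation and travel components of
    the published cost breakdown are matched simultaneously (ATI sufferers
    both present with a suspected infection and return for a follow-up).
    """

    gp_visits_per_ati: float = 2.0
    gp_baseline_visits_per_cycle: float = 0.239
    hourly_wage: float = 24.78  # EUR/hour, all-worker mean, 2019
    hours_per_workday: float = 7.1
    surgery_recovery_days_adult: float = 10.0  # working days (2 weeks)
    surgery_recovery_days_child: float = 5.0  # informal-care days (1 week)
    discount_convention: str = "per_cycle"  # or "annual_step"
    include_dispensing_fee: bool = False  # add EUR 5/course on top of the printed price

    def validate(self) -> None:
        numeric = (
            self.gp_visits_per_ati,
            self.gp_baseline_visits_per_cycle,
            self.hourly_wage,
            self.hours_per_workday,
            self.surgery_recovery_days_adult,
            self.surgery_recovery_days_child,
        )
        if any(v < 0 for v in numeric):
            raise ValidationError("calibration constants must be >= 0")
        if self.discount_convention not in ("per_cycle", "annual_step"):
            raise ValidationError(
                f"discount_convention must be 'per_cycle' or 'annual_step', "
                f"got {self.discount_convention!r}"
            )


def _default_wtp_grid(wtp_max: float = 2000.0, wtp_step: float = 10.0) -> tuple[float, ...]:
    n = int(round(wtp_max / wtp_step))
    return tuple(float(i) * wtp_step for i in range(n + 1))


@dataclass(frozen=True)
class EconomicSettings:
    """Run-level settings: cycle structure, horizon, discounting, WTP grid.

    One model cycle is 4 months (8 weeks of adjuvant treatment followed by
    8 weeks of observation): 3 cycles per year, 6 over the 2-year horizon.
    ``discount_rate_costs``/``discount_rate_outcomes`` of ``None`` mean "use
    the ledger rows ``discount_costs``/``discount_outcomes``"; an explicit
    number (e.g. 0.0) overrides the ledger, which is how scenario analyses
    switch discounting off.
    """

    cycles_per_year: int = 3
    horizon_cycles: int = 6
    discount_rate_costs: float | None = None
    discount_rate_outcomes: float | None = None
    wtp_grid: tuple[float, ...] = field(default_factory=_default_wtp_grid)

    def validate(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.cycles_per_year < 1:
            raise ValidationError("cycles_per_year must be >= 1")
        for r in (self.discount_rate_costs, self.discount_rate_outcomes):
            if r is not None and r < 0:
                raise ValidationError("discount rates must be >= 0")
        if len(self.wtp_grid) == 0:
            raise ValidationError("wtp_grid must be non-empty")
        if any(b < a for a, b in zip(self.wtp_grid, self.wtp_grid[1:])):
            raise ValidationError("wtp_grid must be non-decreasing")

    def digest(self) -> str:
        payload = repr(
            (
                self.cycles_per_year,
                self.horizon_cycles,
                self.discount_rate_costs,
                self.discount_rate_outcomes,
                self.wtp_grid,
            )
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class ParameterSet:
    """The complete, validated ledger for one age group.

    Arm-specific rows (``p_ati``, ``n_ati_given_ati``, ``p_antibiotics``,
    ``days_out_per_cycle``) are stored with ``_int``/``_uc`` suffixes and
    resolved through :meth:`arm_value`.
    """

    age_group: str
    params: dict[str, ModelParameter]
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )

    def __getitem__(self, name: str) -> ModelParameter:
        return self.params[name]

    def value(self, name: str) -> float:
        return self.params[name].value

    def arm_value(self, base_name: str, arm: str) -> float:
        """Resolve an arm-specific row (``p_ati`` etc.) for ``arm``; plain rows
        fall through to their single value."""
        if arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {arm!r}")
        if base_name in ARM_SPECIFIC:
            return self.value(f"{base_name}_{_ARM_SUFFIX[arm]}")
        return self.value(base_name)

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.params))

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Copy of the set with one deterministic value replaced (bounds and
        distribution untouched; no re-validation — used by sensitivity/PSA)."""
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        new = dict(self.params)
        new[name] = replace(new[name], value=float(value))
        return ParameterSet(self.age_group, new, self.calibration)

    def digest(self) -> str:
        payload = repr(
            (self.age_group, tuple((n, self.params[n].value) for n in self.names()))
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.params]
        if missing:
            raise ValidationError(f"missing required parameters: {', '.join(missing)}")
        problems: list[str] = []
        for p in self.params.values():
            problems.extend(p.validate())
        if problems:
            raise ValidationError("invalid parameters: " + "; ".join(problems))
        self.calibration.validate()


# ---------------------------------------------------------------------------
# configuration I/O


def default_config_path() -> Path:
    """Path of the packaged default configuration (the published ledger)."""
    return Path(str(resources.files("silatro_cea") / "data" / "default_config.yaml"))


def _parse_dist(name: str, raw: Mapping) -> DistributionSpec:
    if not isinstance(raw, Mapping) or "kind" not in raw:
        raise ConfigError(f"{name}.dist must be a mapping with a 'kind' key")
    known = {"kind", "value", "alpha", "beta_param", "rate", "min", "mode", "max", "shape_pert"}
    extra = set(raw) - known
    if extra:
        raise ConfigError(f"{name}.dist has unknown keys: {', '.join(sorted(extra))}")
    try:
        return DistributionSpec(**{k: raw[k] for k in raw})
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"{name}.dist: {exc}") from exc


def _parse_parameter(name: str, raw) -> ModelParameter:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"parameter {name!r} must be a mapping with a 'value' key")
    if "value" not in raw:
        raise ConfigError(f"parameter {name!r} is missing 'value'")
    dist = None
    if raw.get("dist") is not None:
        dist = _parse_dist(name, raw["dist"])
    try:
        value = float(raw["value"])
        low = None if raw.get("low") is None else float(raw["low"])
        high = None if raw.get("high") is None else float(raw["high"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"parameter {name!r}: non-numeric entry ({exc})") from exc
    return ModelParameter(
        name=name,
        value=value,
        low=low,
        high=high,
        dist=dist,
        units=str(raw.get("units", "")),
        source=str(raw.get("source", "")),
    )


def _parse_settings(raw: Mapping) -> tuple[EconomicSettings, CalibrationConstants]:
    raw = dict(raw or {})
    calib_raw = raw.pop("calibration", {}) or {}
    try:
        calibration = CalibrationConstants(**calib_raw)
    except TypeError as exc:
        raise ConfigError(f"settings.calibration: {exc}") from exc
    wtp_max = raw.pop("wtp_max", 2000.0)
    wtp_step = raw.pop("wtp_step", 10.0)
    if "wtp_grid" in raw:
        grid = tuple(float(v) for v in raw.pop("wtp_grid"))
    else:
        grid = _default_wtp_grid(wtp_max, wtp_step)
    try:
        settings = EconomicSettings(wtp_grid=grid, **raw)
    except TypeError as exc:
        raise ConfigError(f"settings: {exc}") from exc
    settings.validate()
    calibration.validate()
    return settings, calibration


def load_config(
    config_path: str | Path | None = None,
) -> tuple[EconomicSettings, dict[str, ParameterSet]]:
    """Load settings plus one validated :class:`ParameterSet` per age group.

    ``config_path`` of ``None`` loads the packaged default (the published
    ledger). YAML is expected; JSON parses as a YAML subset.
    """
    path = Path(config_path) if config_path is not None else default_config_path()
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    settings, calibration = _parse_settings(raw.get("settings", {}))
    sets: dict[str, ParameterSet] = {}
    for group in AGE_GROUPS:
        if group not in raw:
            raise ConfigError(f"{path}: missing top-level key {group!r}")
        block = raw[group]
        if not isinstance(block, Mapping):
            raise ConfigError(f"{path}: {group!r} must be a mapping of parameters")
        params = {name: _parse_parameter(name, spec) for name, spec in block.items()}
        ps = ParameterSet(age_group=group, params=params, calibration=calibration)
        ps.validate()
        sets[group] = ps
    return settings, sets


def load_parameters(
    config_path: str | Path | None = None,
    age_group: str = "adults_adolescents",
) -> ParameterSet:
    """Load and validate the ledger for one age group."""
    if age_group not in AGE_GROUPS:
        raise ValidationError(f"age_group must be one of {AGE_GROUPS}, got {age_group!r}")
    _, sets = load_config(config_path)
    return sets[age_group]


def load_settings(config_path: str | Path | None = None) -> EconomicSettings:
    """Load only the run-level settings block."""
    settings, _ = load_config(config_path)
    return settings


def save_config(
    settings: EconomicSettings,
    param_sets: Mapping[str, ParameterSet],
    path: str | Path,
) -> None:
    """Write a configuration file that :func:`load_config` round-trips exactly."""
    doc: dict = {
        "settings": {
            "cycles_per_year": settings.cycles_per_year,
            "horizon_cycles": settings.horizon_cycles,
            "wtp_grid": list(settings.wtp_grid),
            "calibration": {
                k: getattr(next(iter(param_sets.values())).calibration, k)
                for k in (
                    "gp_visits_per_ati",
                    "gp_baseline_visits_per_cycle",
                    "hourly_wage",
                    "hours_per_workday",
                    "surgery_recovery_days_adult",
                    "surgery_recovery_days_child",
                    "discount_convention",
                    "include_dispensing_fee",
                )
            },
        }
    }
    if settings.discount_rate_costs is not None:
        doc["settings"]["discount_rate_costs"] = settings.discount_rate_costs
    if settings.discount_rate_outcomes is not None:
        doc["settings"]["discount_rate_outcomes"] = settings.discount_rate_outcomes
    for group, ps in param_sets.items():
        block = {}
        for name in ps.names():
            p = ps[name]
            entry: dict = {"value": p.value}
            if p.low is not None:
                entry["low"] = p.low
            if p.high is not None:
                entry["high"] = p.high
            if p.dist is not None:
                entry["dist"] = p.dist.to_dict()
            if p.units:
                entry["units"] = p.units
            if p.source:
                entry["source"] = p.source
            block[name] = entry
        doc[group] = block
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
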