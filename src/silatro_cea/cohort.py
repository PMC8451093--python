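"""Deterministic Markov cohort engine.

Four states — well (at risk of ATIs), post-surgery (tonsillectomy received,
treated as curative and absorbing), and dead (absorbing); the transient
"ATI" state of the care pathway is realised as within-cycle expected-event
accrual on the well occupancy rather than as an end-of-cycle occupancy.

Each 4-month cycle, in order:

1. background mortality removes ``p_death_cycle`` of the well occupancy;
2. expected ATI events accrue on the survivors:
   ``e = occ_well * p_ati(arm) * n_ati_given_ati(arm)``;
3. costs accrue (adjuvant therapy, antibiotics, GP consultations and travel,
   productivity / informal-care losses), discounted to model entry;
4. once the cumulative expected event count per surviving patient plus the
   baseline ATI history reaches 4, a fraction ``p_surgery_if_eligible`` of the
   well occupancy undergoes tonsillectomy (surgery cost, hospital travel,
   recovery losses, operative mortality) and moves to the post-surgery state,
   where nothing further accrues.

The surgery trigger operates on *expected* cumulative events, which is what
makes the base case produce exactly zero operations (2.5 prior ATIs plus at
most ~0.83 expected events over 2 years never reaches 4); the individual-level
microsimulation uses true integer counts instead, a documented structural
difference.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ARMS, EconomicSettings, ParameterSet, ValidationError

__all__ = [
    "COST_CATEGORIES",
    "CohortState",
    "CycleLedger",
    "ArmResult",
    "discount_factor",
    "step_cycle",
    "run_arm",
]

COST_CATEGORIES = (
    "adjuvant_therapy",
    "antibiotics",
    "gp_consultations",
    "gp_travel_time",
    "tonsillectomy_surgery",
    "tonsillectomy_travel_time",
    "productivity_loss",
)

#: expected cumulative ATIs (prior history + in-model) at which tonsillectomy
#: may be offered
SURGERY_ELIGIBILITY_ATIS = 4.0

_CONSERVATION_TOL = 1e-12


def discount_factor(
    cycle_index: int,
    rate: float,
    convention: str = "per_cycle",
    cycles_per_year: int = 3,
) -> float:
    """Discount factor for a 1-based cycle index.

    ``per_cycle``: geometric within the year, ``(1+r)^(-(i-1)/cycles_per_year)``;
    ``annual_step``: 1 throughout year one, ``(1+r)^-1`` in year two, etc.
    Cycle 1 has factor 1 under both conventions.
    """
    if cycle_index < 1:
        raise ValidationError("cycle_index is 1-based and must be >= 1")
    if convention == "per_cycle":
        return (1.0 + rate) ** (-(cycle_index - 1) / cycles_per_year)
    if convention == "annual_step":
        return (1.0 + rate) ** (-((cycle_index - 1) // cycles_per_year))
    raise ValidationError(f"unknown discounting convention {convention!r}")


@dataclass
class CohortState:
    """Occupancies at the start of a cycle; ``cum_expected_atis`` is the
    undiscounted expected event count per surviving at-risk patient."""

    occ_well: float = 1.0
    occ_post_surgery: float = 0.0
    occ_dead: float = 0.0
    cum_expected_atis: float = 0.0
    cycle_index: int = 1

    def check(self) -> None:
        occs = (self.occ_well, self.occ_post_surgery, self.occ_dead)
        if any(o < -_CONSERVATION_TOL for o in occs):
            raise ValidationError(f"negative occupancy in cycle {self.cycle_index}: {occs}")
        if abs(sum(occs) - 1.0) > 1e-9:
            raise ValidationError(
                f"occupancy not conserved in cycle {self.cycle_index}: sum={sum(occs)!r}"
            )


@dataclass
class CycleLedger:
    """Per-cycle amounts, undiscounted and discounted (costs rate for costs,
    outcomes rate for expected ATI events)."""

    cycle_index: int
    undiscounted: dict[str, float]
    discounted: dict[str, float]
    expected_atis: float
    expected_atis_discounted: float
    gp_visits: float
    new_surgeries: float
    new_deaths: float


@dataclass
class ArmResult:
    """Aggregated discounted results for one arm (one Table-2-style column)."""

    arm: str
    age_group: str
    horizon_cycles: int
    categories: dict[str, float]
    total_cost: float
    total_atis: float
    total_atis_undiscounted: float
    surgeries: float
    deaths: float
    trace: list[CycleLedger] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-ready mapping; the productivity category is labelled
        ``informal_care`` for children (a parent's time, not the patient's)."""
        out: dict = {"arm": self.arm, "age_group": self.age_group}
        for cat in COST_CATEGORIES:
            key = cat
            if cat == "productivity_loss" and self.age_group == "children":
                key = "informal_care"
            out[key] = round(self.categories[cat], 6)
        out["total_cost"] = round(self.total_cost, 6)
        out["atis"] = round(self.total_atis, 6)
        out["atis_undiscounted"] = round(self.total_atis_undiscounted, 6)
        out["surgeries"] = round(self.surgeries, 8)
        out["deaths"] = round(self.deaths, 8)
        return out


def _resolve_rates(params: ParameterSet, settings: EconomicSettings) -> tuple[float, float]:
    rc = settings.discount_rate_costs
    ro = settings.discount_rate_outcomes
    if rc is None:
        rc = params.value("discount_costs")
    if ro is None:
        ro = params.value("discount_outcomes")
    return rc, ro


def step_cycle(
    state: CohortState,
    params: ParameterSet,
    arm: str,
    settings: EconomicSettings,
) -> tuple[CohortState, CycleLedger]:
    """Advance the cohort one cycle; returns the new state and the cycle ledger."""
    if arm not in ARMS:
        raise ValidationError(f"arm must be one of {ARMS}, got {arm!r}")
    state.check()
    cal = params.calibration
    i = state.cycle_index
    rate_costs, rate_outcomes = _resolve_rates(params, settings)
    df_cost = discount_factor(i, rate_costs, cal.discount_convention, settings.cycles_per_year)
    df_out = discount_factor(i, rate_outcomes, cal.discount_convention, settings.cycles_per_year)

    occ_well = state.occ_well
    occ_post = state.occ_post_surgery
    occ_dead = state.occ_dead

    # 1. background mortality
    deaths = occ_well * params.value("p_death_cycle")
    occ_well -= deaths
    occ_dead += deaths

    # 2. expected ATI events on the surviving at-risk occupancy
    intensity = params.arm_value("p_ati", arm) * params.arm_value("n_ati_given_ati", arm)
    e = occ_well * intensity
    cum_atis = state.cum_expected_atis + intensity  # per at-risk patient

    # 3. cost accrual
    wage = cal.hourly_wage
    amounts = dict.fromkeys(COST_CATEGORIES, 0.0)
    if arm == "intervention":
        # 8 weeks (2 months) of adjuvant therapy per cycle while alive/unoperated
        amounts["adjuvant_therapy"] = params.value("therapy_cost_month") * 2.0 * occ_well
    course_cost = params.value("antibiotics_course_cost")
    if cal.include_dispensing_fee:
        course_cost += params.value("dispensing_fee")
    amounts["antibiotics"] = e * params.arm_value("p_antibiotics", arm) * course_cost
    gp_visits = cal.gp_baseline_visits_per_cycle * occ_well + cal.gp_visits_per_ati * e
    amounts["gp_consultations"] = gp_visits * params.value("gp_consult_cost")
    amounts["gp_travel_time"] = gp_visits * params.value("gp_travel_hours") * wage
    amounts["productivity_loss"] = (
        e * params.arm_value("days_out_per_cycle", arm) * params.value("daily_productivity_cost")
    )

    # 4. tonsillectomy once the expected cumulative history reaches the bar
    surgeries = 0.0
    if params.value("prior_atis") + cum_atis >= SURGERY_ELIGIBILITY_ATIS:
        surgeries = params.value("p_surgery_if_eligible") * occ_well
        surgery_deaths = surgeries * params.value("p_death_surgery")
        occ_well -= surgeries
        occ_post += surgeries - surgery_deaths
        occ_dead += surgery_deaths
        deaths += surgery_deaths
        amounts["tonsillectomy_surgery"] = surgeries * params.value("surgery_cost")
        amounts["tonsillectomy_travel_time"] = (
            surgeries * params.value("hospital_travel_hours") * wage
        )
        recovery_days = (
            cal.surgery_recovery_days_child
            if params.age_group == "children"
            else cal.surgery_recovery_days_adult
        )
        amounts["productivity_loss"] += (
            surgeries * recovery_days * params.value("daily_productivity_cost")
        )

    ledger = CycleLedger(
        cycle_index=i,
        undiscounted=amounts,
        discounted={k: v * df_cost for k, v in amounts.items()},
        expected_atis=e,
        expected_atis_discounted=e * df_out,
        gp_visits=gp_visits,
        new_surgeries=surgeries,
        new_deaths=deaths,
    )
    new_state = CohortState(
        occ_well=occ_well,
        occ_post_surgery=occ_post,
        occ_dead=occ_dead,
        cum_expected_atis=cum_atis,
        cycle_index=i + 1,
    )
    new_state.check()
    return new_state, ledger


def run_arm(
    params: ParameterSet,
    arm: str,
    settings: EconomicSettings | None = None,
    keep_trace: bool = True,
) -> ArmResult:
    """Evaluate one arm over the full horizon starting from a 100%-well cohort."""
    settings = settings if settings is not None else EconomicSettings()
    settings.validate()
    state = CohortState()
    totals = dict.fromkeys(COST_CATEGORIES, 0.0)
    atis_disc = 0.0
    atis_undisc = 0.0
    surgeries = 0.0
    deaths = 0.0
    trace: list[CycleLedger] = []
    for _ in range(settings.horizon_cycles):
        state, ledger = step_cycle(state, params, arm, settings)
        for cat in COST_CATEGORIES:
            totals[cat] += ledger.discounted[cat]
        atis_disc += ledger.expected_atis_discounted
        atis_undisc += ledger.expected_atis
        surgeries += ledger.new_surgeries
        deaths += ledger.new_deaths
        if keep_trace:
            trace.append(ledger)
    return ArmResult(
        arm=arm,
        age_group=params.age_group,
        horizon_cycles=settings.horizon_cycles,
        categories=totals,
        total_cost=sum(totals.values()),
        total_atis=atis_disc,
        total_atis_undiscounted=atis_undisc,
        surgeries=surgeries,
        deaths=deaths,
        trace=trace,
    )
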