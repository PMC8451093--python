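"""Individual-level Monte Carlo simulation of the ATI care pathway.

This module plays two roles:

* **synthetic-data generator** — it emulates the kind of patient-level data
  the underlying trial produced (per-cycle ATI flags, integer event counts,
  antibiotic courses, diary "time out of role" fractions), from which the
  generating parameters can be recovered by method of moments; and
* **independent oracle** — with tonsillectomy disabled its sample means
  converge (law of large numbers) to the deterministic cohort engine's
  expected cost components and ATI counts, giving a brute-force equivalence
  check that shares no code path with the cohort recursion.

Per cycle and patient: a death draw; if alive, an ATI-cycle draw with
``p_ati``; within an ATI cycle an event draw whose success probability is
``n_ati_given_ati`` (a Bernoulli with the printed conditional mean — the
minimal integer-valued law; a Poisson alternative is available); one
antibiotics draw per event; diary days out accrued per event; and once the
integer cumulative event count plus baseline history reaches 4, a surgery
draw followed by an operative-mortality draw. Costs and discounting are
identical to the cohort engine.

Unlike the cohort engine's expected-count surgery trigger, the
microsimulation triggers on true integer counts, so with high baseline
history it produces *more* surgeries than the cohort model — a documented
structural difference, not a bug.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import COST_CATEGORIES, discount_factor, run_arm
from .parameters import (
    ARMS,
    DistributionSpec,
    EconomicSettings,
    ParameterSet,
    ValidationError,
)

__all__ = [
    "PatientRecord",
    "SyntheticTrial",
    "OracleReport",
    "simulate_patient",
    "simulate_trial",
    "recover_parameters",
    "oracle_check",
]


@dataclass
class PatientRecord:
    patient_id: int
    age_group: str
    arm: str
    prior_atis: float
    cycles: list[dict]
    totals: dict[str, float]


@dataclass
class SyntheticTrial:
    """Patient-level synthetic dataset: one row per patient-cycle in
    ``cycles``, one row per patient in ``patients``."""

    cycles: pd.DataFrame
    patients: pd.DataFrame
    seed: int
    parameter_digests: dict[str, str]

    @property
    def records(self) -> list[PatientRecord]:
        cycle_cols = [
            "alive", "at_risk", "ati_cycle", "n_ati_events",
            "antibiotics", "days_out", "operated",
        ]
        out = []
        grouped = self.cycles.groupby("patient_id", sort=True)
        for pid, prow in self.patients.set_index("patient_id").iterrows():
            block = grouped.get_group(pid).sort_values("cycle")
            out.append(
                PatientRecord(
                    patient_id=int(pid),
                    age_group=prow["age_group"],
                    arm=prow["arm"],
                    prior_atis=float(prow["prior_atis"]),
                    cycles=block[cycle_cols].to_dict("records"),
                    totals={
                        k: float(prow[k])
                        for k in (*COST_CATEGORIES, "total_cost", "atis", "atis_undiscounted")
                    },
                )
            )
        return out


def _sample_many(dist: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if dist.kind == "fixed":
        return np.full(n, float(dist.value))
    if dist.kind == "beta":
        return rng.beta(dist.alpha, dist.beta_param, n)
    if dist.kind == "gamma":
        return rng.gamma(dist.alpha, 1.0 / dist.rate, n)
    a, b = dist._pert_shapes()
    return dist.min + (dist.max - dist.min) * rng.beta(a, b, n)


def _simulate_arm(
    params: ParameterSet,
    arm: str,
    settings: EconomicSettings,
    n: int,
    rng: np.random.Generator,
    *,
    surgery_enabled: bool = True,
    sample_prior: bool = True,
    event_law: str = "bernoulli",
    record: bool = False,
) -> dict:
    """Vectorised engine over ``n`` patients; one fixed draw sequence per
    cycle (death, ATI, events, antibiotics, surgery, operative death) with
    full-length uniform draws so results are seed-reproducible regardless of
    which patients are still at risk."""
    if arm not in ARMS:
        raise ValidationError(f"arm must be one of {ARMS}, got {arm!r}")
    if event_law not in ("bernoulli", "poisson"):
        raise ValidationError("event_law must be 'bernoulli' or 'poisson'")
    cal = params.calibration
    T = settings.horizon_cycles
    cpy = settings.cycles_per_year
    rate_costs = (
        settings.discount_rate_costs
        if settings.discount_rate_costs is not None
        else params.value("discount_costs")
    )
    rate_out = (
        settings.discount_rate_outcomes
        if settings.discount_rate_outcomes is not None
        else params.value("discount_outcomes")
    )

    p_death = params.value("p_death_cycle")
    p_ati = params.arm_value("p_ati", arm)
    n_given = params.arm_value("n_ati_given_ati", arm)
    p_ab = params.arm_value("p_antibiotics", arm)
    p_surg = params.value("p_surgery_if_eligible")
    p_death_surg = params.value("p_death_surgery")
    days_out_rate = params.arm_value("days_out_per_cycle", arm)
    course_cost = params.value("antibiotics_course_cost")
    if cal.include_dispensing_fee:
        course_cost += params.value("dispensing_fee")
    therapy_cycle = params.value("therapy_cost_month") * 2.0 if arm == "intervention" else 0.0
    gp_unit = params.value("gp_consult_cost")
    gp_travel_unit = params.value("gp_travel_hours") * cal.hourly_wage
    hosp_travel_unit = params.value("hospital_travel_hours") * cal.hourly_wage
    dpc = params.value("daily_productivity_cost")
    recovery_days = (
        cal.surgery_recovery_days_child
        if params.age_group == "children"
        else cal.surgery_recovery_days_adult
    )

    prior_dist = params["prior_atis"].dist
    if sample_prior and prior_dist is not None and prior_dist.kind != "fixed":
        prior = _sample_many(prior_dist, rng, n)
    else:
        prior = np.full(n, params.value("prior_atis"))

    status = np.zeros(n, dtype=np.int8)  # 0 well, 1 post-surgery, 2 dead
    cum_events = np.zeros(n)
    totals = {cat: np.zeros(n) for cat in COST_CATEGORIES}
    atis_disc = np.zeros(n)
    atis_undisc = np.zeros(n)
    operated_any = np.zeros(n, dtype=bool)
    rec: dict[str, np.ndarray] = {}
    if record:
        for key in ("alive", "at_risk", "ati_cycle", "operated"):
            rec[key] = np.zeros((n, T), dtype=bool)
        rec["n_ati_events"] = np.zeros((n, T), dtype=np.int64)
        rec["antibiotics"] = np.zeros((n, T), dtype=np.int64)
        rec["days_out"] = np.zeros((n, T))

    for t in range(1, T + 1):
        df_cost = discount_factor(t, rate_costs, cal.discount_convention, cpy)
        df_out = discount_factor(t, rate_out, cal.discount_convention, cpy)

        well = status == 0
        dies = well & (rng.random(n) < p_death)
        status[dies] = 2
        well = status == 0

        ati_cycle = well & (rng.random(n) < p_ati)
        if event_law == "bernoulli":
            events = (ati_cycle & (rng.random(n) < n_given)).astype(np.int64)
        else:
            events = np.where(ati_cycle, rng.poisson(n_given, n), 0)
        courses = rng.binomial(events, p_ab)
        cum_events += events

        totals["adjuvant_therapy"] += np.where(well, therapy_cycle, 0.0) * df_cost
        totals["antibiotics"] += courses * course_cost * df_cost
        visits = np.where(well, cal.gp_baseline_visits_per_cycle, 0.0) + (
            cal.gp_visits_per_ati * events
        )
        totals["gp_consultations"] += visits * gp_unit * df_cost
        totals["gp_travel_time"] += visits * gp_travel_unit * df_cost
        days_out = events * days_out_rate
        totals["productivity_loss"] += days_out * dpc * df_cost
        atis_disc += events * df_out
        atis_undisc += events

        u_surg = rng.random(n)
        u_sdeath = rng.random(n)
        operated = np.zeros(n, dtype=bool)
        if surgery_enabled:
            eligible = well & (prior + cum_events >= 4.0)
            operated = eligible & (u_surg < p_surg)
            totals["tonsillectomy_surgery"] += (
                operated * params.value("surgery_cost") * df_cost
            )
            totals["tonsillectomy_travel_time"] += operated * hosp_travel_unit * df_cost
            totals["productivity_loss"] += operated * recovery_days * dpc * df_cost
            sdeath = operated & (u_sdeath < p_death_surg)
            status[operated] = 1
            status[sdeath] = 2
            operated_any |= operated

        if record:
            rec["alive"][:, t - 1] = status != 2
            rec["at_risk"][:, t - 1] = well
            rec["ati_cycle"][:, t - 1] = ati_cycle
            rec["n_ati_events"][:, t - 1] = events
            rec["antibiotics"][:, t - 1] = courses
            rec["days_out"][:, t - 1] = days_out
            rec["operated"][:, t - 1] = operated

    return {
        "prior": prior,
        "totals": totals,
        "total_cost": sum(totals.values()),
        "atis_disc": atis_disc,
        "atis_undisc": atis_undisc,
        "operated_any": operated_any,
        "died": status == 2,
        "record": rec,
    }


def simulate_patient(
    params: ParameterSet,
    arm: str,
    settings: EconomicSettings,
    rng: np.random.Generator,
    **kwargs,
) -> PatientRecord:
    """One patient's trajectory (a convenience wrapper over the vectorised path)."""
    out = _simulate_arm(params, arm, settings, 1, rng, record=True, **kwargs)
    rec = out["record"]
    cycles = [
        {
            "alive": bool(rec["alive"][0, t]),
            "at_risk": bool(rec["at_risk"][0, t]),
            "ati_cycle": bool(rec["ati_cycle"][0, t]),
            "n_ati_events": int(rec["n_ati_events"][0, t]),
            "antibiotics": int(rec["antibiotics"][0, t]),
            "days_out": float(rec["days_out"][0, t]),
            "operated": bool(rec["operated"][0, t]),
        }
        for t in range(settings.horizon_cycles)
    ]
    totals = {cat: float(out["totals"][cat][0]) for cat in COST_CATEGORIES}
    totals["total_cost"] = float(out["total_cost"][0])
    totals["atis"] = float(out["atis_disc"][0])
    totals["atis_undiscounted"] = float(out["atis_undisc"][0])
    return PatientRecord(
        patient_id=0,
        age_group=params.age_group,
        arm=arm,
        prior_atis=float(out["prior"][0]),
        cycles=cycles,
        totals=totals,
    )


def simulate_trial(
    params_by_group: ParameterSet | Mapping[str, ParameterSet],
    n_per_arm: int,
    settings: EconomicSettings | None = None,
    seed: int = 0,
    **kwargs,
) -> SyntheticTrial:
    """Generate a trial-like dataset: ``n_per_arm`` patients per arm for each
    supplied age group, fully reproducible from ``seed``."""
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be >= 1")
    settings = settings if settings is not None else EconomicSettings()
    if isinstance(params_by_group, ParameterSet):
        params_by_group = {params_by_group.age_group: params_by_group}
    rng = np.random.default_rng(seed)
    cycle_rows = []
    patient_rows = []
    digests = {}
    pid0 = 0
    T = settings.horizon_cycles
    for group in sorted(params_by_group):
        params = params_by_group[group]
        digests[group] = params.digest()
        for arm in ARMS:
            out = _simulate_arm(
                params, arm, settings, n_per_arm, rng, record=True, **kwargs
            )
            rec = out["record"]
            pids = np.arange(pid0, pid0 + n_per_arm)
            pid0 += n_per_arm
            patient_block = {
                "patient_id": pids,
                "age_group": group,
                "arm": arm,
                "prior_atis": out["prior"],
                **{cat: out["totals"][cat] for cat in COST_CATEGORIES},
                "total_cost": out["total_cost"],
                "atis": out["atis_disc"],
                "atis_undiscounted": out["atis_undisc"],
                "operated": out["operated_any"],
                "died": out["died"],
            }
            patient_rows.append(pd.DataFrame(patient_block))
            cycle_block = {
                "patient_id": np.repeat(pids, T),
                "age_group": group,
                "arm": arm,
                "prior_atis": np.repeat(out["prior"], T),
                "cycle": np.tile(np.arange(1, T + 1), n_per_arm),
                "alive": rec["alive"].ravel(),
                "at_risk": rec["at_risk"].ravel(),
                "ati_cycle": rec["ati_cycle"].ravel(),
                "n_ati_events": rec["n_ati_events"].ravel(),
                "antibiotics": rec["antibiotics"].ravel(),
                "days_out": rec["days_out"].ravel(),
                "operated": rec["operated"].ravel(),
            }
            cycle_rows.append(pd.DataFrame(cycle_block))
    return SyntheticTrial(
        cycles=pd.concat(cycle_rows, ignore_index=True),
        patients=pd.concat(patient_rows, ignore_index=True),
        seed=seed,
        parameter_digests=digests,
    )


def recover_parameters(trial: SyntheticTrial) -> dict:
    """Method-of-moments recovery of the Bernoulli generators per (group, arm).

    ``p_ati``: share of at-risk patient-cycles that are ATI cycles;
    ``n_ati_given_ati``: mean events per ATI cycle (the conditional success
    probability under the Bernoulli event law); ``p_antibiotics``: share of
    events treated with antibiotics. Standard errors are binomial; estimates
    with a zero denominator are reported as missing (NaN).
    """

    def _binomial(successes: float, denom: float) -> tuple[float, float]:
        if denom <= 0:
            return float("nan"), float("nan")
        p = successes / denom
        return p, float(np.sqrt(max(p * (1.0 - p), 0.0) / denom))

    out: dict = {}
    for (group, arm), block in trial.cycles.groupby(["age_group", "arm"], sort=True):
        n_risk = float(block["at_risk"].sum())
        n_ati = float(block["ati_cycle"].sum())
        n_events = float(block["n_ati_events"].sum())
        n_courses = float(block["antibiotics"].sum())
        out[(group, arm)] = {
            "p_ati": _binomial(n_ati, n_risk),
            "n_ati_given_ati": _binomial(n_events, n_ati),
            "p_antibiotics": _binomial(n_courses, n_events),
        }
    return out


@dataclass
class OracleReport:
    arm: str
    n: int
    tolerance: float
    rows: dict[str, dict]
    passed: bool

    def to_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "tolerance": self.tolerance,
            "passed": self.passed,
            "rows": self.rows,
        }


def oracle_check(
    params: ParameterSet,
    settings: EconomicSettings,
    arm: str = "usual_care",
    n: int = 200_000,
    seed: int = 0,
    tolerance: float = 0.01,
    sim_params: ParameterSet | None = None,
) -> OracleReport:
    """Law-of-large-numbers equivalence check: microsimulation sample means
    versus cohort-engine expectations, per cost category and for ATIs.

    Tonsillectomy is disabled and the baseline ATI history held at its
    deterministic value, so the expected-count vs integer-count trigger
    difference between the two engines is inert and the comparison is exact
    in expectation. ``sim_params`` feeds the microsimulation a different
    parameter set (a negative control: a mismatched generator must be flagged).
    """
    frozen = params.with_value("p_surgery_if_eligible", 0.0)
    cohort = run_arm(frozen, arm, settings, keep_trace=False)
    gen = (sim_params if sim_params is not None else params).with_value(
        "p_surgery_if_eligible", 0.0
    )
    rng = np.random.default_rng(seed)
    sim = _simulate_arm(
        gen, arm, settings, n, rng,
        surgery_enabled=False, sample_prior=False,
    )
    rows: dict[str, dict] = {}
    passed = True
    pairs = {cat: (cohort.categories[cat], float(sim["totals"][cat].mean()))
             for cat in COST_CATEGORIES}
    pairs["atis"] = (cohort.total_atis, float(sim["atis_disc"].mean()))
    pairs["total_cost"] = (cohort.total_cost, float(sim["total_cost"].mean()))
    for name, (expected, observed) in pairs.items():
        if abs(expected) < 1e-9:
            within = abs(observed) < 1e-9
            rel = abs(observed - expected)
        else:
            rel = abs(observed - expected) / abs(expected)
            within = rel <= tolerance
        passed &= within
        rows[name] = {
            "cohort": expected,
            "microsim": observed,
            "rel_dev": rel,
            "within_tol": bool(within),
        }
    return OracleReport(arm=arm, n=n, tolerance=tolerance, rows=rows, passed=passed)
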