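"""One-way sensitivity analysis, tornado ordering, threshold search, scenarios.

All deterministic: each analysis perturbs one parameter (or one run setting)
at a time, re-evaluates both arms with the cohort engine, and records the
incremental comparison. Thresholds are located by bisection on a boolean
condition over the perturbed parameter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

from .cohort import run_arm
from .metrics import ComparisonResult, compare, nmb
from .parameters import EconomicSettings, ParameterSet, ValidationError, owsa_range

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "DOMINANT_SENTINEL",
    "DOMINATED_SENTINEL",
    "one_way",
    "tornado",
    "threshold_search",
    "scenario_run",
    "bisect_boolean",
    "evaluate",
]

#: ordering sentinels for dominance outcomes on the EUR/ATI-averted axis.
#: A dominant (cost-saving) result is placed at the dominance boundary, ICER
#: zero — negative ICERs are savings, so clamping at the boundary keeps
#: tornado ranges commensurate with ordinary ICER swings instead of letting
#: any parameter that merely touches dominance outrank every other one. A
#: dominated result maps far above any plausible ICER.
DOMINANT_SENTINEL = 0.0
DOMINATED_SENTINEL = 1.0e6

CONDITIONS = ("becomes_dominant", "ceases_dominant", "crosses_wtp")


def _apply(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Set a parameter by canonical name; ``therapy_cost_cycle`` is accepted as
    an alias for the per-cycle (2-month) adjuvant therapy price."""
    if name == "therapy_cost_cycle":
        return params.with_value("therapy_cost_month", value / 2.0)
    return params.with_value(name, value)


def evaluate(params: ParameterSet, settings: EconomicSettings) -> ComparisonResult:
    """Deterministic two-arm evaluation and incremental comparison."""
    return compare(
        run_arm(params, "intervention", settings, keep_trace=False),
        run_arm(params, "usual_care", settings, keep_trace=False),
    )


def _ordering_value(result: ComparisonResult) -> float:
    if result.label == "dominant":
        return DOMINANT_SENTINEL
    if result.label == "dominated":
        return DOMINATED_SENTINEL
    if result.icer is None:  # equivalent: no incremental effect or cost
        return 0.0
    return result.icer


@dataclass
class TornadoEntry:
    parameter: str
    low_bound: float
    high_bound: float
    result_at_low: ComparisonResult
    result_at_high: ComparisonResult

    @property
    def icer_at_low(self) -> float:
        return _ordering_value(self.result_at_low)

    @property
    def icer_at_high(self) -> float:
        return _ordering_value(self.result_at_high)

    @property
    def range_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass
class ThresholdResult:
    parameter: str
    condition: str
    bracket: tuple[float, float]
    tol: float
    found: bool
    threshold: float | None = None
    verified: bool = False

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "condition": self.condition,
            "bracket": list(self.bracket),
            "tol": self.tol,
            "found": self.found,
            "threshold": None if self.threshold is None else round(self.threshold, 6),
            "verified": self.verified,
        }


def one_way(
    params: ParameterSet,
    settings: EconomicSettings,
    parameter_name: str,
    bounds: tuple[float, float] | None = None,
) -> TornadoEntry:
    """Re-run both arms with one parameter at each of its one-way bounds."""
    if parameter_name not in params.params:
        raise ValidationError(f"unknown parameter {parameter_name!r}")
    if bounds is None:
        bounds = owsa_range(params[parameter_name])
    lo, hi = bounds
    return TornadoEntry(
        parameter=parameter_name,
        low_bound=lo,
        high_bound=hi,
        result_at_low=evaluate(_apply(params, parameter_name, lo), settings),
        result_at_high=evaluate(_apply(params, parameter_name, hi), settings),
    )


def tornado(
    params: ParameterSet,
    settings: EconomicSettings,
    parameter_list: Sequence[str],
) -> list[TornadoEntry]:
    """One-way entries sorted by ICER range width, widest first; ties broken
    alphabetically by parameter name."""
    if not parameter_list:
        raise ValidationError("parameter_list must be non-empty")
    entries = [one_way(params, settings, name) for name in parameter_list]
    entries.sort(key=lambda t: (-t.range_width, t.parameter))
    return entries


def bisect_boolean(
    predicate: Callable[[float], bool],
    lo: float,
    hi: float,
    tol: float = 1e-3,
) -> float:
    """Locate the flip point of a boolean predicate on [lo, hi] by bisection.

    Requires ``predicate(lo) != predicate(hi)``; returns the bracket midpoint
    once the bracket width is <= ``tol``.
    """
    f_lo, f_hi = predicate(lo), predicate(hi)
    if f_lo == f_hi:
        raise ValidationError("no sign change in bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_search(
    params: ParameterSet,
    settings: EconomicSettings,
    parameter_name: str,
    condition: str,
    bracket: tuple[float, float],
    tol: float = 1e-3,
    wtp: float | None = None,
) -> ThresholdResult:
    """Bisect for the parameter value at which a cost-effectiveness condition
    flips: ``becomes_dominant`` / ``ceases_dominant`` (dominance of the
    intervention) or ``crosses_wtp`` (ICER no longer acceptable at ``wtp``,
    i.e. net monetary benefit < 0).

    The bracket is first scanned on a coarse grid so that conditions holding
    only on an interior window (e.g. a dominance region that opens and closes
    again within the bracket) are still located; the lowest flip point is
    returned. If the condition never changes truth value across the scanned
    bracket, the result records ``found=False`` — "no threshold in bracket".
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if condition == "crosses_wtp" and wtp is None:
        raise ValidationError("crosses_wtp requires a wtp value")

    def holds(value: float) -> bool:
        result = evaluate(_apply(params, parameter_name, value), settings)
        if condition == "becomes_dominant":
            return result.label == "dominant"
        if condition == "ceases_dominant":
            return result.label != "dominant"
        return nmb(result, wtp) < 0.0

    lo, hi = float(bracket[0]), float(bracket[1])
    n_scan = max(2, min(64, int(math.ceil((hi - lo) / max(tol, 1e-12)))))
    grid = [lo + (hi - lo) * k / n_scan for k in range(n_scan + 1)]
    flags = [holds(v) for v in grid]
    flip = next(
        (k for k in range(n_scan) if flags[k] != flags[k + 1]),
        None,
    )
    if flip is None:
        return ThresholdResult(parameter_name, condition, (lo, hi), tol, found=False)
    threshold = bisect_boolean(holds, grid[flip], grid[flip + 1], tol)
    verified = holds(max(lo, threshold - tol)) != holds(min(hi, threshold + tol))
    return ThresholdResult(
        parameter_name, condition, (lo, hi), tol, found=True,
        threshold=threshold, verified=verified,
    )


def scenario_run(
    params: ParameterSet,
    settings: EconomicSettings,
    **overrides,
) -> ComparisonResult:
    """Deterministic comparison under overridden run settings (e.g.
    ``horizon_cycles=3`` for the 1-year scenario, ``discount_rate_costs=0.0``
    and ``discount_rate_outcomes=0.0`` for undiscounted runs)."""
    new_settings = replace(settings, **overrides)
    new_settings.validate()
    return evaluate(params, new_settings)
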