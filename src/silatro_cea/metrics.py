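"""Incremental cost-effectiveness comparison and net monetary benefit.

Conventions: ``delta_cost`` is intervention minus comparator cost;
``delta_effect`` is ATIs *averted*, i.e. comparator minus intervention ATI
counts (outcome-discounted, matching the discounting of effects). The ICER is
``delta_cost / delta_effect`` and is reported as undefined (``None``) when no
ATIs are averted or caused.
"""
from __future__ import annotations

from dataclasses import dataclass

from .cohort import ArmResult
from .parameters import ValidationError

__all__ = ["ComparisonResult", "compare", "nmb", "LABELS"]

LABELS = ("dominant", "dominated", "equivalent", "tradeoff_ne", "tradeoff_sw")

_EPS = 1e-12


@dataclass
class ComparisonResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    label: str
    intervention: ArmResult | None = None
    comparator: ArmResult | None = None

    @property
    def icer_display(self) -> str:
        if self.label in ("dominant", "dominated", "equivalent"):
            return self.label
        return "n/a" if self.icer is None else f"{self.icer:.2f}"

    def to_dict(self) -> dict:
        return {
            "delta_cost": round(self.delta_cost, 6),
            "delta_effect": round(self.delta_effect, 6),
            "icer": None if self.icer is None else round(self.icer, 4),
            "label": self.label,
        }


def _sign(x: float) -> int:
    if abs(x) <= _EPS:
        return 0
    return 1 if x > 0 else -1


def classify(delta_cost: float, delta_effect: float) -> str:
    """Dominance label from the signs of the increments.

    Boundary cases with one increment exactly zero count toward dominance
    ("cheaper and no worse" is dominant; "costlier and no better" dominated),
    which keeps the classification antisymmetric under swapping the arms.
    """
    sc, se = _sign(delta_cost), _sign(delta_effect)
    if sc == 0 and se == 0:
        return "equivalent"
    if sc <= 0 and se >= 0:
        return "dominant"
    if sc >= 0 and se <= 0:
        return "dominated"
    return "tradeoff_ne" if sc > 0 else "tradeoff_sw"


def compare(intervention: ArmResult, comparator: ArmResult) -> ComparisonResult:
    """Incremental comparison of two arm evaluations from the same run setup."""
    if intervention.age_group != comparator.age_group:
        raise ValidationError(
            "cannot compare arms from different age groups: "
            f"{intervention.age_group} vs {comparator.age_group}"
        )
    if intervention.horizon_cycles != comparator.horizon_cycles:
        raise ValidationError("cannot compare arms run over different horizons")
    delta_cost = intervention.total_cost - comparator.total_cost
    delta_effect = comparator.total_atis - intervention.total_atis  # ATIs averted
    icer = None if _sign(delta_effect) == 0 else delta_cost / delta_effect
    return ComparisonResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        label=classify(delta_cost, delta_effect),
        intervention=intervention,
        comparator=comparator,
    )


def nmb(comparison: ComparisonResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * delta_effect - delta_cost`` at a
    willingness to pay per ATI averted; the intervention is preferred when
    the result is >= 0 (ties count as preferred)."""
    if wtp < 0:
        raise ValidationError("willingness to pay must be >= 0")
    return wtp * comparison.delta_effect - comparison.delta_cost
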