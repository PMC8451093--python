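"""Probabilistic sensitivity analysis (PSA).

Each replication draws one joint parameter set — every ledger row with a
non-fixed distribution replaced by a single draw, rows shared by the two arms
sampled once (common random numbers) and arm-specific rows sampled from their
own distributions — evaluates both arms deterministically with the cohort
engine, and records the incremental cost and ATIs averted. Draws are taken
from one seeded generator in canonical (sorted) parameter-name order, so runs
are bit-reproducible from the seed.

Summaries: cost-effectiveness plane quadrant shares, empirical 95% percentile
intervals per arm, the cost-effectiveness acceptability curve (CEAC, the
fraction of replications with non-negative net monetary benefit at each
willingness to pay), and a bivariate-normal 95% ellipse of the incremental
cloud (mean/covariance parameters, not a drawing).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ArmResult, run_arm
from .parameters import EconomicSettings, ParameterSet, ValidationError

__all__ = [
    "PsaSample",
    "PsaSummary",
    "draw_parameter_set",
    "run_psa",
    "summarize_psa",
    "samples_to_frame",
]

QUADRANTS = ("cheaper_better", "costlier_better", "inferior", "cheaper_worse")


@dataclass
class PsaSample:
    replication: int
    parameter_digest: str
    intervention: ArmResult
    usual_care: ArmResult
    delta_cost: float
    delta_effect: float


@dataclass
class PsaSummary:
    n_replications: int
    quadrant_shares: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    ceac: list[tuple[float, float]]
    ellipse: dict

    def to_dict(self) -> dict:
        return {
            "n_replications": self.n_replications,
            "quadrant_shares": {k: round(v, 6) for k, v in self.quadrant_shares.items()},
            "intervals": {k: [round(a, 4), round(b, 4)] for k, (a, b) in self.intervals.items()},
            "ceac": [[w, round(p, 6)] for w, p in self.ceac],
            "ellipse": self.ellipse,
        }


def draw_parameter_set(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One joint draw: every non-fixed row replaced by a sample from its PSA
    distribution (independent across rows; no correlation structure is
    specified for these inputs), fixed rows unchanged."""
    from dataclasses import replace as _replace

    new = {}
    for name in sorted(base.params):
        p = base.params[name]
        if p.dist is None or p.dist.kind == "fixed":
            new[name] = p
        else:
            new[name] = _replace(p, value=p.dist.sample(rng))
    return ParameterSet(base.age_group, new, base.calibration)


def run_psa(
    base: ParameterSet,
    settings: EconomicSettings,
    n: int,
    seed: int,
) -> list[PsaSample]:
    """Monte Carlo propagation: ``n`` joint draws, both arms evaluated per draw."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples: list[PsaSample] = []
    for k in range(n):
        drawn = draw_parameter_set(base, rng)
        res_int = run_arm(drawn, "intervention", settings, keep_trace=False)
        res_uc = run_arm(drawn, "usual_care", settings, keep_trace=False)
        samples.append(
            PsaSample(
                replication=k,
                parameter_digest=drawn.digest(),
                intervention=res_int,
                usual_care=res_uc,
                delta_cost=res_int.total_cost - res_uc.total_cost,
                delta_effect=res_uc.total_atis - res_int.total_atis,
            )
        )
    return samples


def summarize_psa(
    samples: list[PsaSample],
    wtp_grid: tuple[float, ...] | None = None,
) -> PsaSummary:
    """Quadrant shares, percentile intervals, CEAC and 95% ellipse parameters."""
    if not samples:
        raise ValidationError("samples must be non-empty")
    if wtp_grid is None:
        wtp_grid = EconomicSettings().wtp_grid
    dc = np.array([s.delta_cost for s in samples])
    de = np.array([s.delta_effect for s in samples])
    n = len(samples)

    better = de > 0
    cheaper = dc < 0
    shares = {
        "cheaper_better": float(np.mean(cheaper & better)),
        "costlier_better": float(np.mean(~cheaper & better)),
        "inferior": float(np.mean(~cheaper & ~better)),
        "cheaper_worse": float(np.mean(cheaper & ~better)),
    }

    def _interval(values: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(values, [2.5, 97.5])
        return float(lo), float(hi)

    intervals = {
        "cost_intervention": _interval(np.array([s.intervention.total_cost for s in samples])),
        "cost_usual_care": _interval(np.array([s.usual_care.total_cost for s in samples])),
        "atis_intervention": _interval(np.array([s.intervention.total_atis for s in samples])),
        "atis_usual_care": _interval(np.array([s.usual_care.total_atis for s in samples])),
    }

    # ties (NMB exactly zero) count as cost-effective
    ceac = [(float(w), float(np.mean(w * de - dc >= 0.0))) for w in wtp_grid]

    mean = np.array([de.mean(), dc.mean()])
    if n > 1:
        cov = np.cov(np.vstack([de, dc]))
    else:
        cov = np.zeros((2, 2))
    ellipse = {
        "mean_delta_effect": float(mean[0]),
        "mean_delta_cost": float(mean[1]),
        "cov": [[float(cov[0, 0]), float(cov[0, 1])], [float(cov[1, 0]), float(cov[1, 1])]],
        # chi-square(2 dof) quantile scaling the covariance ellipse to 95% mass
        "chi2_95": 5.991464547107979,
    }
    return PsaSummary(
        n_replications=n,
        quadrant_shares=shares,
        intervals=intervals,
        ceac=ceac,
        ellipse=ellipse,
    )


def samples_to_frame(samples: list[PsaSample]) -> pd.DataFrame:
    """Replication-level table matching the ``psa_points.csv`` layout."""
    return pd.DataFrame(
        {
            "replication": [s.replication for s in samples],
            "cost_int": [s.intervention.total_cost for s in samples],
            "cost_uc": [s.usual_care.total_cost for s in samples],
            "atis_int": [s.intervention.total_atis for s in samples],
            "atis_uc": [s.usual_care.total_atis for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
            "delta_effect": [s.delta_effect for s in samples],
        }
    )
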