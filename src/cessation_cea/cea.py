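"""Incremental cost-effectiveness analysis of two cohort traces.

Compares the best-practice program against the basic program on expected
discounted cost, QALYs and life-years.  The incremental cost-effectiveness
ratio (ICER) is the difference in expected cost divided by the difference
in expected effect; dominance is classified before any ratio is reported,
and cost-effectiveness at a willingness-to-pay threshold is decided by the
sign of the net monetary benefit (NMB = lambda * dQALY - dCost), which
handles cost-saving (southeast-quadrant) outcomes cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .engine import CohortTrace, run_cohort
from .mortality import (
    DEFAULT_EXCESS_CANCER_MULTIPLIER,
    AdjustedMortality,
    derive_adjusted_mortality,
)
from .synthetic import CauseSplit, LifeTable

__all__ = [
    "Dominance",
    "CEResult",
    "compute_icer",
    "net_monetary_benefit",
    "evaluate_strategies",
]


class Dominance(str, Enum):
    none = "none"
    bp_dominant = "bp_dominant"  # best practice cheaper and at least as effective
    bp_dominated = "bp_dominated"  # best practice costlier and no more effective


@dataclass(frozen=True)
class CEResult:
    """Per-strategy expected outcomes, incrementals and ICERs.

    Incrementals are best practice minus basic.  ICERs are `None` when
    undefined (zero effect difference) or suppressed by dominance; the
    unrounded values are retained — use `icer_qaly_rounded` /
    `icer_ly_rounded` for reporting to the nearest dollar.
    """

    cost_basic: float
    qaly_basic: float
    ly_basic: float
    cost_bp: float
    qaly_bp: float
    ly_bp: float
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_qaly: float | None
    icer_ly: float | None
    dominance: Dominance

    @property
    def icer_qaly_rounded(self) -> int | None:
        return None if self.icer_qaly is None else round(self.icer_qaly)

    @property
    def icer_ly_rounded(self) -> int | None:
        return None if self.icer_ly is None else round(self.icer_ly)

    def to_frame(self) -> pd.DataFrame:
        """Results table: strategy rows, incremental and ICER rows."""
        rows = [
            {"row": "basic", "cost": self.cost_basic,
             "qaly": self.qaly_basic, "ly": self.ly_basic},
            {"row": "best_practice", "cost": self.cost_bp,
             "qaly": self.qaly_bp, "ly": self.ly_bp},
            {"row": "incremental", "cost": self.delta_cost,
             "qaly": self.delta_qaly, "ly": self.delta_ly},
            {"row": "icer", "cost": None,
             "qaly": self.icer_qaly_rounded, "ly": self.icer_ly_rounded},
            {"row": "dominance", "cost": None,
             "qaly": self.dominance.value, "ly": None},
        ]
        return pd.DataFrame(rows, columns=["row", "cost", "qaly", "ly"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ratio(delta_cost: float, delta_effect: float) -> float | None:
    """ICER when meaningful: both deltas same-signed trade-off, effect != 0."""
    if delta_effect == 0.0:
        return None
    if (delta_cost > 0 and delta_effect > 0) or (delta_cost < 0 and delta_effect < 0):
        return delta_cost / delta_effect
    return None


def compute_icer(trace_basic: CohortTrace, trace_bp: CohortTrace) -> CEResult:
    """Incremental cost-effectiveness of best practice versus basic.

    Both traces must come from the same sex, horizon and settings.  Uses
    the discounted ledgers.  Dominance (one strategy cheaper and more
    effective) suppresses the corresponding ratio; an effect difference of
    exactly zero with a nonzero cost difference leaves the ICER undefined
    rather than dividing.
    """
    if trace_basic.sex != trace_bp.sex:
        raise ValueError("traces compare different sexes")
    if trace_basic.n_cycles != trace_bp.n_cycles:
        raise ValueError("traces compare different horizons")
    if not math.isclose(trace_basic.discount_rate, trace_bp.discount_rate):
        raise ValueError("traces use different discount rates")

    d_cost = trace_bp.total_cost_disc - trace_basic.total_cost_disc
    d_qaly = trace_bp.total_qaly_disc - trace_basic.total_qaly_disc
    d_ly = trace_bp.total_ly_disc - trace_basic.total_ly_disc

    if d_cost <= 0 and d_qaly >= 0 and not (d_cost == 0 and d_qaly == 0):
        dom = Dominance.bp_dominant
    elif d_cost >= 0 and d_qaly <= 0 and not (d_cost == 0 and d_qaly == 0):
        dom = Dominance.bp_dominated
    else:
        dom = Dominance.none

    icer_q = _ratio(d_cost, d_qaly) if dom is Dominance.none else None
    icer_l = _ratio(d_cost, d_ly) if dom is Dominance.none else None
    return CEResult(
        cost_basic=trace_basic.total_cost_disc,
        qaly_basic=trace_basic.total_qaly_disc,
        ly_basic=trace_basic.total_ly_disc,
        cost_bp=trace_bp.total_cost_disc,
        qaly_bp=trace_bp.total_qaly_disc,
        ly_bp=trace_bp.total_ly_disc,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer_qaly=icer_q,
        icer_ly=icer_l,
        dominance=dom,
    )


def net_monetary_benefit(delta_cost, delta_qaly, wtp: float):
    """NMB = wtp * dQALY - dCost; non-negative means cost-effective at wtp.

    Accepts scalars or aligned arrays of incremental outcomes.
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * delta_qaly - delta_cost


def evaluate_strategies(
    params,
    lt: LifeTable,
    cs: CauseSplit,
    sex: str,
    excess_cancer_multiplier: float = DEFAULT_EXCESS_CANCER_MULTIPLIER,
    horizon: int | None = None,
    y2_quit_both_arms: bool = False,
    mort: AdjustedMortality | None = None,
) -> CEResult:
    """Full base-case evaluation: mortality adjustment, both arms, ICER.

    Convenience wrapper tying the pipeline together; `mort` can be supplied
    to reuse a pre-derived mortality table (the probabilistic sensitivity
    analysis does this per draw).
    """
    if mort is None:
        mort = derive_adjusted_mortality(lt, cs, params.mortality,
                                         excess_cancer_multiplier)
    trace_basic = run_cohort("basic", sex, params, mort, horizon=horizon,
                             y2_quit_both_arms=y2_quit_both_arms)
    trace_bp = run_cohort("best_practice", sex, params, mort, horizon=horizon,
                          y2_quit_both_arms=y2_quit_both_arms)
    return compute_icer(trace_basic, trace_bp)
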