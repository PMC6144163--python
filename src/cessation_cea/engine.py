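"""Markov cohort engine for the two smoking-cessation strategies.

The cohort starts 100% as current smokers with cancer at the start age and
moves yearly among three conceptual states — current smoker, former smoker,
dead — where the former-smoker state is expanded into one-year tunnel
compartments so that the annual relapse probability can depend on years
since quitting (bands 1-2, 3-4, 5-8, 9-10 and 10+ years, with dwell times
2, 2, 4, 2 and unbounded).

Event ordering within a cycle is fixed for reproducibility: death is
applied first from every living state using the status-specific annual
death probability, then quitting (from the current-smoker state) or relapse
(from the former-smoker tunnels) occurs among survivors.  Quitting follows
the program schedule: the arm-specific 12-month abstinence probability in
cycle 1, a residual program-driven quit probability in cycle 2 (best
practice only, by default), and the background self-quit probability from
then on.  Relapsers return to the current-smoker state and are thereafter
eligible only for self-quit — program effects and program costs are
one-time.

Payoffs per cycle: costs (annual cancer care for everyone alive, a
smoking-attributable excess for current smokers and recent quitters still
inside the utilization decay window, and the one-time program cost at
entry), quality-adjusted life-years (age/sex/status utility minus
the cancer utility decrement), and life-years (alive fraction), each kept
as discounted and undiscounted ledgers.  Cycle t payoffs are discounted by
(1+r)^-t; the one-time entry cost is charged undiscounted at entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import AdjustedMortality
from .params import ModelParams

__all__ = [
    "STRATEGIES",
    "STATE_NAMES",
    "N_STATES",
    "IDX_S",
    "IDX_D",
    "BAND_OF_STATE",
    "NEXT_STATE",
    "CohortTrace",
    "quit_probability",
    "entry_cost",
    "build_transition_matrix",
    "accrue_cycle",
    "run_cohort",
]

STRATEGIES = ("basic", "best_practice")

# Tunnel expansion of the former-smoker state.  Bands carry the relapse
# probabilities from the parameter set, in order (1-2, 3-4, 5-8, 9-10, 10+).
_BAND_DWELL = (2, 2, 4, 2, 1)  # the last band is self-looping (10+ years)

STATE_NAMES: tuple[str, ...] = ("S",) + tuple(
    f"F{band + 1}y{year + 1}"
    for band, dwell in enumerate(_BAND_DWELL)
    for year in range(dwell)
) + ("D",)
N_STATES = len(STATE_NAMES)  # 13
IDX_S = 0
IDX_D = N_STATES - 1
_F_FIRST = 1
_F_LAST = IDX_D - 1

#: relapse band index for each former-smoker tunnel state
BAND_OF_STATE: dict[int, int] = {}
#: successor tunnel state when a former smoker survives without relapsing
NEXT_STATE: dict[int, int] = {}
_i = _F_FIRST
for _band, _dwell in enumerate(_BAND_DWELL):
    for _year in range(_dwell):
        BAND_OF_STATE[_i] = _band
        NEXT_STATE[_i] = _i if _i == _F_LAST else _i + 1
        _i += 1


def quit_probability(strategy: str, cycle: int, params: ModelParams,
                     y2_quit_both_arms: bool = False) -> float:
    """Annual probability that a surviving current smoker quits in `cycle`.

    Cycle 1 uses the arm's 12-month program abstinence probability.  Cycle 2
    uses the residual program-driven quit probability in the best-practice
    arm (both arms if `y2_quit_both_arms`); otherwise, and in every later
    cycle, the background self-quit probability applies.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    c = params.cessation
    if cycle == 1:
        return c.abstinence_bp_y1 if strategy == "best_practice" else c.abstinence_basic_y1
    if cycle == 2 and (strategy == "best_practice" or y2_quit_both_arms):
        return c.program_quit_y2
    return c.self_quit


def entry_cost(strategy: str, params: ModelParams) -> float:
    """One-time program cost charged to the whole entering cohort."""
    if strategy == "basic":
        return params.costs.basic_admin
    if strategy == "best_practice":
        return params.costs.bp_admin + params.costs.nurse_fee + params.costs.varenicline
    raise ValueError(f"unknown strategy {strategy!r}")


def build_transition_matrix(
    age: int,
    sex: str,
    strategy: str,
    cycle: int,
    params: ModelParams,
    mort: AdjustedMortality,
    y2_quit_both_arms: bool = False,
) -> np.ndarray:
    """One-cycle row-stochastic transition matrix over the tunnel state space.

    Death is applied first from each living state; quitting and relapse are
    competing moves among survivors.  The dead state is absorbing.
    """
    q = quit_probability(strategy, cycle, params, y2_quit_both_arms)
    relapse = params.cessation.relapse_by_band
    p_die_cur = mort.lookup(age, "current")
    p_die_fmr = mort.lookup(age, "former")

    M = np.zeros((N_STATES, N_STATES))
    # current smoker: die, quit into the first tunnel year, or stay
    M[IDX_S, IDX_D] = p_die_cur
    M[IDX_S, _F_FIRST] = (1.0 - p_die_cur) * q
    M[IDX_S, IDX_S] = (1.0 - p_die_cur) * (1.0 - q)
    # former-smoker tunnels: die, relapse, or advance one year
    for i in range(_F_FIRST, _F_LAST + 1):
        r = relapse[BAND_OF_STATE[i]]
        M[i, IDX_D] = p_die_fmr
        M[i, IDX_S] = (1.0 - p_die_fmr) * r
        M[i, NEXT_STATE[i]] += (1.0 - p_die_fmr) * (1.0 - r)
    M[IDX_D, IDX_D] = 1.0
    return M


def accrue_cycle(
    occupancy: np.ndarray,
    age: int,
    sex: str,
    strategy: str,
    cycle: int,
    params: ModelParams,
) -> tuple[float, float, float]:
    """Undiscounted (cost, QALY, LY) accrued by `occupancy` in one cycle.

    Cost is the annual cancer-care cost for the alive fraction (when
    enabled), the smoking-attributable annual cost for current smokers and
    for former smokers still inside the decay window
    (``smoking_cost_decay_years`` of abstinence), and — in cycle 1 only —
    the one-time program cost for the whole entering cohort.  QALYs apply
    the sex/age-band utility of each smoking status minus the cancer
    utility decrement; the dead state accrues nothing.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    alive = float(occupancy[:IDX_D].sum())
    frac_s = float(occupancy[IDX_S])
    frac_f = float(occupancy[_F_FIRST:_F_LAST + 1].sum())
    # former smokers within the decay window still incur smoker-level costs;
    # tunnel state _F_FIRST + k corresponds to abstinence year k + 1
    decay = min(params.settings.smoking_cost_decay_years, _F_LAST - _F_FIRST + 1)
    frac_smoker_cost = frac_s + float(occupancy[_F_FIRST:_F_FIRST + decay].sum())

    cost = params.costs.smoking_attrib_cost * frac_smoker_cost
    if params.settings.include_cancer_cost:
        cost += params.costs.annual_cancer_cost * alive
    if cycle == 1:
        cost += entry_cost(strategy, params)

    dec = params.utilities.cancer_decrement
    qaly = 0.0
    if frac_s > 0.0:
        qaly += frac_s * (params.utilities.lookup(sex, age, "current") - dec)
    if frac_f > 0.0:
        qaly += frac_f * (params.utilities.lookup(sex, age, "former") - dec)
    return cost, qaly, alive


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of a cohort run: occupancy and payoff ledgers.

    `occupancy[t]` is the state distribution after cycle t (row 0 is the
    initial distribution).  Cycle arrays are 1-based in cycle index, stored
    0-based: `cycle_cost[t-1]` belongs to cycle t.
    """

    strategy: str
    sex: str
    start_age: int
    discount_rate: float
    occupancy: np.ndarray  # (n_cycles+1, N_STATES)
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    cycle_ly: np.ndarray
    cycle_cost_disc: np.ndarray
    cycle_qaly_disc: np.ndarray
    cycle_ly_disc: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_cost)

    # expected totals per member of the entering cohort
    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    @property
    def total_ly(self) -> float:
        return float(self.cycle_ly.sum())

    @property
    def total_cost_disc(self) -> float:
        return float(self.cycle_cost_disc.sum())

    @property
    def total_qaly_disc(self) -> float:
        return float(self.cycle_qaly_disc.sum())

    @property
    def total_ly_disc(self) -> float:
        return float(self.cycle_ly_disc.sum())

    def to_frame(self) -> pd.DataFrame:
        cycles = np.arange(1, self.n_cycles + 1)
        df = pd.DataFrame({"cycle": cycles, "age": self.start_age + cycles - 1})
        for j, name in enumerate(STATE_NAMES):
            df[f"occ_{name}"] = self.occupancy[1:, j]
        df["cycle_cost"] = self.cycle_cost
        df["cycle_qaly"] = self.cycle_qaly
        df["cycle_ly"] = self.cycle_ly
        df["cycle_cost_disc"] = self.cycle_cost_disc
        df["cycle_qaly_disc"] = self.cycle_qaly_disc
        df["cycle_ly_disc"] = self.cycle_ly_disc
        df["cum_cost_disc"] = self.cycle_cost_disc.cumsum()
        df["cum_qaly_disc"] = self.cycle_qaly_disc.cumsum()
        df["cum_ly_disc"] = self.cycle_ly_disc.cumsum()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(
    strategy: str,
    sex: str,
    params: ModelParams,
    mort: AdjustedMortality,
    horizon: int | None = None,
    y2_quit_both_arms: bool = False,
) -> CohortTrace:
    """Run the cohort simulation for one strategy and sex.

    The cohort starts entirely in the current-smoker state at the start
    age; each cycle applies the age-specific transition matrix and then
    accrues payoffs on the post-transition occupancy (or the start/end
    average when the half-cycle correction is enabled).  `horizon`
    truncates the run to a number of cycles (defaults to end_age -
    start_age).
    """
    s = params.settings
    n_cycles = s.n_cycles if horizon is None else int(horizon)
    if n_cycles < 1:
        raise ValueError("horizon must be at least one cycle")
    mort_ages = set(int(a) for a in mort.ages)
    needed = set(range(s.start_age, s.start_age + n_cycles))
    if not needed <= mort_ages:
        raise ValueError("mortality table does not cover the run horizon")

    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0, IDX_S] = 1.0
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    ly = np.zeros(n_cycles)
    disc = (1.0 + s.discount_rate) ** -np.arange(1, n_cycles + 1)

    for t in range(1, n_cycles + 1):
        age = s.start_age + t - 1
        M = build_transition_matrix(age, sex, strategy, t, params, mort,
                                    y2_quit_both_arms)
        occ[t] = occ[t - 1] @ M
        payoff_occ = 0.5 * (occ[t - 1] + occ[t]) if s.half_cycle_correction else occ[t]
        cost[t - 1], qaly[t - 1], ly[t - 1] = accrue_cycle(
            payoff_occ, age, sex, strategy, t, params)

    # one-time entry cost is charged undiscounted at entry in both ledgers
    e0 = entry_cost(strategy, params)
    cost_disc = (cost - np.where(np.arange(n_cycles) == 0, e0, 0.0)) * disc
    cost_disc[0] += e0
    return CohortTrace(
        strategy=strategy,
        sex=sex,
        start_age=s.start_age,
        discount_rate=s.discount_rate,
        occupancy=occ,
        cycle_cost=cost,
        cycle_qaly=qaly,
        cycle_ly=ly,
        cycle_cost_disc=cost_disc,
        cycle_qaly_disc=qaly * disc,
        cycle_ly_disc=ly * disc,
    )
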