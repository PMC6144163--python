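"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the full base case at each parameter's
lower and upper bound and records the ICER swing.  Probabilistic analysis
samples every uncertain parameter from a distribution fitted to its base
value and 95% range — gamma for costs, beta for probabilities and the
cancer utility decrement, lognormal for the two mortality hazard ratios —
propagates each draw through the whole pipeline (mortality adjustment,
both cohort arms), and summarises the cloud of incremental (cost, QALY)
points as a cost-effectiveness plane and an acceptability curve (CEAC).

Distribution fitting is by moment matching on SE = (upper - lower) / (2 *
1.96); the lognormal is parameterised so the base value is the *median*
(mu = ln base), the standard choice for a hazard ratio reported with a
confidence interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cea import evaluate_strategies, net_monetary_benefit
from .mortality import DEFAULT_EXCESS_CANCER_MULTIPLIER, derive_adjusted_mortality
from .params import DistKind, ModelParams, ParamSpec
from .synthetic import CauseSplit, LifeTable

__all__ = [
    "Sampler",
    "fit_distribution",
    "TornadoEntry",
    "one_way_tornado",
    "PSASettings",
    "PSAResult",
    "run_psa",
    "ceac_curve",
]

logger = logging.getLogger(__name__)

_Z95 = 2 * 1.96  # width of a 95% interval in SE units


@dataclass(frozen=True)
class Sampler:
    """Frozen sampling distribution for one parameter.

    Draws are generated through the inverse CDF so that rank coupling
    (feeding two samplers one shared uniform) is possible.
    """

    name: str
    kind: DistKind
    base: float
    dist: object | None  # frozen scipy distribution; None for a point mass

    def ppf(self, u):
        """Inverse CDF; a point mass returns the base value for any u."""
        if self.dist is None:
            return np.full_like(np.asarray(u, dtype=float), self.base)
        return self.dist.ppf(u)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        u = rng.random(size if size is not None else ())
        out = self.ppf(u)
        return float(out) if size is None else out

    @property
    def mean(self) -> float:
        return self.base if self.dist is None else float(self.dist.mean())


def fit_distribution(spec: ParamSpec) -> Sampler:
    """Fit the assigned distribution family from base value and 95% bounds.

    gamma
        shape = base^2 / SE^2, scale = SE^2 / base (mean equals base).
    beta
        variance = SE^2; alpha = base * (base(1-base)/var - 1) and
        beta = (1-base) * (same); if the variance is infeasible
        (var >= base(1-base)) the parameter falls back to fixed with a
        warning.
    lognormal
        mu = ln(base) (base is the median),
        sigma = (ln upper - ln lower) / (2 * 1.96).
    fixed
        a point mass at the base value.

    A degenerate range (lower == upper) always yields a point mass.
    """
    se = (spec.upper - spec.lower) / _Z95
    if spec.dist_kind is DistKind.fixed or se == 0.0:
        return Sampler(spec.name, DistKind.fixed, spec.base, None)

    if spec.dist_kind is DistKind.gamma:
        if spec.base <= 0:
            raise ValueError(f"{spec.name}: gamma requires base > 0")
        shape = spec.base**2 / se**2
        scale = se**2 / spec.base
        return Sampler(spec.name, DistKind.gamma, spec.base,
                       stats.gamma(a=shape, scale=scale))

    if spec.dist_kind is DistKind.beta:
        if not (0.0 < spec.base < 1.0):
            raise ValueError(f"{spec.name}: beta requires base in (0, 1)")
        var = se**2
        if var >= spec.base * (1.0 - spec.base):
            warnings.warn(
                f"{spec.name}: range too wide for a beta fit; treated as fixed",
                RuntimeWarning, stacklevel=2)
            return Sampler(spec.name, DistKind.fixed, spec.base, None)
        nu = spec.base * (1.0 - spec.base) / var - 1.0
        return Sampler(spec.name, DistKind.beta, spec.base,
                       stats.beta(a=spec.base * nu, b=(1.0 - spec.base) * nu))

    if spec.dist_kind is DistKind.lognormal:
        if spec.lower <= 0 or spec.base <= 0:
            raise ValueError(f"{spec.name}: lognormal requires positive bounds")
        sigma = (math.log(spec.upper) - math.log(spec.lower)) / _Z95
        return Sampler(spec.name, DistKind.lognormal, spec.base,
                       stats.lognorm(s=sigma, scale=spec.base))

    raise ValueError(f"unknown dist_kind {spec.dist_kind!r}")  # pragma: no cover


# ----------------------------------------------------------------------
# one-way deterministic sensitivity (tornado)
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    """ICER ($/QALY) at a parameter's lower and upper bound.

    An endpoint where the incremental QALY is not positive carries a
    dominance note instead of a numeric ICER, and the swing is NaN.
    """

    name: str
    icer_at_lower: float | None
    icer_at_upper: float | None
    note_lower: str = ""
    note_upper: str = ""

    @property
    def swing(self) -> float:
        if self.icer_at_lower is None or self.icer_at_upper is None:
            return float("nan")
        return abs(self.icer_at_upper - self.icer_at_lower)


def _icer_or_note(result) -> tuple[float | None, str]:
    if result.icer_qaly is not None:
        return result.icer_qaly, ""
    return None, result.dominance.value if result.dominance.value != "none" else "undefined"


def one_way_tornado(
    params: ModelParams,
    lt: LifeTable,
    cs: CauseSplit,
    param_names: list[str] | None = None,
    sex: str = "male",
    excess_cancer_multiplier: float = DEFAULT_EXCESS_CANCER_MULTIPLIER,
    horizon_scenarios: tuple[int, int] = (2, 4),
) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to each parameter's 95% range.

    Re-runs the full base case twice per parameter (everything else at
    base) and returns entries sorted by swing, largest first.  The
    time-horizon scenario (truncating the run to `horizon_scenarios`
    cycles) is included as the entry ``time_horizon``.
    """
    specs = params.param_specs()
    if param_names is None:
        names = [n for n, s in specs.items() if s.dist_kind is not DistKind.fixed]
        names.append("time_horizon")
    else:
        names = list(param_names)

    entries: list[TornadoEntry] = []
    for name in names:
        if name == "time_horizon":
            lo, hi = horizon_scenarios
            res_lo = evaluate_strategies(params, lt, cs, sex,
                                         excess_cancer_multiplier, horizon=lo)
            res_hi = evaluate_strategies(params, lt, cs, sex,
                                         excess_cancer_multiplier, horizon=hi)
        else:
            spec = specs[name]
            res_lo = evaluate_strategies(params.with_value(name, spec.lower),
                                         lt, cs, sex, excess_cancer_multiplier)
            res_hi = evaluate_strategies(params.with_value(name, spec.upper),
                                         lt, cs, sex, excess_cancer_multiplier)
        icer_lo, note_lo = _icer_or_note(res_lo)
        icer_hi, note_hi = _icer_or_note(res_hi)
        entries.append(TornadoEntry(name, icer_lo, icer_hi, note_lo, note_hi))

    entries.sort(key=lambda e: (not math.isnan(e.swing), e.swing), reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    rows = [{"name": e.name, "icer_at_lower": e.icer_at_lower,
             "icer_at_upper": e.icer_at_upper, "swing": e.swing,
             "note_lower": e.note_lower, "note_upper": e.note_upper}
            for e in entries]
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis
# ----------------------------------------------------------------------

DEFAULT_WTP_GRID = tuple(float(x) for x in range(0, 105_000, 5_000))


@dataclass(frozen=True)
class PSASettings:
    """Monte-Carlo settings for the probabilistic analysis."""

    n_draws: int = 10_000
    seed: int = 0
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    couple_hrs: bool = False  # sample both hazard ratios from one quantile

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental outcomes and their CEAC summary."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    samples: pd.DataFrame  # one row per draw, one column per sampled parameter
    wtp_grid: tuple[float, ...]
    ceac: dict[float, float]
    n_rejected: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.delta_cost)

    @property
    def quadrant_counts(self) -> dict[str, int]:
        """Cost-effectiveness-plane quadrants (boundaries go to NE/NW)."""
        dq, dc = self.delta_qaly, self.delta_cost
        return {
            "NE": int(np.sum((dq >= 0) & (dc >= 0))),
            "SE": int(np.sum((dq >= 0) & (dc < 0))),
            "NW": int(np.sum((dq < 0) & (dc >= 0))),
            "SW": int(np.sum((dq < 0) & (dc < 0))),
        }

    def to_frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df.insert(0, "draw", np.arange(len(df)))
        df["delta_cost"] = self.delta_cost
        df["delta_qaly"] = self.delta_qaly
        return df

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": list(self.ceac), "fraction": list(self.ceac.values())})


def ceac_curve(psa: PSAResult, grid=None) -> dict[float, float]:
    """Fraction of draws with non-negative NMB at each threshold."""
    grid = psa.wtp_grid if grid is None else grid
    if len(grid) == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    out: dict[float, float] = {}
    for wtp in grid:
        if wtp < 0:
            raise ValueError("willingness-to-pay threshold must be >= 0")
        nmb = net_monetary_benefit(psa.delta_cost, psa.delta_qaly, float(wtp))
        out[float(wtp)] = float(np.mean(nmb >= 0))
    return out


def run_psa(
    params: ModelParams,
    lt: LifeTable,
    cs: CauseSplit,
    settings: PSASettings,
    sex: str = "male",
    excess_cancer_multiplier: float = DEFAULT_EXCESS_CANCER_MULTIPLIER,
    sample_names: list[str] | None = None,
) -> PSAResult:
    """Propagate parameter uncertainty through the full pipeline.

    Per draw, every non-fixed parameter is sampled independently (with the
    two hazard ratios optionally rank-coupled through one shared quantile),
    the adjusted mortality is rebuilt and both strategy arms are re-run;
    the incremental discounted (cost, QALY) pair is recorded.  Draws whose
    sampled values violate a model invariant are rejected and redrawn (the
    count is logged).  Fully reproducible given the seed.

    `sample_names` restricts sampling to the named parameters (everything
    else held fixed at base); an empty list degenerates every draw to the
    base case.
    """
    rng = np.random.default_rng(settings.seed)
    specs = params.param_specs()
    samplers = {n: fit_distribution(s) for n, s in specs.items()
                if s.dist_kind is not DistKind.fixed
                and (sample_names is None or n in sample_names)}
    names = list(samplers)

    d_cost = np.empty(settings.n_draws)
    d_qaly = np.empty(settings.n_draws)
    records: dict[str, np.ndarray] = {n: np.empty(settings.n_draws) for n in names}
    n_rejected = 0

    for i in range(settings.n_draws):
        while True:
            u = {n: rng.random() for n in names}
            if settings.couple_hrs and "hr_former_vs_never" in u and \
                    "hr_current_vs_never" in u:
                u["hr_former_vs_never"] = u["hr_current_vs_never"]
            try:
                draw = params
                values = {}
                for n in names:
                    values[n] = float(samplers[n].ppf(u[n]))
                    draw = draw.with_value(n, values[n])
                mort = derive_adjusted_mortality(
                    lt, cs, draw.mortality, excess_cancer_multiplier)
                res = evaluate_strategies(draw, lt, cs, sex,
                                          excess_cancer_multiplier, mort=mort)
            except ValueError:
                n_rejected += 1
                continue
            break
        d_cost[i] = res.delta_cost
        d_qaly[i] = res.delta_qaly
        for n in names:
            records[n][i] = values[n]

    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid draws", n_rejected)
    grid = tuple(float(w) for w in settings.wtp_grid)
    ceac = {}
    for wtp in grid:
        ceac[wtp] = float(np.mean(net_monetary_benefit(d_cost, d_qaly, wtp) >= 0))
    return PSAResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        samples=pd.DataFrame(records),
        wtp_grid=grid,
        ceac=ceac,
        n_rejected=n_rejected,
    )
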