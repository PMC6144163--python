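"""End-to-end orchestration: run configurations and file outputs.

Ties the modules together for the four analysis commands — base case,
tornado, probabilistic sensitivity analysis, and scenario re-runs — and
writes their CSV outputs to an output directory.  All randomness flows
from the single seed in the run configuration, which is recorded alongside
the outputs so every file reproduces bit-identically from the same config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .cea import CEResult, evaluate_strategies
from .engine import run_cohort
from .mortality import DEFAULT_EXCESS_CANCER_MULTIPLIER, derive_adjusted_mortality
from .params import ModelParams, load_params
from .sensitivity import (
    PSAResult,
    PSASettings,
    one_way_tornado,
    run_psa,
    tornado_frame,
)
from .synthetic import CauseSplit, LifeTable, default_cause_split, default_life_table

__all__ = ["RunConfig", "run_base_case", "run_tornado", "run_psa_analysis", "run_scenario"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Inputs for one analysis run.

    Exactly one life-table source applies: a CSV path (`life_table_path`,
    with `cause_split_path`) or the packaged synthetic tables
    (`synthetic=True`).
    """

    sex: str = "male"
    params_path: str | None = None
    life_table_path: str | None = None
    cause_split_path: str | None = None
    synthetic: bool = True
    out_dir: str = "results"
    seed: int = 0
    excess_cancer_multiplier: float = DEFAULT_EXCESS_CANCER_MULTIPLIER
    horizon: int | None = None
    include_cancer_cost: bool | None = None  # override the parameter file

    def resolve_inputs(self) -> tuple[ModelParams, LifeTable, CauseSplit]:
        params = load_params(self.params_path)
        if self.include_cancer_cost is not None:
            from dataclasses import replace
            params = replace(params, settings=replace(
                params.settings, include_cancer_cost=self.include_cancer_cost))
        if self.life_table_path is not None:
            lt = LifeTable.from_csv(self.life_table_path, self.sex)
            if self.cause_split_path is None:
                raise ValueError("a cause-split CSV is required with a life-table CSV")
            cs = CauseSplit.from_csv(self.cause_split_path, self.sex)
        elif self.synthetic:
            lt = default_life_table(self.sex)
            cs = default_cause_split(self.sex)
        else:
            raise ValueError("no life-table source: give a CSV path or set synthetic=True")
        return params, lt, cs


def _prepare_out(config: RunConfig, command: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"command": command, "sex": config.sex, "seed": config.seed,
            "params": config.params_path or "packaged defaults",
            "life_table": config.life_table_path or "packaged synthetic",
            "excess_cancer_multiplier": config.excess_cancer_multiplier,
            "horizon": config.horizon}
    (out / f"{command}_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out


def run_base_case(config: RunConfig) -> CEResult:
    """Run both arms, write the results table and per-cycle traces."""
    params, lt, cs = config.resolve_inputs()
    out = _prepare_out(config, "base_case")
    mort = derive_adjusted_mortality(lt, cs, params.mortality,
                                     config.excess_cancer_multiplier)
    mort.to_csv(out / f"adjusted_mortality_{config.sex}.csv")
    traces = {}
    for strategy in ("basic", "best_practice"):
        traces[strategy] = run_cohort(strategy, config.sex, params, mort,
                                      horizon=config.horizon)
        traces[strategy].to_csv(out / f"trace_{strategy}_{config.sex}.csv")
    from .cea import compute_icer
    result = compute_icer(traces["basic"], traces["best_practice"])
    result.to_csv(out / f"cea_{config.sex}.csv")
    logger.info("base case (%s): dCost=%.2f dQALY=%.4f ICER=%s",
                config.sex, result.delta_cost, result.delta_qaly,
                result.icer_qaly_rounded)
    return result


def run_tornado(config: RunConfig, param_names: list[str] | None = None):
    """One-way sensitivity analysis; writes the tornado CSV."""
    params, lt, cs = config.resolve_inputs()
    out = _prepare_out(config, "tornado")
    entries = one_way_tornado(params, lt, cs, param_names=param_names,
                              sex=config.sex,
                              excess_cancer_multiplier=config.excess_cancer_multiplier)
    tornado_frame(entries).to_csv(out / f"tornado_{config.sex}.csv", index=False)
    return entries


def run_psa_analysis(config: RunConfig, n_draws: int = 10_000,
                     wtp_grid=None, couple_hrs: bool = False) -> PSAResult:
    """Probabilistic sensitivity analysis; writes draws and CEAC CSVs."""
    params, lt, cs = config.resolve_inputs()
    out = _prepare_out(config, "psa")
    settings = PSASettings(
        n_draws=n_draws, seed=config.seed,
        wtp_grid=tuple(wtp_grid) if wtp_grid is not None
        else PSASettings().wtp_grid,
        couple_hrs=couple_hrs)
    psa = run_psa(params, lt, cs, settings, sex=config.sex,
                  excess_cancer_multiplier=config.excess_cancer_multiplier)
    psa.to_frame().to_csv(out / f"psa_draws_{config.sex}.csv", index=False)
    psa.ceac_frame().to_csv(out / f"ceac_{config.sex}.csv", index=False)
    return psa


def run_scenario(config: RunConfig, no_cancer_cost: bool = False,
                 horizon: int | None = None) -> CEResult:
    """Scenario re-run: drop cancer-care costs and/or truncate the horizon."""
    from dataclasses import replace as dc_replace
    scenario = dc_replace(
        config,
        include_cancer_cost=False if no_cancer_cost else config.include_cancer_cost,
        horizon=horizon if horizon is not None else config.horizon,
    )
    params, lt, cs = scenario.resolve_inputs()
    out = _prepare_out(scenario, "scenario")
    result = evaluate_strategies(params, lt, cs, scenario.sex,
                                 scenario.excess_cancer_multiplier,
                                 horizon=scenario.horizon)
    result.to_csv(out / f"cea_scenario_{scenario.sex}.csv")
    return result
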