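"""Shared fixtures: default inputs and pre-run base cases."""

import numpy as np
import pytest

from cessation_cea import (
    AdjustedMortality,
    default_cause_split,
    default_life_table,
    default_params,
    derive_adjusted_mortality,
    run_cohort,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def male_inputs():
    return default_life_table("male"), default_cause_split("male")


@pytest.fixture(scope="session")
def female_inputs():
    return default_life_table("female"), default_cause_split("female")


@pytest.fixture(scope="session")
def male_mort(params, male_inputs):
    lt, cs = male_inputs
    return derive_adjusted_mortality(lt, cs, params.mortality)


@pytest.fixture(scope="session")
def base_traces(params, male_mort):
    """Male base-case traces for both strategies."""
    return {
        strategy: run_cohort(strategy, "male", params, male_mort)
        for strategy in ("basic", "best_practice")
    }


@pytest.fixture()
def zero_mortality():
    """No deaths at any model age (terminal closure irrelevant to a 35-cycle run)."""
    ages = range(65, 111)
    return AdjustedMortality(
        sex="male",
        p_death={(a, s): 0.0 for a in ages for s in ("current", "former")},
    )


@pytest.fixture()
def frozen_params(params):
    """No quitting, no relapse: the cohort never leaves the smoker state."""
    from dataclasses import replace

    from cessation_cea import CessationParams

    return replace(
        params,
        cessation=CessationParams(
            abstinence_bp_y1=0.0,
            abstinence_basic_y1=0.0,
            program_quit_y2=0.0,
            self_quit=0.0,
            relapse_by_band=(0.0,) * 5,
        ),
    )
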