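"""Markov cohort engine: transition structure, accrual, ledgers."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cessation_cea import (
    CessationParams,
    CostParams,
    EconSettings,
    STATE_NAMES,
    accrue_cycle,
    build_transition_matrix,
    entry_cost,
    run_cohort,
)
from cessation_cea.engine import IDX_D, IDX_S, N_STATES, quit_probability

# ----------------------------------------------------------------------
# independent brute-force oracle: re-derives the cohort trace from the
# parameter definitions with plain dict arithmetic, sharing no code with
# the engine's matrix construction
# ----------------------------------------------------------------------

def _oracle_trace(strategy, sex, params, mort, n_cycles, y2_both=False):
    """Expected occupancy per cycle via explicit state bookkeeping.

    States are ("S",), ("F", band, year) and ("D",); probabilities are read
    straight from the parameter set.
    """
    dwell = [2, 2, 4, 2, math.inf]
    relapse = params.cessation.relapse_by_band
    occ = {("S",): 1.0, ("D",): 0.0}
    history = [dict(occ)]
    for t in range(1, n_cycles + 1):
        age = params.settings.start_age + t - 1
        c = params.cessation
        if t == 1:
            q = c.abstinence_bp_y1 if strategy == "best_practice" else c.abstinence_basic_y1
        elif t == 2 and (strategy == "best_practice" or y2_both):
            q = c.program_quit_y2
        else:
            q = c.self_quit
        new = {("S",): 0.0, ("D",): occ.get(("D",), 0.0)}
        # current smokers
        s = occ.get(("S",), 0.0)
        pd_cur = mort.lookup(age, "current")
        new[("D",)] += s * pd_cur
        new[("S",)] += s * (1 - pd_cur) * (1 - q)
        new[("F", 0, 0)] = new.get(("F", 0, 0), 0.0) + s * (1 - pd_cur) * q
        # former smokers by band/year
        pd_fmr = mort.lookup(age, "former")
        for (kind, *rest), mass in occ.items():
            if kind != "F" or mass == 0.0:
                continue
            band, year = rest
            r = relapse[band]
            new[("D",)] += mass * pd_fmr
            new[("S",)] += mass * (1 - pd_fmr) * r
            stay = mass * (1 - pd_fmr) * (1 - r)
            if band == 4:
                nxt = ("F", 4, 0)
            elif year + 1 < dwell[band]:
                nxt = ("F", band, year + 1)
            else:
                nxt = ("F", band + 1, 0)
            new[nxt] = new.get(nxt, 0.0) + stay
        occ = new
        history.append(dict(occ))
    return history


def _oracle_vector(state_dict):
    """Map oracle dict states onto the engine's state ordering."""
    vec = np.zeros(N_STATES)
    offsets = {0: 1, 1: 3, 2: 5, 3: 9, 4: 11}
    for key, mass in state_dict.items():
        if key == ("S",):
            vec[IDX_S] += mass
        elif key == ("D",):
            vec[IDX_D] += mass
        else:
            _, band, year = key
            vec[offsets[band] + year] += mass
    return vec


def test_trace_matches_independent_oracle(params, male_mort):
    for strategy in ("basic", "best_practice"):
        trace = run_cohort(strategy, "male", params, male_mort)
        oracle = _oracle_trace(strategy, "male", params, male_mort, trace.n_cycles)
        for t in range(trace.n_cycles + 1):
            np.testing.assert_allclose(
                trace.occupancy[t], _oracle_vector(oracle[t]), atol=1e-10)


# ----------------------------------------------------------------------
# transition-matrix structure
# ----------------------------------------------------------------------

def test_cycle1_best_practice_quit_split(params, zero_mortality):
    M = build_transition_matrix(65, "male", "best_practice", 1, params, zero_mortality)
    assert M[IDX_S, 1] == pytest.approx(0.24)  # into first tunnel year
    assert M[IDX_S, IDX_S] == pytest.approx(0.76)


def test_first_band_relapse(params, zero_mortality):
    M = build_transition_matrix(70, "male", "basic", 5, params, zero_mortality)
    assert M[1, IDX_S] == pytest.approx(0.24)
    assert M[2, IDX_S] == pytest.approx(0.24)  # both years of band 1-2
    assert M[3, IDX_S] == pytest.approx(0.10)  # band 3-4


def test_competing_risk_composition(params, male_mort):
    """Death applies first; quit splits the survivors. Verifiable by hand."""
    from cessation_cea import AdjustedMortality
    mort = AdjustedMortality(sex="male", p_death={
        (a, s): 0.1 for a in range(65, 111) for s in ("current", "former")})
    M = build_transition_matrix(65, "male", "best_practice", 1, params, mort)
    assert M[IDX_S, IDX_D] == pytest.approx(0.1)
    assert M[IDX_S, 1] == pytest.approx(0.9 * 0.24)
    assert M[IDX_S, IDX_S] == pytest.approx(0.9 * 0.76)
    np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)


def test_rows_stochastic_and_dead_absorbing(params, male_mort):
    for cycle, age in [(1, 65), (2, 66), (10, 74), (35, 99)]:
        for strategy in ("basic", "best_practice"):
            M = build_transition_matrix(age, "male", strategy, cycle, params, male_mort)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert (M >= 0).all() and (M <= 1).all()
            assert M[IDX_D, IDX_D] == 1.0


def test_quit_schedule(params):
    c = params.cessation
    assert quit_probability("best_practice", 1, params) == c.abstinence_bp_y1
    assert quit_probability("basic", 1, params) == c.abstinence_basic_y1
    assert quit_probability("best_practice", 2, params) == c.program_quit_y2
    assert quit_probability("basic", 2, params) == c.self_quit
    assert quit_probability("basic", 2, params, y2_quit_both_arms=True) == c.program_quit_y2
    assert quit_probability("best_practice", 3, params) == c.self_quit
    with pytest.raises(ValueError):
        quit_probability("basic", 0, params)
    with pytest.raises(ValueError):
        quit_probability("gold_standard", 1, params)


# ----------------------------------------------------------------------
# payoff accrual
# ----------------------------------------------------------------------

def test_utility_of_smoker_with_cancer(params):
    occ = np.zeros(N_STATES)
    occ[IDX_S] = 1.0
    cost, qaly, ly = accrue_cycle(occ, 70, "male", "basic", 5, params)
    assert qaly == pytest.approx(0.7551 - 0.12)
    assert ly == 1.0


def test_entry_cost_components(params):
    assert entry_cost("best_practice", params) == pytest.approx(47 + 105 + 150)
    assert entry_cost("basic", params) == pytest.approx(16)
    occ = np.zeros(N_STATES)
    occ[IDX_S] = 1.0
    cost1, _, _ = accrue_cycle(occ, 65, "male", "best_practice", 1, params)
    cost2, _, _ = accrue_cycle(occ, 65, "male", "best_practice", 2, params)
    assert cost1 - cost2 == pytest.approx(302)  # charged in cycle 1 only


def test_dead_cohort_accrues_nothing(params):
    occ = np.zeros(N_STATES)
    occ[IDX_D] = 1.0
    assert accrue_cycle(occ, 80, "female", "basic", 5, params) == (0.0, 0.0, 0.0)


# ----------------------------------------------------------------------
# cohort runs and ledgers
# ----------------------------------------------------------------------

def test_frozen_cohort_undiscounted_life_years(frozen_params, zero_mortality):
    trace = run_cohort("basic", "male", frozen_params, zero_mortality)
    assert np.allclose(trace.occupancy[:, IDX_S], 1.0)
    assert trace.total_ly == pytest.approx(35.0)


def test_frozen_cohort_discounted_geometric_sum(frozen_params, zero_mortality):
    trace = run_cohort("basic", "male", frozen_params, zero_mortality)
    expected = sum(1.05 ** -t for t in range(1, 36))
    assert trace.total_ly_disc == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(16.374, abs=5e-4)


def test_conservation_and_monotone_death(base_traces):
    for trace in base_traces.values():
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        dead = trace.occupancy[:, IDX_D]
        assert np.all(np.diff(dead) >= -1e-15)


def test_ledger_orderings(base_traces):
    for trace in base_traces.values():
        assert trace.total_cost_disc <= trace.total_cost
        assert trace.total_qaly_disc <= trace.total_qaly
        assert trace.total_ly_disc <= trace.total_ly
        assert trace.total_qaly <= trace.total_ly
        assert trace.total_qaly_disc <= trace.total_ly_disc


def test_best_practice_dominates_on_health(base_traces):
    assert base_traces["best_practice"].total_qaly_disc \
        >= base_traces["basic"].total_qaly_disc
    assert base_traces["best_practice"].total_ly_disc \
        >= base_traces["basic"].total_ly_disc


def test_arm_symmetry_when_programs_identical(params, male_mort):
    """Equal effectiveness and equal entry cost make the arms coincide."""
    p = replace(params,
                cessation=replace(params.cessation, abstinence_basic_y1=0.24),
                costs=replace(params.costs, basic_admin=302.0))
    tb = run_cohort("basic", "male", p, male_mort, y2_quit_both_arms=True)
    tp = run_cohort("best_practice", "male", p, male_mort, y2_quit_both_arms=True)
    np.testing.assert_allclose(tb.occupancy, tp.occupancy, atol=1e-15)
    assert tb.total_cost_disc == pytest.approx(tp.total_cost_disc, rel=1e-12)
    assert tb.total_qaly_disc == pytest.approx(tp.total_qaly_disc, rel=1e-12)


def test_cost_scaling_linearity(params, male_mort):
    k = 3.7
    scaled = replace(params, costs=CostParams(
        **{f: k * getattr(params.costs, f) for f in (
            "nurse_fee", "bp_admin", "basic_admin", "varenicline",
            "annual_cancer_cost", "smoking_attrib_cost")}))
    t1 = run_cohort("best_practice", "male", params, male_mort)
    t2 = run_cohort("best_practice", "male", scaled, male_mort)
    assert t2.total_cost == pytest.approx(k * t1.total_cost, rel=1e-12)
    assert t2.total_cost_disc == pytest.approx(k * t1.total_cost_disc, rel=1e-12)


def test_zero_discount_equates_ledgers(params, male_mort):
    p = replace(params, settings=replace(params.settings, discount_rate=0.0))
    trace = run_cohort("basic", "male", p, male_mort)
    assert trace.total_cost == pytest.approx(trace.total_cost_disc, rel=1e-12)
    assert trace.total_qaly == pytest.approx(trace.total_qaly_disc, rel=1e-12)
    assert trace.total_ly == pytest.approx(trace.total_ly_disc, rel=1e-12)


def test_half_cycle_correction_averages_payoffs(params, male_mort):
    p = replace(params, settings=replace(params.settings, half_cycle_correction=True))
    t_std = run_cohort("basic", "male", params, male_mort)
    t_hcc = run_cohort("basic", "male", p, male_mort)
    # occupancy path identical; payoffs larger because deaths count half a year
    np.testing.assert_allclose(t_std.occupancy, t_hcc.occupancy)
    assert t_hcc.total_ly > t_std.total_ly


def test_horizon_validation(params, male_mort, zero_mortality):
    with pytest.raises(ValueError):
        run_cohort("basic", "male", params, male_mort, horizon=0)
    from cessation_cea import AdjustedMortality
    short = AdjustedMortality(sex="male", p_death={
        (a, s): 0.01 for a in range(65, 80) for s in ("current", "former")})
    with pytest.raises(ValueError, match="horizon"):
        run_cohort("basic", "male", params, short)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    abstinence=st.floats(0.0, 1.0),
    relapse1=st.floats(0.0, 1.0),
    p_die=st.floats(0.0, 0.5),
)
def test_conservation_under_arbitrary_probabilities(abstinence, relapse1, p_die):
    """Any fixed event ordering conserves probability mass."""
    from cessation_cea import AdjustedMortality, default_params
    params = default_params()
    p = replace(params, cessation=replace(
        params.cessation,
        abstinence_bp_y1=abstinence,
        relapse_by_band=(relapse1, 0.10, 0.02, 0.021, relapse1 * 0.005)))
    mort = AdjustedMortality(sex="male", p_death={
        (a, s): p_die for a in range(65, 111) for s in ("current", "former")})
    trace = run_cohort("best_practice", "male", p, mort)
    np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(np.diff(trace.occupancy[:, IDX_D]) >= -1e-15)


def test_trace_csv_schema(base_traces, tmp_path):
    base_traces["basic"].to_csv(tmp_path / "trace.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "trace.csv")
    assert len(df) == 35
    for name in STATE_NAMES:
        assert f"occ_{name}" in df.columns
    assert df["cum_qaly_disc"].iloc[-1] == pytest.approx(
        base_traces["basic"].total_qaly_disc)
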