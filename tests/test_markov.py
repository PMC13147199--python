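"""Markov engine: closed forms, stochasticity, loop oracle, linearity."""

import numpy as np
import pytest

from icas_cea import (
    MarkovParameters,
    PriceSchedule,
    build_transition_matrix,
    incremental,
    run_cohort,
)
from icas_cea.markov import STATES


def test_treated_recurrence_closed_form(base_params):
    # rate scale: 1 - (1 - 0.149)^(1 - 0.32)
    assert base_params.treated_recurrence_probability() == pytest.approx(
        1 - 0.851**0.68, abs=1e-12
    )
    prob_scale = base_params.with_(rrr_scale="probability")
    assert prob_scale.treated_recurrence_probability() == pytest.approx(
        0.149 * 0.68, abs=1e-12
    )


@pytest.mark.parametrize(
    "kwargs, message",
    [
        (dict(p_recurrent_annual=0.99), "exceeds 1"),
        (dict(u_recurrent=0.95), "u_recurrent"),
        (dict(u_stable=1.2), "u_stable"),
        (dict(rrr=1.0), "rrr"),
        (dict(horizon_years=0), "horizon_years"),
        (dict(discount_rate_annual=-0.01), "discount_rate_annual"),
        (dict(price=PriceSchedule("short", (6600.0,) * 3)), "3 entries"),
    ],
)
def test_parameter_validation(base_params, kwargs, message):
    with pytest.raises(ValueError, match=message):
        base_params.with_(**kwargs).validate()


def _random_params(rng):
    p_rec = rng.uniform(0.01, 0.4)
    u_s = rng.uniform(0.5, 1.0)
    return MarkovParameters(
        p_recurrent_annual=p_rec,
        p_mort_background_annual=rng.uniform(0.0, 0.1),
        p_mort_poststroke_annual=rng.uniform(0.0, 0.2),
        u_stable=u_s,
        u_recurrent=rng.uniform(0.0, u_s),
        discount_rate_annual=rng.uniform(0.0, 0.08),
        discontinuation_annual=rng.uniform(0.0, 0.3),
        rrr=rng.uniform(-0.3, 0.8),
        price=PriceSchedule.flat(rng.uniform(0, 12000)),
        c_stroke_state_annual=rng.uniform(0, 40000),
        c_stroke_event_acute=rng.uniform(0, 60000),
        cycle_accounting=rng.choice(["end", "start"]),
        drug_cost_basis=rng.choice(["annuity", "occupancy"]),
        discontinuation_removes_effect=bool(rng.integers(0, 2)),
    )


def test_transition_matrices_are_row_stochastic():
    rng = np.random.default_rng(42)
    for _ in range(50):
        params = _random_params(rng)
        for arm in ("standard", "pcsk9i"):
            M = build_transition_matrix(params, arm)
            assert M.shape == (5, 5)
            assert ((M >= 0) & (M <= 1)).all()
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-14)


def test_null_treatment_equalises_matrices(base_params):
    params = base_params.with_(rrr=0.0)
    np.testing.assert_array_equal(
        build_transition_matrix(params, "standard"),
        build_transition_matrix(params, "pcsk9i"),
    )


def test_stay_healthy_identity():
    # no events, no deaths, utility 1, no discounting: 5 QALYs exactly
    params = MarkovParameters(
        p_recurrent_annual=0.0,
        p_mort_background_annual=0.0,
        p_mort_poststroke_annual=0.0,
        u_stable=1.0,
        u_recurrent=0.5,
        discount_rate_annual=0.0,
    )
    for arm in ("standard", "pcsk9i"):
        assert run_cohort(params, arm).total_qaly_discounted == pytest.approx(
            5.0, abs=1e-12
        )


@pytest.mark.parametrize("basis", ["annuity", "occupancy"])
def test_drug_cost_geometric_series(basis):
    # nobody leaves the stable-on state, so both cost bases coincide
    # with the discounted annuity 6600 * sum 1.03^-k
    params = MarkovParameters(
        p_recurrent_annual=0.0,
        p_mort_background_annual=0.0,
        p_mort_poststroke_annual=0.0,
        discontinuation_annual=0.0,
        drug_cost_basis=basis,
        c_stroke_state_annual=0.0,
        c_stroke_event_acute=0.0,
    )
    res = run_cohort(params, "pcsk9i")
    expected = 6600 * sum(1.03**-k for k in range(5))
    assert res.drug_cost_component == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(31132.85, abs=0.5)
    assert res.care_cost_component == 0.0


def _oracle_run(params, arm):
    """Literal scalar re-implementation: no matrices, plain dicts."""
    p_trt = params.treated_recurrence_probability()
    p_on = p_trt if arm == "pcsk9i" else params.p_recurrent_annual
    if arm == "pcsk9i" and not params.discontinuation_removes_effect:
        p_off = p_trt
    else:
        p_off = params.p_recurrent_annual
    mb, mp, d = (
        params.p_mort_background_annual,
        params.p_mort_poststroke_annual,
        params.discontinuation_annual,
    )
    x = {s: 0.0 for s in STATES}
    x["stable_on" if arm == "pcsk9i" else "stable_off"] = 1.0
    qaly = drug = care = 0.0
    for k in range(1, params.horizon_years + 1):
        disc = (1 + params.discount_rate_annual) ** -(k - 1)
        entries = x["stable_on"] * p_on + x["stable_off"] * p_off
        nxt = {
            "stable_on": x["stable_on"] * (1 - p_on - mb) * (1 - d),
            "stable_off": x["stable_off"] * (1 - p_off - mb)
            + x["stable_on"] * (1 - p_on - mb) * d,
            "recurrent_on": x["recurrent_on"] * (1 - mp) * (1 - d)
            + x["stable_on"] * p_on,
            "recurrent_off": x["recurrent_off"] * (1 - mp)
            + x["recurrent_on"] * (1 - mp) * d
            + x["stable_off"] * p_off,
            "dead": x["dead"]
            + (x["stable_on"] + x["stable_off"]) * mb
            + (x["recurrent_on"] + x["recurrent_off"]) * mp,
        }
        rx = x if params.cycle_accounting == "start" else nxt
        stable = rx["stable_on"] + rx["stable_off"]
        rec = rx["recurrent_on"] + rx["recurrent_off"]
        qaly += disc * (params.u_stable * stable + params.u_recurrent * rec)
        care += disc * (
            params.c_stroke_state_annual * rec
            + params.c_stroke_event_acute * entries
        )
        price_k = params.price.annual_cost_by_year[k - 1]
        if arm == "pcsk9i":
            if params.drug_cost_basis == "annuity":
                drug += disc * price_k
            else:
                drug += disc * price_k * (rx["stable_on"] + rx["recurrent_on"])
        x = nxt
    return qaly, drug, care


def test_engine_matches_loop_oracle_on_random_parameters():
    rng = np.random.default_rng(7)
    for _ in range(50):
        params = _random_params(rng)
        for arm in ("standard", "pcsk9i"):
            res = run_cohort(params, arm)
            qaly, drug, care = _oracle_run(params, arm)
            assert res.total_qaly_discounted == pytest.approx(qaly, abs=1e-10)
            assert res.drug_cost_component == pytest.approx(drug, abs=1e-10)
            assert res.care_cost_component == pytest.approx(care, abs=1e-10)
            # occupancy conservation and monotone death fraction
            trace = res.occupancy_trace
            np.testing.assert_allclose(trace.sum(axis=1), 1.0, atol=1e-12)
            assert (np.diff(trace["dead"]) >= -1e-15).all()


def test_cost_linearity_and_zero_discount(base_params):
    res = run_cohort(base_params, "pcsk9i")
    doubled = base_params.with_(
        price=base_params.price.scaled(2.0),
        c_stroke_state_annual=2 * base_params.c_stroke_state_annual,
        c_stroke_event_acute=2 * base_params.c_stroke_event_acute,
    )
    res2 = run_cohort(doubled, "pcsk9i")
    assert res2.total_cost_discounted == pytest.approx(
        2 * res.total_cost_discounted, rel=1e-12
    )
    assert res2.total_qaly_discounted == res.total_qaly_discounted

    undisc = base_params.with_(discount_rate_annual=0.0)
    res0 = run_cohort(undisc, "standard")
    qaly, drug, care = _oracle_run(undisc, "standard")
    assert res0.total_qaly_discounted == pytest.approx(qaly, abs=1e-12)


def test_qaly_monotone_in_rrr(base_params):
    qalys = [
        run_cohort(base_params.with_(rrr=r), "pcsk9i").total_qaly_discounted
        for r in np.linspace(0.0, 0.9, 10)
    ]
    assert all(b >= a for a, b in zip(qalys, qalys[1:]))


def test_incremental_flags(base_params):
    # null effect, positive price: no QALY gain, ICER undefined
    inc = incremental(base_params.with_(rrr=0.0))
    assert inc.delta_qaly == pytest.approx(0.0, abs=1e-14)
    assert inc.delta_cost > 0
    assert inc.icer is None and inc.flag == "undefined"

    # near-total prevention with a free drug: dominant
    free = base_params.with_(rrr=0.95, price=PriceSchedule.flat(0.0))
    inc = incremental(free)
    assert inc.flag == "dominant" and inc.delta_cost < 0 < inc.delta_qaly

    # base case: conventional ICER
    inc = incremental(base_params)
    assert inc.flag == "icer"
    assert inc.icer == pytest.approx(inc.delta_cost / inc.delta_qaly)
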