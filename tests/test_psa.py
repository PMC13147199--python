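"""PSA: moment matching, Wilson intervals, degenerate and seeded runs."""

import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from icas_cea import (
    MarkovParameters,
    PriceSchedule,
    incremental,
    moments_to_beta,
    moments_to_gamma,
    plane_export,
    run_psa,
    wilson_interval,
)
from icas_cea.psa import Beta, CoxMappedRRR, Gamma, LdlMappedRRR, PointMass

from conftest import make_point_dists


def test_beta_method_of_moments_closed_form():
    a, b = moments_to_beta(0.9, 0.15)
    assert a == pytest.approx(2.7, abs=1e-12)
    assert b == pytest.approx(0.3, abs=1e-12)
    with pytest.raises(ValueError, match="too large"):
        moments_to_beta(0.9, 0.31)
    with pytest.raises(ValueError):
        moments_to_beta(1.2, 0.1)


def test_gamma_method_of_moments_closed_form():
    shape, scale = moments_to_gamma(6600, 0.2)
    assert shape == pytest.approx(25.0, abs=1e-12)
    assert scale == pytest.approx(264.0, abs=1e-12)
    with pytest.raises(ValueError):
        moments_to_gamma(-1.0, 0.2)
    with pytest.raises(ValueError):
        moments_to_gamma(100.0, 0.0)


def test_moment_round_trip_by_sampling():
    rng = np.random.default_rng(0)
    n = 200_000
    for dist, mean, spread in [(Beta(0.9, 0.15), 0.9, 0.15), (Beta(0.5, 0.1), 0.5, 0.1)]:
        x = dist.draw(rng, n)
        assert abs(x.mean() - mean) < 3 * spread / np.sqrt(n)
        assert abs(x.std() - spread) < 0.003
    g = Gamma(6600, 0.2).draw(rng, n)
    assert abs(g.mean() - 6600) < 3 * 6600 * 0.2 / np.sqrt(n)
    assert abs(g.std() / g.mean() - 0.2) < 0.003


def test_point_mass_substitution_below_threshold():
    rng = np.random.default_rng(1)
    assert Beta(0.5, 0.0).draw(rng) == 0.5
    assert Gamma(6600, 0.0).draw(rng) == 6600


@pytest.mark.parametrize(
    "k, n, lo_pct, hi_pct",
    [
        (586, 1000, 55.5, 61.6),
        (538, 1000, 50.7, 56.9),
        (367, 1000, 33.8, 39.7),
    ],
)
def test_wilson_reproduces_published_intervals(k, n, lo_pct, hi_pct):
    lo, hi = wilson_interval(k, n)
    assert round(100 * lo, 1) == lo_pct
    assert round(100 * hi, 1) == hi_pct


def test_wilson_against_statsmodels_and_boundaries():
    for k, n in [(0, 10), (1, 7), (5, 10), (10, 10), (42, 99)]:
        lo, hi = wilson_interval(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, method="wilson")
        assert lo == pytest.approx(sm_lo, abs=1e-10)
        assert hi == pytest.approx(sm_hi, abs=1e-10)
    lo, hi = wilson_interval(0, 10)
    assert lo == 0.0 and hi > 0.0
    with pytest.raises(ValueError):
        wilson_interval(5, 4)
    with pytest.raises(ValueError):
        wilson_interval(-1, 4)


def test_point_mass_psa_equals_deterministic_engine(base_params, point_dists):
    res = run_psa(base_params, point_dists, n_iter=20, seed=3)
    inc = incremental(base_params)
    assert res.n_redraws == 0
    np.testing.assert_allclose(res.draws["delta_cost"], inc.delta_cost, rtol=1e-12)
    np.testing.assert_allclose(res.draws["delta_qaly"], inc.delta_qaly, rtol=1e-12)
    # all iterations identical, so the CE probability is 0 or 1
    for wtp, (p, lo, hi) in res.ce_probability.items():
        nmb = wtp * inc.delta_qaly - inc.delta_cost
        assert p == (1.0 if nmb > 0 else 0.0)
        assert lo <= p <= hi


def test_seeded_determinism(base_params, loose_cost_dists):
    r1 = run_psa(base_params, loose_cost_dists, n_iter=50, seed=11)
    r2 = run_psa(base_params, loose_cost_dists, n_iter=50, seed=11)
    r3 = run_psa(base_params, loose_cost_dists, n_iter=50, seed=12)
    assert r1.draws.equals(r2.draws)
    assert not r1.draws.equals(r3.draws)


def test_zero_wtp_counts_cost_saving_iterations(base_params, loose_cost_dists):
    res = run_psa(base_params, loose_cost_dists, n_iter=100, seed=5, wtps=(0.0, 120e3))
    assert res.ce_probability[0.0][0] == (res.draws["delta_cost"] < 0).mean()


def test_ce_monotonicity_under_common_random_numbers(base_params):
    # identical seeds reuse identical draws, so these orderings are exact
    def ce(price=6600.0, rrr_dist=None, wtp=120_000.0):
        dists = make_point_dists(base_params).with_(
            u_stable=Beta(0.9, 0.15),
            u_recurrent=Beta(0.5, 0.15),
            price_multiplier=Gamma(1.0, 0.2),
            rrr=rrr_dist or PointMass(0.32),
        )
        params = base_params.with_(price=PriceSchedule.flat(price))
        res = run_psa(params, dists, n_iter=300, seed=17, wtps=(wtp,))
        return res.ce_probability[wtp][0]

    assert ce(price=3000) >= ce(price=6600) >= ce(price=9000)
    assert ce(wtp=50_000) <= ce(wtp=120_000) <= ce(wtp=200_000)
    assert ce(rrr_dist=PointMass(0.20)) <= ce(rrr_dist=PointMass(0.32)) <= ce(
        rrr_dist=PointMass(0.50)
    )


def test_summaries_recomputable_from_draws(base_params, loose_cost_dists):
    res = run_psa(base_params, loose_cost_dists, n_iter=200, seed=2)
    s = res.summaries()
    d = res.draws
    assert s["delta_cost"]["median"] == pytest.approx(np.median(d["delta_cost"]))
    assert s["delta_qaly_mean"] == pytest.approx(d["delta_qaly"].mean())
    k = int((d["nmb_120000"] > 0).sum())
    assert res.ce_probability[120_000.0][0] == k / res.n_iter
    assert res.ce_probability[120_000.0][1:] == wilson_interval(k, res.n_iter)
    assert "P(CE)" in res.summary()


def test_plane_export_round_trip(base_params, loose_cost_dists):
    res = run_psa(base_params, loose_cost_dists, n_iter=150, seed=8)
    plane = plane_export(res)
    assert len(plane) == res.n_iter
    recomputed = (
        120_000.0 * plane["delta_qaly"] - plane["delta_cost"] > 0
    ).astype(int)
    np.testing.assert_array_equal(recomputed, plane["ce_at_120000"])


def test_invalid_draws_are_redrawn_or_rejected(base_params):
    # utilities drawn around an inverted ordering: some redraws, still valid
    dists = make_point_dists(base_params).with_(
        u_stable=PointMass(0.55), u_recurrent=Beta(0.5, 0.15)
    )
    res = run_psa(base_params, dists, n_iter=100, seed=1)
    assert res.n_redraws > 0
    assert (res.draws["delta_qaly"].notna()).all()

    # impossible ordering every draw: explicit failure, not an infinite loop
    hopeless = make_point_dists(base_params).with_(
        u_stable=PointMass(0.3), u_recurrent=PointMass(0.6)
    )
    with pytest.raises(RuntimeError, match="valid parameters"):
        run_psa(base_params, hopeless, n_iter=5, seed=1)


def test_rrr_mapping_anchors_at_base_case():
    rng = np.random.default_rng(0)
    ldl = LdlMappedRRR(0.32, 0.60, 0.0)
    assert ldl.draw(rng) == pytest.approx(0.32, abs=1e-12)
    cox = CoxMappedRRR(rrr_base=0.32, red_sd=0.0, log_hr_se=0.0)
    assert cox.draw(rng) == pytest.approx(0.32, abs=1e-12)
    # spread-free anchor generalises: draws stay below 1
    draws = CoxMappedRRR().draw(rng, 5000)
    assert (draws < 1.0).all()
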