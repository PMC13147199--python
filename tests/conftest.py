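import pytest

from icas_cea import CohortSpec, CoxEffectModel, MarkovParameters, generate_cohort
from icas_cea.psa import Gamma, ParameterDistributions, PointMass


@pytest.fixture(scope="session")
def default_cohort():
    """Trial-sized synthetic cohort (n=367) under default calibration."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Cox fit on the default cohort (shared; fitting is the slow part)."""
    return CoxEffectModel(default_cohort).fit()


@pytest.fixture
def base_params():
    return MarkovParameters()


def make_point_dists(params: MarkovParameters) -> ParameterDistributions:
    """Degenerate distributions pinning the PSA at one parameter set."""
    return ParameterDistributions(
        p_recurrent=PointMass(params.p_recurrent_annual),
        p_mort_background=PointMass(params.p_mort_background_annual),
        p_mort_poststroke=PointMass(params.p_mort_poststroke_annual),
        u_stable=PointMass(params.u_stable),
        u_recurrent=PointMass(params.u_recurrent),
        rrr=PointMass(params.rrr),
        price_multiplier=PointMass(1.0),
        c_stroke_state_annual=PointMass(params.c_stroke_state_annual),
        c_stroke_event_acute=PointMass(params.c_stroke_event_acute),
    )


@pytest.fixture
def point_dists(base_params):
    return make_point_dists(base_params)


@pytest.fixture
def loose_cost_dists(base_params):
    """Cost uncertainty only — cheap, deterministic elsewhere."""
    return make_point_dists(base_params).with_(
        price_multiplier=Gamma(1.0, 0.20),
        c_stroke_state_annual=Gamma(base_params.c_stroke_state_annual, 0.085),
    )
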