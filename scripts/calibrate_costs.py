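"""Calibrate the stroke-care cost defaults.

The one-time acute cost of a recurrent stroke and the annual cost of
living in the recurrent-stroke state are not fixed by published unit
costs.  Their *ratio* is set a priori at 1.75:1 (the index admission
dominates US stroke-care spending; episode costs of an acute ischemic
stroke admission run well above the annual maintenance cost of a
disabled survivor) and their *level* is calibrated so the
probabilistic median 5-year discounted standard-care cost equals the
published ~$35.9k.  Standard-care cost is exactly linear in the common
scale factor, so a single PSA at a reference level identifies the
calibrated pair in closed form.

Run from the repository root:

    python scripts/calibrate_costs.py

The resulting values (rounded to $50) are frozen as
DEFAULT_C_STROKE_EVENT_ACUTE / DEFAULT_C_STROKE_STATE_ANNUAL in
icas_cea.markov; this script records how they were obtained and
verifies the result, also reporting the implied median incremental
cost at the alirocumab direct-to-consumer price as a cross-check.
"""

import numpy as np

from icas_cea.markov import MarkovParameters, PriceSchedule
from icas_cea.psa import CARE_COST_CV, Gamma, ParameterDistributions, run_psa

TARGET_MEDIAN_STANDARD_COST = 35_900.0  # 2025 USD, 5-year discounted
RATIO_ACUTE_TO_ANNUAL = 1.75
REFERENCE_ANNUAL = 15_000.0
CALIBRATION_SEED = 20_250_101
N_ITER = 20_000


def _run(c_event: float, c_state: float):
    base = MarkovParameters().with_(
        price=PriceSchedule.flat(6600.0, name="alirocumab"),
        c_stroke_event_acute=c_event,
        c_stroke_state_annual=c_state,
    )
    dists = ParameterDistributions(
        c_stroke_event_acute=Gamma(c_event, CARE_COST_CV),
        c_stroke_state_annual=Gamma(c_state, CARE_COST_CV),
    )
    return run_psa(base, dists, n_iter=N_ITER, seed=CALIBRATION_SEED)


def main() -> None:
    ref = _run(RATIO_ACUTE_TO_ANNUAL * REFERENCE_ANNUAL, REFERENCE_ANNUAL)
    median_ref = float(np.median(ref.draws["cost_standard"]))
    scale = TARGET_MEDIAN_STANDARD_COST / median_ref
    annual = REFERENCE_ANNUAL * scale
    acute = RATIO_ACUTE_TO_ANNUAL * annual
    acute_r, annual_r = (round(x / 50.0) * 50.0 for x in (acute, annual))
    print(f"median standard-care cost at reference "
          f"(${RATIO_ACUTE_TO_ANNUAL * REFERENCE_ANNUAL:,.0f} acute / "
          f"${REFERENCE_ANNUAL:,.0f} annual): ${median_ref:,.2f}")
    print(f"calibrated: acute ${acute:,.2f}, annual ${annual:,.2f} "
          f"(rounded: ${acute_r:,.0f} / ${annual_r:,.0f})")

    check = _run(acute_r, annual_r)
    med_std = float(np.median(check.draws["cost_standard"]))
    med_dc = float(np.median(check.draws["delta_cost"]))
    print(f"verification at rounded values: median standard ${med_std:,.0f} "
          f"(target ${TARGET_MEDIAN_STANDARD_COST:,.0f}); "
          f"median incremental at alirocumab DTC ${med_dc:,.0f}")


if __name__ == "__main__":
    main()
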