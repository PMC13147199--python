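"""Scenario grid and threshold (equipoise) price analyses.

Scenarios rerun the PSA with declared overrides: an alternative
treatment effect (conservative 20%, optimistic 50%), scaled stroke-care
costs (50% / 150%), alternative flat drug prices, and the published
out-of-pocket schedules.  The threshold analysis finds the flat annual
drug price at which the probability of cost-effectiveness at a given
willingness-to-pay reaches a target (50% equipoise, 75%, 90%), by
bisection with common random numbers across price evaluations — the
same seed is reused for every candidate price, so the probability-price
curve is monotone non-increasing and the crossing is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .markov import MarkovParameters, PriceSchedule
from .psa import Gamma, ParameterDistributions, PointMass, PSAResult, run_psa

__all__ = [
    "ScenarioSpec",
    "ThresholdResult",
    "builtin_schedules",
    "run_scenario",
    "threshold_price",
]


def builtin_schedules(horizon_years: int = 5) -> dict[str, PriceSchedule]:
    """Catalogue of published drug price schedules (2025 USD).

    Direct-to-consumer (DTC): alirocumab $6600/yr, evolocumab $7200/yr,
    inclisiran $10,800 in year 1 then $7200/yr.  Out-of-pocket (OOP)
    Medicare/commercial: $600/yr for alirocumab and evolocumab; $2160
    then $1440/yr for inclisiran.  The ``*_fss`` entries are editable
    placeholders only — Federal Supply Schedule prices are not published
    in the source material and the shipped values are *not*
    authoritative; replace them with current FSS quotes before use.
    """
    h = horizon_years

    def sched(name, first, rest=None):
        rest = first if rest is None else rest
        return PriceSchedule(name, (float(first),) + (float(rest),) * (h - 1))

    return {
        "alirocumab": sched("alirocumab", 6600),
        "evolocumab": sched("evolocumab", 7200),
        "inclisiran": sched("inclisiran", 10_800, 7200),
        "alirocumab_oop": sched("alirocumab_oop", 600),
        "evolocumab_oop": sched("evolocumab_oop", 600),
        "inclisiran_oop": sched("inclisiran_oop", 2160, 1440),
        # synthetic placeholders, not published values
        "alirocumab_fss": sched("alirocumab_fss", 6600),
        "evolocumab_fss": sched("evolocumab_fss", 7200),
        "inclisiran_fss": sched("inclisiran_fss", 10_800, 7200),
    }


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid.

    ``rrr_override`` replaces the treatment-effect distribution with a
    point mass; ``stroke_cost_multiplier`` scales the means of both
    stroke-care cost distributions (CV unchanged).
    """

    name: str
    price_schedule: PriceSchedule
    rrr_override: float | None = None
    stroke_cost_multiplier: float = 1.0
    wtps: tuple[float, ...] = (50_000.0, 120_000.0)

    def validate(self) -> None:
        if self.stroke_cost_multiplier <= 0:
            raise ValueError(
                f"stroke_cost_multiplier must be > 0, got {self.stroke_cost_multiplier}"
            )
        if self.rrr_override is not None and not self.rrr_override < 1.0:
            raise ValueError(f"rrr_override must be < 1, got {self.rrr_override}")
        if not self.wtps:
            raise ValueError("wtps must be non-empty")


def run_scenario(
    spec: ScenarioSpec,
    base: MarkovParameters,
    dists: ParameterDistributions | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Apply the scenario's overrides and delegate to :func:`run_psa`."""
    spec.validate()
    if dists is None:
        dists = ParameterDistributions()
    base = base.with_(price=spec.price_schedule)
    updates: dict = {}
    if spec.rrr_override is not None:
        base = base.with_(rrr=spec.rrr_override)
        updates["rrr"] = PointMass(spec.rrr_override)
    if spec.stroke_cost_multiplier != 1.0:
        m = spec.stroke_cost_multiplier
        for name in ("c_stroke_state_annual", "c_stroke_event_acute"):
            d = getattr(dists, name)
            if isinstance(d, Gamma):
                updates[name] = d.scaled(m)
            elif isinstance(d, PointMass):
                updates[name] = PointMass(d.value * m)
            else:
                raise TypeError(
                    f"cannot scale distribution of type {type(d).__name__} for {name}"
                )
        base = base.with_(
            c_stroke_state_annual=base.c_stroke_state_annual * m,
            c_stroke_event_acute=base.c_stroke_event_acute * m,
        )
    if updates:
        dists = dists.with_(**updates)
    return run_psa(
        base, dists, n_iter=n_iter, seed=seed, wtps=spec.wtps, label=spec.name
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the threshold-price bisection."""

    target_probability: float
    wtp: float
    annual_price: float
    achieved_probability: float
    search_trace: tuple[tuple[float, float], ...] = field(default=())


def _ce_prob_at_price(
    price: float,
    base: MarkovParameters,
    dists: ParameterDistributions,
    wtp: float,
    n_iter: int,
    seed: int,
) -> float:
    params = base.with_(
        price=PriceSchedule.flat(price, base.horizon_years, name="threshold_search")
    )
    res = run_psa(params, dists, n_iter=n_iter, seed=seed, wtps=(wtp,))
    return res.ce_probability[wtp][0]


def threshold_price(
    base: MarkovParameters,
    dists: ParameterDistributions | None = None,
    wtp: float = 120_000.0,
    target_probability: float = 0.50,
    n_iter: int = 1000,
    seed: int = 0,
    price_bounds: tuple[float, float] = (0.0, 30_000.0),
    price_tol: float = 50.0,
    prob_tol: float = 0.005,
) -> ThresholdResult:
    """Flat annual drug price achieving a target CE probability.

    Bisects over the price with common random numbers (every evaluation
    is a full ``n_iter``-iteration PSA under the same seed).  Stops when
    the bracket is narrower than ``price_tol`` dollars or the achieved
    probability is within ``prob_tol`` of the target.  Raises if the
    endpoint probabilities do not bracket the target.
    """
    if not 0.0 < target_probability < 1.0:
        raise ValueError(
            f"target_probability must be in (0, 1), got {target_probability}"
        )
    if dists is None:
        dists = ParameterDistributions()
    lo, hi = price_bounds
    if not 0.0 <= lo < hi:
        raise ValueError(f"invalid price bounds {price_bounds}")

    trace: list[tuple[float, float]] = []
    p_lo = _ce_prob_at_price(lo, base, dists, wtp, n_iter, seed)
    p_hi = _ce_prob_at_price(hi, base, dists, wtp, n_iter, seed)
    trace += [(lo, p_lo), (hi, p_hi)]
    # CE probability is non-increasing in price under common random numbers
    if not (p_lo >= target_probability >= p_hi):
        raise ValueError(
            f"price bounds do not bracket the target: P(CE) is {p_lo:.3f} at "
            f"${lo:,.0f} and {p_hi:.3f} at ${hi:,.0f}, target {target_probability}"
        )

    price, prob = lo, p_lo
    while hi - lo > price_tol:
        mid = 0.5 * (lo + hi)
        p_mid = _ce_prob_at_price(mid, base, dists, wtp, n_iter, seed)
        trace.append((mid, p_mid))
        price, prob = mid, p_mid
        if abs(p_mid - target_probability) <= prob_tol:
            break
        if p_mid >= target_probability:
            lo = mid
        else:
            hi = mid
    else:
        price = 0.5 * (lo + hi)
        prob = _ce_prob_at_price(price, base, dists, wtp, n_iter, seed)
        trace.append((price, prob))

    return ThresholdResult(
        target_probability=target_probability,
        wtp=wtp,
        annual_price=price,
        achieved_probability=prob,
        search_trace=tuple(trace),
    )
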