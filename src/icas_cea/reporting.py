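"""Result tables and the end-to-end reproduction pipeline.

All reported numbers are recomputed from the persisted per-iteration
draws — nothing is cached — so a results table can always be checked
against the CSV of draws that accompanies it.  Display rounding follows
health-economics convention (whole dollars, percentages to one
decimal); full-precision values are persisted alongside every table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort, summarize_cohort, write_cohort
from .effect import CoxEffectModel, LdlEffect, project_margins
from .markov import MarkovParameters
from .psa import ParameterDistributions, PSAResult, plane_export, run_psa
from .scenarios import ScenarioSpec, builtin_schedules, run_scenario, threshold_price

__all__ = ["RunConfig", "make_table2", "end_to_end"]

logger = logging.getLogger(__name__)


def _fmt_usd(x: float) -> str:
    return f"{x:,.0f}".replace(",", " ")


def _fmt_pct_ci(p: float, lo: float, hi: float) -> str:
    return f"{100*p:.1f} ({100*lo:.1f}-{100*hi:.1f})"


def make_table2(results: Mapping[str, PSAResult]) -> pd.DataFrame:
    """Model-outcomes table: one column per drug, rows for median (95% CI)
    costs, median (IQR) QALYs, the median ICER and CE probabilities with
    Wilson intervals.  Everything is recomputed from the stored draws."""
    if not results:
        raise ValueError("no PSA results supplied")
    cols = {}
    for drug, res in results.items():
        if res.draws is None or len(res.draws) == 0:
            raise ValueError(f"PSA result for {drug!r} has no draws")
        s = res.summaries()
        col = {
            "Costs standard care, median (95% CI), $": (
                f"{_fmt_usd(s['cost_standard']['median'])} "
                f"({_fmt_usd(s['cost_standard']['lo'])} to {_fmt_usd(s['cost_standard']['hi'])})"
            ),
            "Costs PCSK9i, median (95% CI), $": (
                f"{_fmt_usd(s['cost_pcsk9i']['median'])} "
                f"({_fmt_usd(s['cost_pcsk9i']['lo'])} to {_fmt_usd(s['cost_pcsk9i']['hi'])})"
            ),
            "Costs incremental, median (95% CI), $": (
                f"{_fmt_usd(s['delta_cost']['median'])} "
                f"({_fmt_usd(s['delta_cost']['lo'])} to {_fmt_usd(s['delta_cost']['hi'])})"
            ),
            "QALYs standard care, median (IQR)": (
                f"{s['qaly_standard']['median']:.2f} "
                f"({s['qaly_standard']['lo']:.2f} to {s['qaly_standard']['hi']:.2f})"
            ),
            "QALYs PCSK9i, median (IQR)": (
                f"{s['qaly_pcsk9i']['median']:.2f} "
                f"({s['qaly_pcsk9i']['lo']:.2f} to {s['qaly_pcsk9i']['hi']:.2f})"
            ),
            "QALYs incremental, median (IQR)": (
                f"{s['delta_qaly']['median']:.2f} "
                f"({s['delta_qaly']['lo']:.2f} to {s['delta_qaly']['hi']:.2f})"
            ),
            "ICER, median (95% CI), $/QALY": (
                f"{_fmt_usd(s['icer']['median'])} "
                f"({_fmt_usd(s['icer']['lo'])} to {_fmt_usd(s['icer']['hi'])})"
                if s["icer"]
                else "NA"
            ),
        }
        for wtp, (p, lo, hi) in res.ce_probability.items():
            col[f"Probability CE at ${_fmt_usd(wtp)}/QALY, %"] = _fmt_pct_ci(p, lo, hi)
        cols[drug] = col
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class RunConfig:
    """Inputs, sizes and seed for one end-to-end reproduction run."""

    out_dir: Path
    seed: int = 1
    n_iter: int = 1000
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    base_params: MarkovParameters = field(default_factory=MarkovParameters)
    dists: ParameterDistributions = field(default_factory=ParameterDistributions)
    ldl_effect: LdlEffect = field(default_factory=LdlEffect)
    drugs: tuple[str, ...] = ("alirocumab", "evolocumab", "inclisiran")
    wtps: tuple[float, ...] = (50_000.0, 120_000.0)
    run_scenarios: bool = True
    run_threshold: bool = True
    verbosity: int = 1

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValueError(f"n_iter must be >= 1, got {self.n_iter}")
        catalog = builtin_schedules(self.base_params.horizon_years)
        for d in self.drugs:
            if d not in catalog:
                raise ValueError(f"unknown drug schedule {d!r}")
        if not self.wtps:
            raise ValueError("wtps must be non-empty")


def _sidecar(path: Path, payload: dict) -> None:
    payload = {"version": __version__, **payload}
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n"
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def end_to_end(config: RunConfig) -> dict:
    """Run cohort -> effect synthesis -> PSA -> scenarios -> tables.

    Writes every artifact under ``config.out_dir`` with a JSON
    provenance sidecar (seed, sizes, parameter echo).  Rerunning with
    the same config reproduces byte-identical numeric outputs.  Returns
    a manifest mapping artifact names to paths and checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict[str, dict] = {}

    def stage(name):
        if config.verbosity:
            logger.info("[%7.2fs] stage: %s", time.time() - t0, name)

    def record(name: str, path: Path, **prov):
        _sidecar(path, {"seed": config.seed, "n_iter": config.n_iter, **prov})
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    # 1. synthetic cohort
    stage("cohort")
    try:
        spec = config.cohort_spec.with_(seed=config.seed)
        cohort = generate_cohort(spec)
        cohort_path = out / "cohort.csv"
        write_cohort(cohort, cohort_path)
        record("cohort", cohort_path, cohort_spec=spec.__dict__)
        summary = summarize_cohort(cohort)
        (out / "cohort_summary.csv").write_text(summary.to_frame().to_csv())
        record("cohort_summary", out / "cohort_summary.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'cohort' failed: {err}") from err

    # 2. evidence synthesis
    stage("effect")
    try:
        fit = CoxEffectModel(cohort).fit()
        est = project_margins(
            fit, cohort, config.ldl_effect, n_boot=200, seed=config.seed
        )
        effect_path = out / "effect.json"
        effect_path.write_text(
            json.dumps(
                {
                    "estimate": est.to_dict(),
                    "coefficients": fit.coefficients.to_dict(),
                    "n_events": fit.n_events,
                    "concordance": fit.concordance,
                    "ldl_effect": config.ldl_effect.__dict__,
                },
                indent=2,
            )
            + "\n"
        )
        record("effect", effect_path)
    except Exception as err:
        raise RuntimeError(f"stage 'effect' failed: {err}") from err

    # 3. PSA per drug
    stage("psa")
    catalog = builtin_schedules(config.base_params.horizon_years)
    psa_results: dict[str, PSAResult] = {}
    try:
        for drug in config.drugs:
            params = config.base_params.with_(price=catalog[drug])
            res = run_psa(
                params,
                config.dists,
                n_iter=config.n_iter,
                seed=config.seed,
                wtps=config.wtps,
                label=drug,
            )
            psa_results[drug] = res
            draws_path = out / f"psa_draws_{drug}.csv"
            res.draws.to_csv(draws_path, index=False, float_format="%.12g")
            record(f"psa_draws_{drug}", draws_path, drug=drug)
            plane_path = out / f"plane_{drug}.csv"
            plane_export(res).to_csv(plane_path, index=False, float_format="%.12g")
            record(f"plane_{drug}", plane_path, drug=drug)
            summary_path = out / f"psa_summary_{drug}.json"
            summary_path.write_text(json.dumps(res.summaries(), indent=2) + "\n")
            record(f"psa_summary_{drug}", summary_path, drug=drug)
    except Exception as err:
        raise RuntimeError(f"stage 'psa' failed: {err}") from err

    # 4. scenario grid
    if config.run_scenarios:
        stage("scenarios")
        try:
            rows = []
            grid: list[ScenarioSpec] = []
            for drug in config.drugs:
                sched = catalog[drug]
                grid += [
                    ScenarioSpec(f"{drug}_base", sched, wtps=config.wtps),
                    ScenarioSpec(
                        f"{drug}_rrr20", sched, rrr_override=0.20, wtps=config.wtps
                    ),
                    ScenarioSpec(
                        f"{drug}_rrr50", sched, rrr_override=0.50, wtps=config.wtps
                    ),
                    ScenarioSpec(
                        f"{drug}_cost50",
                        sched,
                        stroke_cost_multiplier=0.5,
                        wtps=config.wtps,
                    ),
                    ScenarioSpec(
                        f"{drug}_cost150",
                        sched,
                        stroke_cost_multiplier=1.5,
                        wtps=config.wtps,
                    ),
                    ScenarioSpec(f"{drug}_oop", catalog[f"{drug}_oop"], wtps=config.wtps),
                ]
            for spec_ in grid:
                res = run_scenario(
                    spec_,
                    config.base_params,
                    config.dists,
                    n_iter=config.n_iter,
                    seed=config.seed,
                )
                s = res.summaries()
                for wtp in config.wtps:
                    p, lo, hi = res.ce_probability[wtp]
                    rows.append(
                        {
                            "scenario": spec_.name,
                            "price_schedule": spec_.price_schedule.name,
                            "rrr_override": spec_.rrr_override,
                            "stroke_cost_multiplier": spec_.stroke_cost_multiplier,
                            "wtp": wtp,
                            "ce_probability": p,
                            "ce_wilson_lo": lo,
                            "ce_wilson_hi": hi,
                            "icer_median": s["icer"]["median"] if s["icer"] else np.nan,
                            "delta_cost_median": s["delta_cost"]["median"],
                            "delta_qaly_median": s["delta_qaly"]["median"],
                        }
                    )
            scen_path = out / "scenarios.csv"
            pd.DataFrame(rows).to_csv(scen_path, index=False, float_format="%.12g")
            record("scenarios", scen_path)
        except Exception as err:
            raise RuntimeError(f"stage 'scenarios' failed: {err}") from err

    # 5. threshold analysis
    if config.run_threshold:
        stage("threshold")
        try:
            rows = []
            for target in (0.50, 0.75, 0.90):
                res = threshold_price(
                    config.base_params,
                    config.dists,
                    wtp=120_000.0,
                    target_probability=target,
                    n_iter=config.n_iter,
                    seed=config.seed,
                )
                rows.append(
                    {
                        "target_probability": target,
                        "wtp": res.wtp,
                        "annual_price": res.annual_price,
                        "achieved_probability": res.achieved_probability,
                    }
                )
            thr_path = out / "threshold_prices.csv"
            pd.DataFrame(rows).to_csv(thr_path, index=False, float_format="%.12g")
            record("threshold_prices", thr_path)
        except Exception as err:
            raise RuntimeError(f"stage 'threshold' failed: {err}") from err

    # 6. outcome table
    stage("table")
    try:
        table = make_table2(psa_results)
        table_path = out / "table_outcomes.csv"
        table.to_csv(table_path)
        record("table_outcomes", table_path)
    except Exception as err:
        raise RuntimeError(f"stage 'table' failed: {err}") from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    stage("done")
    return manifest
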