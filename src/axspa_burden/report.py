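"""Run orchestration and rendering of the summary tables.

Builds the full base-case + PSA + extrapolation result bundle and renders it
as comma-separated tables (cost-by-category, cost-by-sex-and-category,
national scenarios, per-year cost series) plus one machine-readable JSON
report.  Rendering is deterministic: the same report renders byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np

from . import __version__
from .cohort import CohortTrace, mean_time_to_diagnosis, mix_cohorts, run_cohort_pair
from .costing import (
    CATEGORIES,
    CostBreakdown,
    accumulate_costs,
    healthcare_cycle_cost,
    oop_cycle_cost,
    productivity_cycle_cost,
)
from .extrapolation import NationalEstimate, build_scenarios
from .mortality import LifeTable
from .parameters import ParameterSet
from .psa import PSAResult, run_psa

__all__ = ["RunReport", "category_share", "build_report", "render_tables"]


def category_share(component: float, total: float) -> float:
    """Category share of the total, in percent (unrounded; rounding is a
    render-time concern)."""
    if total <= 0:
        raise ValueError("share undefined for a nonpositive total")
    return 100.0 * component / total


@dataclass(frozen=True)
class RunReport:
    """Everything a full model run produces, ready to render."""

    params: ParameterSet
    seed: int
    traces: dict[str, CohortTrace]  # male / female / mixed
    breakdowns: dict[str, CostBreakdown]  # male / female / mixed
    psa: PSAResult | None
    national: list[NationalEstimate]
    per_year_cost: np.ndarray  # undiscounted mixed cost per year since onset
    annual_cost_per_ttd_year: float  # cumulative discounted total / mean TTD
    annual_cost_first_year: float  # undiscounted first-year cost

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.params.to_yaml().encode()).hexdigest()[:16]

    def shares(self, which: str = "mixed") -> dict[str, float]:
        totals = self.breakdowns[which].totals()
        return {c: category_share(totals[c], totals["total"]) for c in CATEGORIES}


def _undiscounted_yearly_costs(
    trace: CohortTrace, params: ParameterSet, sex: str
) -> np.ndarray:
    """Expected undiscounted cost per year since onset (per cohort member)."""
    occ_u = trace.occupancy[:, 0]
    hc = healthcare_cycle_cost(params)
    oop = oop_cycle_cost(params)
    per_cycle = np.array(
        [
            (hc + oop + productivity_cycle_cost(params, sex, age)) * occ_u[t]
            for t, age in enumerate(trace.attained_age)
        ]
    )
    n_years = int(np.ceil(len(per_cycle) / 4))
    padded = np.zeros(n_years * 4)
    padded[: len(per_cycle)] = per_cycle
    return padded.reshape(n_years, 4).sum(axis=1)


def build_report(
    params: ParameterSet,
    life_table: LifeTable,
    seed: int = 0,
    n_draws: int = 1000,
    with_psa: bool = True,
) -> RunReport:
    """Run the whole pipeline at the base case (plus PSA) and collect it."""
    traces = run_cohort_pair(params, life_table)
    traces["mixed"] = mix_cohorts(traces["male"], traces["female"], params.pct_male)
    breakdowns = {sex: accumulate_costs(traces[sex], params, sex) for sex in ("male", "female")}
    breakdowns["mixed"] = CostBreakdown.mix(
        breakdowns["male"], breakdowns["female"], params.pct_male
    )

    yearly = params.pct_male * _undiscounted_yearly_costs(
        traces["male"], params, "male"
    ) + (1 - params.pct_male) * _undiscounted_yearly_costs(traces["female"], params, "female")

    cumulative_total = breakdowns["mixed"].total("total")
    ttd = mean_time_to_diagnosis(traces["mixed"])
    annual_per_ttd = cumulative_total / ttd
    annual_first_year = float(yearly[0])

    psa = run_psa(params, life_table, n_draws=n_draws, seed=seed) if with_psa else None
    national = build_scenarios(params, annual_per_ttd)
    return RunReport(
        params=params,
        seed=seed,
        traces=traces,
        breakdowns=breakdowns,
        psa=psa,
        national=national,
        per_year_cost=yearly,
        annual_cost_per_ttd_year=annual_per_ttd,
        annual_cost_first_year=annual_first_year,
    )


def _money(x: float) -> str:
    # thousands separators need CSV quoting
    return f'"{x:,.2f}"'


def render_tables(report: RunReport, destination: str | os.PathLike) -> list[str]:
    """Write the table bundle to ``destination``; returns the file paths.

    Files: ``table1_categories.csv`` (mixed cohort by category, with shares
    and PSA summary), ``table2_by_sex.csv``, ``table3_national.csv``,
    ``per_year_costs.csv``, and ``report.json`` (raw floats).
    """
    dest = os.fspath(destination)
    os.makedirs(dest, exist_ok=True)
    paths: list[str] = []

    def write(name: str, lines: list[str]) -> None:
        path = os.path.join(dest, name)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
        paths.append(path)

    shares = report.shares("mixed")
    totals = report.breakdowns["mixed"].totals()
    psa = report.psa
    lines = ["category,base_case_gbp,share_pct,psa_mean_gbp,psa_p2.5_gbp,psa_p97.5_gbp"]
    for c in CATEGORIES + ("total",):
        share = f"{shares[c]:.1f}" if c in shares else "100.0"
        if psa is not None:
            p = f"{_money(psa.mean(c))},{_money(psa.percentile(c, 2.5))},{_money(psa.percentile(c, 97.5))}"
        else:
            p = ",,"
        lines.append(f"{c},{_money(totals[c])},{share},{p}")
    write("table1_categories.csv", lines)

    lines = ["sex,category,base_case_gbp,share_pct"]
    for sex in ("male", "female"):
        t = report.breakdowns[sex].totals()
        for c in CATEGORIES + ("total",):
            share = f"{category_share(t[c], t['total']):.1f}"
            lines.append(f"{sex},{c},{_money(t[c])},{share}")
    write("table2_by_sex.csv", lines)

    lines = [
        "scenario,population,undiagnosed_fraction,per_person_annual_gbp,total_annual_gbp,total_annual_bn"
    ]
    for s in report.national:
        lines.append(
            f"{s.scenario_name},{s.population:.2f},{s.undiagnosed_fraction},"
            f"{_money(s.per_person_annual_cost)},{_money(s.total_annual_cost)},"
            f"{s.total_annual_cost / 1e9:.1f}"
        )
    write("table3_national.csv", lines)

    lines = ["year_since_onset,attained_age,undiscounted_cost_gbp"]
    onset = report.params.onset_age
    for k, v in enumerate(report.per_year_cost):
        lines.append(f"{k},{onset + k:.0f},{_money(float(v))}")
    write("per_year_costs.csv", lines)

    doc = {
        "version": __version__,
        "seed": report.seed,
        "config_hash": report.config_hash,
        "base_case": {which: report.breakdowns[which].totals() for which in report.breakdowns},
        "shares_pct": shares,
        "mean_time_to_diagnosis_years": mean_time_to_diagnosis(report.traces["mixed"]),
        "annual_cost_per_ttd_year": report.annual_cost_per_ttd_year,
        "annual_cost_first_year": report.annual_cost_first_year,
        "psa": psa.summary() if psa is not None else None,
        "psa_n_draws": psa.n_draws if psa is not None else 0,
        "national": [
            {
                "scenario": s.scenario_name,
                "population": s.population,
                "undiagnosed_fraction": s.undiagnosed_fraction,
                "per_person_annual_cost": s.per_person_annual_cost,
                "total_annual_cost": s.total_annual_cost,
            }
            for s in report.national
        ],
        "per_year_cost": [float(v) for v in report.per_year_cost],
    }
    path = os.path.join(dest, "report.json")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(path)
    return paths
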