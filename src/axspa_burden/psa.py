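"""Probabilistic sensitivity analysis.

Every uncertain input carries a distribution (beta for quantities bounded in
[0, 1], gamma for nonnegative costs and counts, uniform or fixed otherwise).
Each Monte-Carlo draw resamples all of them jointly and independently,
rebuilds the parameter set, reruns the sex-specific cohorts, mixes them, and
accrues costs; category totals are summarized by their empirical mean and
nearest-rank 2.5/97.5 percentiles.  A master seed spawns one independent
substream per draw, so results are bitwise reproducible and independent of
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .cohort import run_cohort_pair
from .costing import CATEGORIES, CostBreakdown, accumulate_costs
from .mortality import LifeTable
from .parameters import DistributionSpec, ParameterSet, ValidationError

__all__ = ["PSAResult", "build_sampler", "run_psa"]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo summary of the cost model."""

    n_draws: int
    seed: int
    draws: np.ndarray  # (n_draws, 4): healthcare, out_of_pocket, productivity, total
    n_rejected: int = 0

    _COLS = CATEGORIES + ("total",)

    def column(self, category: str) -> np.ndarray:
        return self.draws[:, self._COLS.index(category)]

    def mean(self, category: str = "total") -> float:
        return float(self.column(category).mean())

    def percentile(self, category: str, q: float) -> float:
        """Nearest-rank percentile (q in percent) of the sorted draws."""
        x = np.sort(self.column(category))
        rank = max(1, math.ceil(q / 100.0 * len(x)))
        return float(x[rank - 1])

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            c: {
                "mean": self.mean(c),
                "p2.5": self.percentile(c, 2.5),
                "p97.5": self.percentile(c, 97.5),
            }
            for c in self._COLS
        }

    def validate(self) -> "PSAResult":
        if self.draws.shape != (self.n_draws, 4):
            raise ValueError("draw matrix shape must be (n_draws, 4)")
        for c in self._COLS:
            lo, hi = self.percentile(c, 2.5), self.percentile(c, 97.5)
            if not (lo <= hi):
                raise ValueError(f"{c}: p2.5 > p97.5")
            x = self.column(c)
            if not (x.min() <= lo and hi <= x.max()):
                raise ValueError(f"{c}: percentiles outside the draw range")
        return self


def _spread_from_pct(spec: DistributionSpec) -> float:
    """Standard deviation implied by a symmetric +/- pct_range band read as
    an approximate 95% interval."""
    return spec.mean * spec.pct_range / _Z95


def build_sampler(spec: DistributionSpec) -> Callable[[np.random.Generator], float]:
    """Compile a distribution spec into ``f(rng) -> value``.

    beta/gamma preserve the mean exactly; when a 95% CI is present their
    shape is chosen (by root-finding on the concentration) so the central
    2.5/97.5 quantile span matches the CI width; otherwise the +/-pct_range
    band sets the standard deviation.  uniform draws on the CI when present,
    else on mean * (1 +/- pct_range).  fixed is degenerate at the mean.
    """
    errs = spec.validate()
    if errs:
        raise ValueError("; ".join(errs))
    kind, m = spec.kind, spec.mean

    if kind == "fixed":
        return lambda rng: m

    if kind == "uniform":
        if spec.ci_low is not None:
            lo, hi = spec.ci_low, spec.ci_high
        else:
            lo, hi = m * (1 - spec.pct_range), m * (1 + spec.pct_range)
        return lambda rng: float(rng.uniform(lo, hi))

    if kind == "beta":
        if m <= 0.0 or m >= 1.0:
            # degenerate boundary proportion: no spread is possible
            return lambda rng: m
        if spec.ci_low is not None:
            width = spec.ci_high - spec.ci_low
            if width <= 0:
                return lambda rng: m

            def beta_width(kappa: float) -> float:
                a, b = m * kappa, (1 - m) * kappa
                return stats.beta.ppf(0.975, a, b) - stats.beta.ppf(0.025, a, b)

            lo_k, hi_k = 1e-3, 1e9
            if beta_width(lo_k) < width:
                raise ValueError(
                    f"beta CI ({spec.ci_low}, {spec.ci_high}) too wide for mean {m}"
                )
            kappa = optimize.brentq(lambda k: beta_width(k) - width, lo_k, hi_k, xtol=1e-10)
        else:
            sd = min(_spread_from_pct(spec), 0.99 * math.sqrt(m * (1 - m)))
            kappa = m * (1 - m) / sd**2 - 1.0
            if kappa <= 0:
                raise ValueError(f"beta spread infeasible for mean {m}")
        a, b = m * kappa, (1 - m) * kappa
        return lambda rng: float(rng.beta(a, b))

    # gamma
    if m == 0.0:
        return lambda rng: 0.0
    if spec.ci_low is not None:
        width = spec.ci_high - spec.ci_low
        if width <= 0:
            return lambda rng: m

        def gamma_width(k: float) -> float:
            return (stats.gamma.ppf(0.975, k) - stats.gamma.ppf(0.025, k)) * m / k

        lo_k, hi_k = 1e-4, 1e9
        if gamma_width(lo_k) < width:
            raise ValueError(f"gamma CI ({spec.ci_low}, {spec.ci_high}) too wide for mean {m}")
        shape = optimize.brentq(lambda k: gamma_width(k) - width, lo_k, hi_k, xtol=1e-10)
    else:
        sd = _spread_from_pct(spec)
        shape = (m / sd) ** 2
    scale = m / shape
    return lambda rng: float(rng.gamma(shape, scale))


def _evaluate(params: ParameterSet, life_table: LifeTable) -> np.ndarray:
    """One full pipeline evaluation: per-category mixed cumulative costs."""
    traces = run_cohort_pair(params, life_table)
    bd_m = accumulate_costs(traces["male"], params, "male")
    bd_f = accumulate_costs(traces["female"], params, "female")
    mixed = CostBreakdown.mix(bd_m, bd_f, params.pct_male)
    t = mixed.totals()
    return np.array([t[c] for c in CATEGORIES] + [t["total"]])


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_draws: int = 1000,
    seed: int = 0,
    max_rejection_fraction: float = 0.10,
) -> PSAResult:
    """Run the full Monte-Carlo sensitivity analysis.

    Draws violating the parameter-set invariants (e.g. a sampled delay
    shorter than the gold-standard delay) are rejected and redrawn; more
    than ``max_rejection_fraction`` rejections aborts with a diagnostic.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    samplers = {name: build_sampler(spec) for name, spec in params.distribution_specs.items()}
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    rows = np.empty((n_draws, 4))
    n_rejected = 0
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        while True:
            overrides = {name: fn(rng) for name, fn in samplers.items()}
            try:
                drawn = params.updated(overrides)
                break
            except ValidationError:
                n_rejected += 1
                if n_rejected > max_rejection_fraction * n_draws:
                    raise RuntimeError(
                        f"PSA rejected {n_rejected} draws (> "
                        f"{max_rejection_fraction:.0%} of {n_draws}); "
                        "distribution specs are inconsistent with the invariants"
                    )
        rows[i] = _evaluate(drawn, life_table)
    return PSAResult(n_draws=n_draws, seed=seed, draws=rows, n_rejected=n_rejected).validate()
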