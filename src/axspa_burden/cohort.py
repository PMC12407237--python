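"""Three-state Markov cohort engine.

The cohort starts fully undiagnosed at symptom onset and is tracked in
3-month cycles over a lifetime horizon through three states:

    UNDIAGNOSED -> DIAGNOSED -> DEAD          (DEAD absorbing)
    UNDIAGNOSED -> DEAD

Diagnosis never reverses.  The per-cycle diagnosis probability is calibrated
so the mean time to diagnosis matches the target delay (8.5 years by
default); death competes within each cycle, applied before diagnosis
(diagnosis reaches cycle survivors only).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import math

import numpy as np

from .mortality import LifeTable, cycle_death_probability
from .parameters import ParameterSet

__all__ = [
    "MarkovState",
    "CohortTrace",
    "calibrate_diagnosis_probability",
    "transition_matrix",
    "run_cohort",
    "mix_cohorts",
    "mean_time_to_diagnosis",
]

ALIVE_MASS_CUTOFF = 1e-8


class MarkovState(IntEnum):
    UNDIAGNOSED = 0
    DIAGNOSED = 1
    DEAD = 2


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of the cohort.

    ``occupancy[t]`` is the distribution at the *start* of cycle ``t`` (so
    row 0 is (1, 0, 0) at the onset age); ``newly_diagnosed[t]`` is the mass
    entering DIAGNOSED during cycle ``t``.
    """

    cycle_index: np.ndarray  # (n,) int
    attained_age: np.ndarray  # (n,) float, age at cycle start
    occupancy: np.ndarray  # (n, 3) float
    newly_diagnosed: np.ndarray  # (n,) float
    cycle_length: float = 0.25

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_index)

    def validate(self, atol: float = 1e-10) -> "CohortTrace":
        occ = self.occupancy
        if occ.shape != (self.n_cycles, 3):
            raise ValueError("occupancy must be (n_cycles, 3)")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > atol:
            raise ValueError("occupancy rows must sum to 1")
        if not np.allclose(occ[0], [1.0, 0.0, 0.0]):
            raise ValueError("cycle 0 occupancy must be (1, 0, 0)")
        if np.any(np.diff(occ[:, MarkovState.DEAD]) < -atol):
            raise ValueError("DEAD occupancy must be nondecreasing")
        if np.any(np.diff(occ[:, MarkovState.UNDIAGNOSED]) > atol):
            raise ValueError("UNDIAGNOSED occupancy must be nonincreasing")
        return self

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle": self.cycle_index,
                "age": self.attained_age,
                "undiagnosed": self.occupancy[:, 0],
                "diagnosed": self.occupancy[:, 1],
                "dead": self.occupancy[:, 2],
                "newly_diagnosed": self.newly_diagnosed,
            }
        )


def calibrate_diagnosis_probability(
    mean_ttd: float, cycle_length: float, mode: str = "continuous"
) -> float:
    """Per-cycle diagnosis probability giving the target mean delay.

    ``continuous`` discretizes an exponential waiting time with mean
    ``mean_ttd``: ``1 - exp(-cycle_length / mean_ttd)``.  ``geometric``
    matches the mean of the discrete geometric in cycle units:
    ``cycle_length / mean_ttd``.  Both must land strictly inside (0, 1) for a
    delay model.
    """
    if mean_ttd <= 0:
        raise ValueError(f"mean_ttd must be > 0, got {mean_ttd}")
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be > 0, got {cycle_length}")
    if mode == "continuous":
        return -math.expm1(-cycle_length / mean_ttd)
    if mode == "geometric":
        p = cycle_length / mean_ttd
        if p >= 1.0:
            raise ValueError(
                f"geometric calibration needs cycle_length < mean_ttd "
                f"(got p = {p}); probability must be < 1 for a delay model"
            )
        return p
    raise ValueError(f"unknown calibration mode {mode!r}")


def transition_matrix(p_diag: float, p_death: float) -> np.ndarray:
    """Row-stochastic 3x3 one-cycle transition matrix.

    Death takes precedence within the cycle; diagnosis applies to survivors:
    the UNDIAGNOSED row is ((1-p_death)(1-p_diag), (1-p_death) p_diag,
    p_death).
    """
    for name, p in (("p_diag", p_diag), ("p_death", p_death)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0,1], got {p}")
    surv = 1.0 - p_death
    return np.array(
        [
            [surv * (1.0 - p_diag), surv * p_diag, p_death],
            [0.0, surv, p_death],
            [0.0, 0.0, 1.0],
        ]
    )


def run_cohort(
    params: ParameterSet,
    life_table: LifeTable,
    sex: str,
    calibration_mode: str = "continuous",
    death_first: bool = True,
    min_cycles: int | None = None,
) -> CohortTrace:
    """Propagate the cohort from onset age to the life-table maximum.

    The cohort starts at ``(1, 0, 0)`` at ``params.onset_age`` and is
    advanced cycle by cycle; it stops once the attained age passes the
    life-table maximum or alive mass falls below ``ALIVE_MASS_CUTOFF``.
    ``death_first`` selects the within-cycle competing-risk ordering
    (death before diagnosis by default).  ``min_cycles`` keeps the trace
    running past the alive-mass cutoff (never past the age bound) so that
    two traces can be put on a common cycle grid for mixing.
    """
    smr = params.smr_male if sex == "male" else params.smr_female
    c = params.cycle_length
    p_diag = calibrate_diagnosis_probability(params.mean_time_to_diagnosis, c, calibration_mode)
    if params.onset_age < life_table.min_age or params.onset_age > life_table.max_age:
        raise LookupError(f"onset age {params.onset_age} outside life table")

    occ = np.array([1.0, 0.0, 0.0])
    rows_occ = [occ.copy()]
    ages = [params.onset_age]
    newly = [0.0]
    t = 0
    while True:
        age = params.onset_age + t * c
        p_death = cycle_death_probability(life_table, age, sex, smr, c)
        if death_first:
            nd = occ[0] * (1.0 - p_death) * p_diag
            m = transition_matrix(p_diag, p_death)
        else:
            # diagnosis before death: all undiagnosed face p_diag first
            nd = occ[0] * p_diag
            surv = 1.0 - p_death
            m = np.array(
                [
                    [(1.0 - p_diag) * surv, p_diag * surv, p_death],
                    [0.0, surv, p_death],
                    [0.0, 0.0, 1.0],
                ]
            )
            nd *= surv  # only survivors of the cycle count as diagnosed
        occ = occ @ m
        t += 1
        next_age = params.onset_age + t * c
        rows_occ.append(occ.copy())
        ages.append(next_age)
        newly.append(float(nd))
        alive = occ[0] + occ[1]
        if math.floor(next_age) > life_table.max_age:
            break
        if alive < ALIVE_MASS_CUTOFF and (min_cycles is None or len(rows_occ) >= min_cycles):
            break

    trace = CohortTrace(
        cycle_index=np.arange(len(rows_occ)),
        attained_age=np.array(ages),
        occupancy=np.vstack(rows_occ),
        newly_diagnosed=np.array(newly),
        cycle_length=c,
    )
    return trace.validate()


def run_cohort_pair(
    params: ParameterSet, life_table: LifeTable, calibration_mode: str = "continuous"
) -> dict[str, CohortTrace]:
    """Run both sex-specific cohorts on a guaranteed-common cycle grid.

    The age horizon is identical for both sexes, but the alive-mass cutoff
    can fire a cycle or two earlier for the higher-mortality sex; the
    shorter trace is extended to the longer grid (the extra occupancy mass
    involved is below ``ALIVE_MASS_CUTOFF``).
    """
    traces = {
        sex: run_cohort(params, life_table, sex, calibration_mode) for sex in ("male", "female")
    }
    n = max(t.n_cycles for t in traces.values())
    for sex, trace in traces.items():
        if trace.n_cycles < n:
            traces[sex] = run_cohort(params, life_table, sex, calibration_mode, min_cycles=n)
    return traces


def mix_cohorts(result_male: CohortTrace, result_female: CohortTrace, pct_male: float) -> CohortTrace:
    """Cycle-wise convex combination of two sex-specific traces."""
    if not (0.0 <= pct_male <= 1.0):
        raise ValueError(f"pct_male must lie in [0,1], got {pct_male}")
    if result_male.n_cycles != result_female.n_cycles or not np.allclose(
        result_male.attained_age, result_female.attained_age
    ):
        raise ValueError("traces are on different cycle grids and cannot be mixed")
    w = pct_male
    return CohortTrace(
        cycle_index=result_male.cycle_index.copy(),
        attained_age=result_male.attained_age.copy(),
        occupancy=w * result_male.occupancy + (1.0 - w) * result_female.occupancy,
        newly_diagnosed=w * result_male.newly_diagnosed + (1.0 - w) * result_female.newly_diagnosed,
        cycle_length=result_male.cycle_length,
    )


def mean_time_to_diagnosis(trace: CohortTrace) -> float:
    """Mean delay implied by the trace's diagnosis-time distribution.

    Diagnoses during cycle ``t`` are timed at the cycle midpoint
    ``(t + 0.5) * cycle_length``; the mean is taken over those eventually
    diagnosed (deaths are censored out).
    """
    nd = trace.newly_diagnosed
    total = nd.sum()
    if total <= 0:
        raise ValueError("no diagnosis mass in trace")
    # newly_diagnosed[t] holds mass diagnosed during cycle t-1 (recorded at
    # the following cycle start), so the midpoint is (t - 0.5) * c.
    times = (trace.cycle_index - 0.5) * trace.cycle_length
    return float((nd * times).sum() / total)
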