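"""Background mortality: life tables and SMR-adjusted per-cycle death risk.

The cohort's death risk comes from an annual life table (age, sex, qx) with
the disease's excess mortality applied as a standardized mortality ratio on
the hazard scale: the annual probability is converted to a hazard
``h = -ln(1 - qx)``, multiplied by the SMR, and converted back over the cycle
length.  Working on the hazard scale keeps the result a probability for any
positive SMR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "read_life_table", "cycle_death_probability", "SEXES"]

SEXES = ("male", "female")


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx by integer age and sex.

    Ages run contiguously from ``min_age`` to ``max_age`` (>= 100), one row
    per (age, sex); the table is closed with qx = 1 at the maximum age.
    """

    min_age: int
    max_age: int
    qx: dict[str, np.ndarray]  # sex -> array indexed by (age - min_age)

    def validate(self) -> "LifeTable":
        errs: list[str] = []
        if self.max_age < 100:
            errs.append(f"max_age must be >= 100, got {self.max_age}")
        if set(self.qx) != set(SEXES):
            errs.append(f"life table must cover sexes {SEXES}, got {sorted(self.qx)}")
        n = self.max_age - self.min_age + 1
        for sex, q in self.qx.items():
            if len(q) != n:
                errs.append(f"{sex}: expected {n} contiguous ages, got {len(q)} rows")
                continue
            if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
                errs.append(f"{sex}: qx values must lie in [0,1]")
            elif q[-1] != 1.0:
                errs.append(f"{sex}: qx at max age must be 1 (closing the table)")
        if errs:
            raise ValueError("; ".join(errs))
        return self

    def annual_q(self, age: float, sex: str) -> float:
        """Annual death probability at integer attained age (floor)."""
        if sex not in self.qx:
            raise KeyError(f"unknown sex {sex!r}")
        idx = int(math.floor(age)) - self.min_age
        if idx < 0 or idx >= len(self.qx[sex]):
            raise LookupError(f"age {age} outside life table [{self.min_age}, {self.max_age}]")
        return float(self.qx[sex][idx])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (age, sex, float(self.qx[sex][age - self.min_age]))
            for sex in SEXES
            for age in range(self.min_age, self.max_age + 1)
        ]
        return pd.DataFrame(rows, columns=["age", "sex", "qx"])

    def to_csv(self, path: Any) -> None:
        self.to_frame().to_csv(path, index=False)


def read_life_table(tabular_source: Any) -> LifeTable:
    """Read and validate an ``age,sex,qx`` CSV (header required).

    Raises ``ValueError`` on age gaps, duplicate (age, sex) rows, or qx
    outside [0, 1].
    """
    df = pd.read_csv(tabular_source)
    required = {"age", "sex", "qx"}
    if not required.issubset(df.columns):
        raise ValueError(f"life table must have columns {sorted(required)}")
    if df.duplicated(subset=["age", "sex"]).any():
        dup = df[df.duplicated(subset=["age", "sex"])].iloc[0]
        raise ValueError(f"duplicate life-table row for (age={dup['age']}, sex={dup['sex']})")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex code(s) {sorted(bad_sex)}; use male/female")
    min_age = int(df["age"].min())
    max_age = int(df["age"].max())
    qx: dict[str, np.ndarray] = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("age")
        ages = sub["age"].to_numpy()
        expected = np.arange(min_age, max_age + 1)
        if len(ages) != len(expected) or np.any(ages != expected):
            missing = sorted(set(expected) - set(ages))
            raise ValueError(f"{sex}: life-table ages not contiguous (missing {missing[:5]})")
        qx[sex] = sub["qx"].to_numpy(dtype=float)
    return LifeTable(min_age=min_age, max_age=max_age, qx=qx).validate()


def cycle_death_probability(
    life_table: LifeTable, age: float, sex: str, smr: float, cycle_length: float
) -> float:
    """SMR-adjusted death probability over one cycle at the given age.

    ``1 - exp(-smr * h * cycle_length)`` with ``h = -ln(1 - qx)``; a closed
    table row (qx = 1) returns 1 regardless of the SMR.
    """
    if smr <= 0:
        raise ValueError(f"smr must be > 0, got {smr}")
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be > 0, got {cycle_length}")
    q = life_table.annual_q(age, sex)
    if q >= 1.0:
        return 1.0
    hazard = -math.log1p(-q)
    return -math.expm1(-smr * hazard * cycle_length)
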