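"""General-population background mortality.

A Gompertz–Makeham law per sex stands in for official national life tables so
the package runs with zero downloads: annual hazard mu(x) = lam + a*exp(b*x),
q(x) = 1 - exp(-mu(x)).  The default coefficients approximate contemporary UK
rates (male life expectancy ~27 y and female ~30 y from age 56).  Users who
want official rates can load a literal CSV table (columns ``age,sex,qx``).

Incremental cost-effectiveness results are insensitive to modest background-
mortality error; absolute life-year totals are approximate by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

AGE_MIN, AGE_MAX = 18, 110

#: default Gompertz–Makeham coefficients (lam, a, b) per sex
DEFAULT_LAW = {
    "M": (5.0e-4, 3.4e-5, 0.095),
    "F": (5.0e-4, 1.2e-5, 0.101),
}


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age and sex."""

    q_male: tuple[float, ...]
    q_female: tuple[float, ...]
    age_min: int = AGE_MIN

    @property
    def age_max(self) -> int:
        return self.age_min + len(self.q_male) - 1

    def q_annual(self, age: float, sex: str) -> float:
        """q for the integer age containing ``age`` (truncation convention)."""
        i = int(math.floor(age)) - self.age_min
        if i < 0 or i >= len(self.q_male):
            raise ValueError(
                f"age {age} outside life-table range "
                f"[{self.age_min}, {self.age_max}]")
        return (self.q_male if sex == "M" else self.q_female)[i]


def make_life_table(law: dict[str, tuple[float, float, float]] | None = None,
                    rows: list[tuple[int, str, float]] | None = None) -> LifeTable:
    """Build a life table from a Gompertz–Makeham law or a literal row list.

    ``law`` maps sex -> (lam, a, b); ``rows`` is a list of (age, sex, qx)
    covering ages 18..110 for both sexes and takes precedence when given.
    """
    if rows is not None:
        by: dict[str, dict[int, float]] = {"M": {}, "F": {}}
        for age, sex, qx in rows:
            if sex not in by:
                raise ValueError(f"sex must be M or F, got {sex!r}")
            if not 0.0 <= qx <= 1.0:
                raise ValueError(f"qx out of [0,1] at age {age}: {qx}")
            by[sex][int(age)] = float(qx)
        ages = sorted(by["M"])
        if ages != sorted(by["F"]) or ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError("life-table rows must cover a contiguous age range "
                             "for both sexes")
        return LifeTable(tuple(by["M"][a] for a in ages),
                         tuple(by["F"][a] for a in ages), age_min=ages[0])

    law = dict(DEFAULT_LAW if law is None else law)
    cols = {}
    for sex in ("M", "F"):
        lam, a, b = law[sex]
        if lam < 0 or a < 0:
            raise ValueError(f"negative mortality coefficients for sex {sex}")
        cols[sex] = tuple(
            min(1.0, 1.0 - math.exp(-(lam + a * math.exp(b * age))))
            for age in range(AGE_MIN, AGE_MAX + 1))
    return LifeTable(cols["M"], cols["F"])


def read_life_table_csv(path: str | Path) -> LifeTable:
    """Read a literal life table from CSV with header ``age,sex,qx``."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        if header[:3] != ["age", "sex", "qx"]:
            raise ValueError(f"{path}: expected header 'age,sex,qx'")
        for line in fh:
            if not line.strip():
                continue
            age, sex, qx = line.strip().split(",")[:3]
            rows.append((int(age), sex.strip().upper(), float(qx)))
    return make_life_table(rows=rows)


def write_life_table_csv(table: LifeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("age,sex,qx\n")
        for i, (qm, qf) in enumerate(zip(table.q_male, table.q_female)):
            age = table.age_min + i
            fh.write(f"{age},M,{qm:.10g}\n{age},F,{qf:.10g}\n")


def monthly_background_mortality(table: LifeTable, age: float,
                                 prop_male: float) -> float:
    """Sex-mixed monthly death probability at a given age.

    The annual probabilities are mixed by the cohort sex split and converted
    to a monthly probability via p = 1 - (1-q)^(1/12).
    """
    if not 0.0 <= prop_male <= 1.0:
        raise ValueError("prop_male must be in [0,1]")
    q = prop_male * table.q_annual(age, "M") + (1 - prop_male) * table.q_annual(age, "F")
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)
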