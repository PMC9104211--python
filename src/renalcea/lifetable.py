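"""Age-specific background mortality.

The cohort model needs, at every monthly cycle, the probability that a
patient of the attained age dies of causes unrelated to the renal tumor.
This module loads a period life table (columns ``age``, ``qx`` — the annual
probability of death at integer age x) or synthesizes a parametric
Gompertz stand-in, and converts annual probabilities to monthly ones under
a constant-hazard-within-year assumption:

    q_month = 1 - (1 - q_year)^(1/12)

The attained age is the integer floor of current age; the table is capped
at ``max_age`` where the death probability is forced to 1, which keeps all
model horizons finite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "load_life_table",
    "synthesize_life_table",
    "monthly_background_death_prob",
    "life_expectancy",
    "fit_gompertz_scale",
]

DEFAULT_MAX_AGE = 100


class LifeTableError(ValueError):
    """Raised on a malformed life table source."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities q(x) for contiguous integer ages.

    ``ages[-1]`` is the cap age at which q = 1 (everyone still alive dies
    within that year).
    """

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx) or not self.ages:
            raise LifeTableError("ages and qx must be non-empty and of equal length")
        for i, (a, q) in enumerate(zip(self.ages, self.qx)):
            if i > 0 and a != self.ages[i - 1] + 1:
                if a <= self.ages[i - 1]:
                    raise LifeTableError(f"ages must be strictly increasing (row {i}, age {a})")
                raise LifeTableError(f"gap at age {self.ages[i - 1] + 1}")
            if not 0.0 <= q <= 1.0:
                raise LifeTableError(f"annual death probability out of [0,1] at age {a}: {q}")
        if self.qx[-1] != 1.0:
            raise LifeTableError(f"death probability at the cap age {self.ages[-1]} must be 1")

    @property
    def min_age(self) -> int:
        return self.ages[0]

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def annual_death_prob(self, age_years: int) -> float:
        """q(x) for the attained integer age; 1 at or beyond the cap age."""
        if age_years < self.min_age:
            raise LifeTableError(f"age {age_years} below table start {self.min_age}")
        if age_years >= self.max_age:
            return 1.0
        return self.qx[age_years - self.min_age]


def load_life_table(source, max_age: int = DEFAULT_MAX_AGE) -> LifeTable:
    """Load a two-column (age, qx) CSV; header row optional.

    Rows beyond ``max_age`` are clipped and the cap entry is forced to
    q = 1.  Non-contiguous ages, out-of-range probabilities and unreadable
    rows raise :class:`LifeTableError` naming the offending row.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    try:
        first = text.lstrip().splitlines()[0]
    except IndexError:
        raise LifeTableError("empty life-table source") from None
    header = 0 if any(c.isalpha() for c in first) else None
    try:
        df = pd.read_csv(io.StringIO(text), header=header)
    except Exception as e:
        raise LifeTableError(f"cannot parse life-table CSV: {e}") from e
    if df.shape[1] < 2:
        raise LifeTableError("life table needs two columns: age, qx")
    df = df.iloc[:, :2]
    df.columns = ["age", "qx"]
    try:
        ages = df["age"].astype(int).to_list()
        qx = df["qx"].astype(float).to_list()
    except (TypeError, ValueError) as e:
        raise LifeTableError(f"non-numeric life-table entry: {e}") from e

    keep = [(a, q) for a, q in zip(ages, qx) if a <= max_age]
    if not keep:
        raise LifeTableError(f"no rows at or below max_age {max_age}")
    ages = [a for a, _ in keep]
    qx = [q for _, q in keep]
    if ages[-1] == max_age:
        qx[-1] = 1.0
    else:
        # extend the cap entry so the absorbing age is explicit
        for a in range(ages[-1] + 1, max_age + 1):
            ages.append(a)
            qx.append(qx[-1] if a < max_age else 1.0)
    return LifeTable(tuple(ages), tuple(qx))


def synthesize_life_table(
    gompertz_a: float,
    gompertz_b: float,
    min_age: int = 0,
    max_age: int = DEFAULT_MAX_AGE,
) -> LifeTable:
    """Parametric life table with Gompertz annual death probabilities.

    q(x) = 1 - exp(-a * e^(b*x)), capped at 1, with the entry at ``max_age``
    forced to 1.  ``a`` scales overall mortality; ``b`` (per year of age) is
    the log-linear slope of the hazard, around 0.085-0.10 for adult human
    mortality.
    """
    if gompertz_a <= 0 or gompertz_b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    if min_age >= max_age:
        raise ValueError("min_age must be below max_age")
    ages = np.arange(min_age, max_age + 1)
    qx = 1.0 - np.exp(-gompertz_a * np.exp(gompertz_b * ages))
    qx = np.clip(qx, 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(tuple(int(a) for a in ages), tuple(float(q) for q in qx))


def monthly_background_death_prob(lt: LifeTable, age_months: int) -> float:
    """Monthly death probability at the attained integer age.

    Constant hazard within each year of age: composing the monthly
    probability twelve times recovers the annual one.  Returns 1 at or
    beyond the cap age.
    """
    age_years = age_months // 12
    q = lt.annual_death_prob(age_years)
    if q >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q) ** (1.0 / 12.0)


def life_expectancy(lt: LifeTable, age_years: int) -> float:
    """Residual life expectancy at an integer age, in years.

    Curtate expectation (sum of annual survival probabilities) plus one half
    year for the part-year lived in the year of death.
    """
    q = np.array([lt.annual_death_prob(a) for a in range(age_years, lt.max_age + 1)])
    survival = np.cumprod(1.0 - q)
    return float(survival.sum()) + 0.5


def fit_gompertz_scale(
    target_life_expectancy: float,
    at_age: int,
    gompertz_b: float = 0.09,
    max_age: int = DEFAULT_MAX_AGE,
) -> float:
    """Find the Gompertz scale ``a`` whose table has the requested residual
    life expectancy at ``at_age`` (bisection; slope ``b`` held fixed)."""
    lo, hi = 1e-12, 1.0

    def le(a: float) -> float:
        return life_expectancy(synthesize_life_table(a, gompertz_b, max_age=max_age), at_age)

    if not (le(hi) <= target_life_expectancy <= le(lo)):
        raise ValueError("target life expectancy not attainable for this slope")
    for _ in range(200):
        mid = (lo * hi) ** 0.5  # geometric bisection: a spans orders of magnitude
        if le(mid) > target_life_expectancy:
            lo = mid
        else:
            hi = mid
    return (lo * hi) ** 0.5
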