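"""Annual background mortality by age.

The lifetime Markov horizon needs an all-cause mortality schedule.  Users can
supply a national life table as a two-column CSV (``age,qx``); for a
self-contained run a Gompertz-Makeham schedule is generated instead, with
default parameters chosen to give a life expectancy at birth of about 82
years (Italy-like).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LifeTable:
    """Annual death probabilities q(age) over a contiguous age range.

    The final age is absorbing: q(max_age) = 1.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.q.shape or self.ages.size == 0:
            raise ValueError("ages and q must be matching non-empty 1-d arrays")
        if not np.array_equal(self.ages, np.arange(self.ages[0], self.ages[-1] + 1)):
            raise ValueError("ages must form a contiguous integer range")
        if np.any(self.q <= 0) or np.any(self.q > 1):
            raise ValueError("all death probabilities must lie in (0, 1]")
        if self.q[-1] != 1.0:
            raise ValueError("q at the final age must be 1 (absorbing horizon)")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: float) -> float:
        """Annual death probability at a (possibly fractional) age; the age is
        floored to whole years, matching annual transition probabilities."""
        if age < self.min_age or age > self.max_age:
            raise ValueError(
                f"age {age} outside life-table range [{self.min_age}, {self.max_age}]"
            )
        return float(self.q[int(np.floor(age)) - self.min_age])

    def survival_curve(self, from_age: float) -> np.ndarray:
        """Cumulative survival from `from_age` over successive whole years:
        element k is the probability of surviving k further annual cycles."""
        idx = int(np.floor(from_age)) - self.min_age
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q[idx:])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.q})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValueError("life-table CSV must have columns 'age' and 'qx'")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())


def generate_gompertz_makeham(
    makeham_a: float = 5e-4,
    gompertz_b: float = 2e-5,
    gompertz_c: float = 0.095,
    min_age: int = 0,
    max_age: int = 110,
) -> LifeTable:
    """Synthetic mortality: hazard h(age) = a + b*exp(c*age), converted to an
    annual death probability q = 1 - exp(-h), with q forced to 1 at max_age.

    Defaults give a life expectancy at birth of ~81.8 years.
    """
    if makeham_a < 0 or gompertz_b <= 0 or gompertz_c <= 0:
        raise ValueError("require a >= 0, b > 0, c > 0")
    if min_age >= max_age:
        raise ValueError("min_age must be below max_age")
    ages = np.arange(min_age, max_age + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages.astype(float))
    q = 1.0 - np.exp(-hazard)
    q = np.clip(q, np.finfo(float).tiny, 1.0)
    if np.any(q[ages < 100] >= 1.0):
        warnings.warn(
            "Gompertz-Makeham parameters produce certain death before age 100",
            stacklevel=2,
        )
    q[-1] = 1.0
    return LifeTable(ages, q)
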