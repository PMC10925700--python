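"""Age-indexed annual non-CVD death probabilities.

The cohort model consumes a :class:`LifeTable` mapping integer age to the
annual probability of death from non-cardiovascular causes.  Users may load a
real national life table from a two-column delimited file; the synthetic
module provides a calibrated Gompertz stand-in when none is available.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LifeTable"]


@dataclass(frozen=True)
class LifeTable:
    ages: np.ndarray    # contiguous, strictly increasing integer years
    q: np.ndarray       # annual non-CVD death probability per age

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != q.shape:
            raise ValueError("life table needs matching 1-d age and q columns")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous and strictly increasing")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("death probabilities must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ValueError(
                f"q at the final age ({ages[-1]}) must be 1 (forced absorption)"
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: int) -> float:
        if not self.min_age <= age <= self.max_age:
            raise ValueError(
                f"age {age} outside life table range [{self.min_age}, {self.max_age}]"
            )
        return float(self.q[int(age) - self.min_age])

    def scaled(self, factor: float) -> "LifeTable":
        """Rescale every q by ``factor`` (capped at 1; final age stays 1).

        Used by sensitivity analyses that vary the representative non-CVD
        mortality level.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        q = np.minimum(1.0, self.q * factor)
        q[-1] = 1.0
        return LifeTable(self.ages.copy(), q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q_noncvd": self.q})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "age" not in cols or not any(c.startswith("q") for c in cols):
            raise ValueError("life table file needs 'age' and 'q*' header columns")
        qcol = next(cols[c] for c in cols if c.startswith("q"))
        return cls(df[cols["age"]].to_numpy(), df[qcol].to_numpy())
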