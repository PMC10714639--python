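"""Age-indexed baseline mortality and disease-specific risk adjustment.

The cohort's background mortality comes from an age-indexed life table of
annual death probabilities ``q(age)`` for the general population.  A Gompertz
stand-in calibrated to plausible East-Asian adult mortality is the default
(the national table the cost-effectiveness literature would use is not
bundled); any two-column CSV life table can replace it.

Two published relative risks adjust the baseline: diabetes vs. the general
population (1.49) for every living state, multiplied by a further 11.54 for
the severe-visual-loss state.  Risks act multiplicatively on the annual
probability and the product is capped at 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = ["LifeTable", "gompertz_life_table", "load_life_table", "state_death_prob"]

GOMPERTZ_A = 2.8e-5  #: baseline hazard at age 0
GOMPERTZ_B = 0.09  #: log-hazard slope per year of age


class LifeTable:
    """Annual general-population death probability by integer age."""

    def __init__(self, ages: np.ndarray, q: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        q = np.asarray(q, dtype=float)
        if ages.shape != q.shape or ages.ndim != 1:
            raise ValueError("ages and q must be equal-length 1-d arrays")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("life-table q values must lie in [0, 1]")
        order = np.argsort(ages)
        self.ages = ages[order]
        self._q = q[order]
        self._lookup = dict(zip(self.ages.tolist(), self._q.tolist()))

    def q(self, age: int) -> float:
        """Annual probability of death at the given integer age."""
        try:
            return self._lookup[int(age)]
        except KeyError:
            raise ValueError(
                f"age {age} outside life table range "
                f"[{self.ages.min()}, {self.ages.max()}]"
            ) from None

    def covers(self, lo: int, hi: int) -> bool:
        return set(range(int(lo), int(hi) + 1)) <= set(self._lookup)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self._q})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __repr__(self):
        return f"LifeTable(ages {self.ages.min()}-{self.ages.max()})"


def gompertz_life_table(
    a: float = GOMPERTZ_A, b: float = GOMPERTZ_B, max_age: int = 110
) -> LifeTable:
    """Gompertz life table: ``q(x) = 1 - exp(-a * e^(b*x))``.

    With the defaults, q(50) is about 0.0025 and rises to about 0.20 by age
    100 — a plausible general-population schedule for the simulated ages.
    ``a`` may be 0 (the zero-hazard limit); both parameters must be >= 0.
    """
    if a < 0 or b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    ages = np.arange(0, max_age + 1)
    q = 1.0 - np.exp(-a * np.exp(b * ages))
    return LifeTable(ages, q)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column (age, q) CSV life table; a header row is required."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "age" not in cols or "q" not in cols:
        raise ValueError("life-table file must have 'age' and 'q' columns")
    return LifeTable(df[cols["age"]].to_numpy(), df[cols["q"]].to_numpy())


def state_death_prob(q_gen: float, params: ParameterSet, is_svl: bool = False) -> float:
    """Annual death probability for a cohort member, given baseline ``q_gen``.

    Non-SVL states: ``min(1, q_gen * rr_death_diabetes)``.  SVL states apply
    the SVL relative risk on top of the diabetes-adjusted probability:
    ``min(1, q_gen * rr_death_diabetes * rr_death_svl)``.
    """
    if not 0.0 <= q_gen <= 1.0:
        raise ValueError(f"q_gen {q_gen} outside [0, 1]")
    rr = params.rr_death_diabetes * (params.rr_death_svl if is_svl else 1.0)
    return min(1.0, q_gen * rr)
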