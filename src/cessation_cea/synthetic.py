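"""Synthetic life tables and cause-of-death splits.

Generates sex-specific life tables (annual probability of death by integer
age) with a Gompertz hazard, and a cancer/non-cancer cause-of-death split
whose cancer fraction declines linearly toward very old age.  These emulate
the statistical structure of national life tables and vital-statistics
cause-of-death data so the downstream mortality adjustment and cohort model
are fully testable with no external inputs.

The table spans ages 65..110 and is closed at the terminal age with q=1, so
a cohort is guaranteed to be absorbed even if a run horizon is extended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MIN",
    "AGE_MAX",
    "LifeTable",
    "CauseSplit",
    "make_life_table",
    "make_cause_split",
    "default_life_table",
    "default_cause_split",
    "life_expectancy",
]

AGE_MIN = 65
AGE_MAX = 110

#: Default Gompertz parameters (baseline hazard a, slope b per year) and
#: linear cause-split endpoints.  These are calibration conveniences giving
#: human-plausible old-age survival, not estimates for any real population;
#: the female table uses a lower baseline hazard than the male one.
DEFAULT_GOMPERTZ = {"male": (1.89e-6, 0.12), "female": (1.57e-6, 0.12)}
DEFAULT_CAUSE_SPLIT = {"male": (0.60, 0.10), "female": (0.64, 0.10)}

_SEXES = ("male", "female")


def _check_sex(sex: str) -> str:
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
    return sex


@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death q(age) for one sex, ages 65..110."""

    sex: str
    q: Mapping[int, float]

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        ages = sorted(self.q)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError("life table ages must be consecutive integers")
        for age, p in self.q.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"q({age})={p} outside [0, 1]")

    @property
    def ages(self) -> np.ndarray:
        return np.array(sorted(self.q), dtype=int)

    def q_array(self) -> np.ndarray:
        return np.array([self.q[a] for a in sorted(self.q)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q_array()})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sex: str) -> "LifeTable":
        """Read a life table reshaped to columns ``age,q``."""
        df = pd.read_csv(path)
        return cls(sex=sex, q={int(a): float(p) for a, p in zip(df["age"], df["q"])})


@dataclass(frozen=True)
class CauseSplit:
    """Fraction of deaths at each age attributable to cancer, for one sex."""

    sex: str
    f_cancer: Mapping[int, float]

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        for age, f in self.f_cancer.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"f_cancer({age})={f} outside [0, 1]")

    @property
    def ages(self) -> np.ndarray:
        return np.array(sorted(self.f_cancer), dtype=int)

    def f_array(self) -> np.ndarray:
        return np.array([self.f_cancer[a] for a in sorted(self.f_cancer)], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "f_cancer": self.f_array()})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sex: str) -> "CauseSplit":
        df = pd.read_csv(path)
        return cls(sex=sex,
                   f_cancer={int(a): float(f) for a, f in zip(df["age"], df["f_cancer"])})


def make_life_table(
    sex: str,
    a: float | None = None,
    b: float | None = None,
    seed: int | None = None,
    noise_sigma: float = 0.03,
) -> LifeTable:
    """Gompertz life table: q(age) = 1 - exp(-a * exp(b * age)).

    Parameters
    ----------
    sex
        "male" or "female"; selects the packaged defaults when `a`/`b`
        are not given.
    a
        Baseline hazard at age 0 (must be > 0).
    b
        Gompertz slope per year of age, in [0, 0.3).  ``b=0`` degenerates to
        a constant annual death probability ``1 - exp(-a)``.
    seed
        If given, applies small multiplicative lognormal noise to the hazard
        (deterministic per seed) and re-enforces monotonicity in age by
        cumulative max, mimicking sampling wiggle in empirical tables.

    The terminal age 110 is always closed with q=1.
    """
    _check_sex(sex)
    if a is None or b is None:
        da, db = DEFAULT_GOMPERTZ[sex]
        a = da if a is None else a
        b = db if b is None else b
    if a <= 0:
        raise ValueError(f"baseline hazard a must be > 0, got {a}")
    if not (0.0 <= b < 0.3):
        raise ValueError(f"Gompertz slope b must be in [0, 0.3), got {b}")

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    hazard = a * np.exp(b * ages)
    if seed is not None:
        rng = np.random.default_rng(seed)
        hazard = hazard * np.exp(rng.normal(0.0, noise_sigma, size=hazard.shape))
    q = 1.0 - np.exp(-hazard)
    if seed is not None:
        q = np.maximum.accumulate(q)
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0  # closure at the terminal age
    return LifeTable(sex=sex, q={int(age): float(p) for age, p in zip(ages, q)})


def make_cause_split(sex: str, f65: float | None = None,
                     f_old: float | None = None) -> CauseSplit:
    """Linear-in-age cancer fraction of deaths from f(65)=f65 to f(110)=f_old.

    The declining default shape reflects that at very old ages a shrinking
    share of deaths is attributable to cancer.
    """
    _check_sex(sex)
    if f65 is None or f_old is None:
        d65, dold = DEFAULT_CAUSE_SPLIT[sex]
        f65 = d65 if f65 is None else f65
        f_old = dold if f_old is None else f_old
    for name, val in (("f65", f65), ("f_old", f_old)):
        if not (0.0 <= val <= 1.0):
            raise ValueError(f"{name}={val} outside [0, 1]")
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    frac = f65 + (f_old - f65) * (ages - AGE_MIN) / (AGE_MAX - AGE_MIN)
    return CauseSplit(sex=sex, f_cancer={int(age): float(f) for age, f in zip(ages, frac)})


def default_life_table(sex: str) -> LifeTable:
    """The packaged default life table for a sex (no noise)."""
    return make_life_table(sex)


def default_cause_split(sex: str) -> CauseSplit:
    """The packaged default cause-of-death split for a sex."""
    return make_cause_split(sex)


def life_expectancy(lt: LifeTable, from_age: int | None = None) -> float:
    """Undiscounted remaining life expectancy at `from_age` (curtate).

    Sums survival probabilities over whole years: e(x) = sum_{t>=1} S(t),
    where S is the product of (1-q) from `from_age` up.  Used as a sanity
    band on synthetic tables, not as a demographic estimator.
    """
    ages = sorted(lt.q)
    start = ages[0] if from_age is None else from_age
    surv = 1.0
    total = 0.0
    for age in ages:
        if age < start:
            continue
        surv *= 1.0 - lt.q[age]
        total += surv
    return total
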