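"""Smoking-status-adjusted mortality for cancer patients.

Derives annual death probabilities by age, sex and smoking status in six
steps from a general-population life table and a cause-of-death split:

1. take the age-specific annual probability of death q(age);
2. take the age-specific fraction of deaths attributable to cancer;
3. split the total hazard m = -ln(1-q) into cancer and non-cancer
   components, m_cancer = m * f_cancer and m_noncancer = m * (1-f_cancer);
4. scale the cancer component by an excess multiplier (>= 1) to lift it
   from the general-population level to a cancer-patient level;
5. apply the mortality hazard ratio for each smoking status on the hazard
   scale — by default to the non-cancer component only, treating the
   cancer hazard as common to both statuses; and
6. convert back to an annual probability,
   p = 1 - exp(-(HR * m_noncancer + multiplier * m_cancer)).

Applying hazard ratios on the hazard scale (not by multiplying
probabilities) keeps every p <= 1 and matches standard HR semantics.
Restricting the HR to the non-cancer component (``hr_on="noncancer"``)
keeps the smoking-status survival gap modest even in a heavily
cancer-loaded hazard; ``hr_on="total"`` instead multiplies the combined
cancer-patient hazard.  The general-population table serves as the
never-smoker baseline; mortality is age-dependent but not
time-since-diagnosis-dependent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import MortalityParams
from .synthetic import CauseSplit, LifeTable

__all__ = [
    "STATUSES",
    "DEFAULT_EXCESS_CANCER_MULTIPLIER",
    "AdjustedMortality",
    "split_mortality",
    "derive_adjusted_mortality",
]

logger = logging.getLogger(__name__)

STATUSES = ("current", "former")

#: Default scaling of the cancer hazard component (step 4).  Chosen so that
#: baseline survival from the packaged synthetic life tables is
#: cancer-patient-like (roughly 11-13 discounted life-years at age 65)
#: rather than general-population-like.
DEFAULT_EXCESS_CANCER_MULTIPLIER = 2.0

#: Hazard cap used where q=1 would give an infinite hazard.
_MAX_HAZARD = 50.0


@dataclass(frozen=True)
class AdjustedMortality:
    """Annual death probability by (age, smoking status) for one sex."""

    sex: str
    p_death: Mapping[tuple[int, str], float]

    def __post_init__(self) -> None:
        for (age, status), p in self.p_death.items():
            if status not in STATUSES:
                raise ValueError(f"unknown smoking status {status!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_death({age}, {status})={p} outside [0, 1]")

    @property
    def ages(self) -> np.ndarray:
        return np.array(sorted({a for a, _ in self.p_death}), dtype=int)

    def lookup(self, age: int, status: str) -> float:
        return self.p_death[(age, status)]

    def p_array(self, status: str) -> np.ndarray:
        return np.array([self.p_death[(a, status)] for a in self.ages], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"age": a, "status": s, "p_death": p}
                for (a, s), p in sorted(self.p_death.items())]
        return pd.DataFrame(rows, columns=["age", "status", "p_death"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def split_mortality(lt: LifeTable, cs: CauseSplit) -> pd.DataFrame:
    """Split each age's total mortality hazard into cancer / non-cancer parts.

    Converts the annual death probability to a hazard, m = -ln(1-q), then
    apportions it by the cancer fraction of deaths at that age.  Ages with
    q=1 (the table's closed terminal age) get a large capped hazard and a
    warning rather than an infinity.

    Returns a DataFrame with columns ``age, hazard_total, hazard_cancer,
    hazard_noncancer``.
    """
    lt_ages, cs_ages = set(map(int, lt.ages)), set(map(int, cs.ages))
    if lt_ages != cs_ages:
        raise ValueError("life table and cause split must cover the same ages")
    if lt.sex != cs.sex:
        raise ValueError(f"sex mismatch: life table {lt.sex!r} vs cause split {cs.sex!r}")

    q = lt.q_array()
    with np.errstate(divide="ignore"):
        m = -np.log1p(-q)
    if np.any(~np.isfinite(m)):
        # q=1 at the closed terminal age is expected; warn only elsewhere
        if np.any(~np.isfinite(m[:-1])):
            warnings.warn("q=1 encountered before the terminal age; hazard capped",
                          RuntimeWarning, stacklevel=2)
        m = np.where(np.isfinite(m), m, _MAX_HAZARD)
    f = cs.f_array()
    return pd.DataFrame({
        "age": lt.ages,
        "hazard_total": m,
        "hazard_cancer": m * f,
        "hazard_noncancer": m * (1.0 - f),
    })


def derive_adjusted_mortality(
    lt: LifeTable,
    cs: CauseSplit,
    mp: MortalityParams,
    excess_cancer_multiplier: float = DEFAULT_EXCESS_CANCER_MULTIPLIER,
    hr_on: str = "noncancer",
) -> AdjustedMortality:
    """Annual death probabilities by age and smoking status (steps 1-6).

    With the default ``hr_on="noncancer"``,
    ``p(age, status) = 1 - exp(-(HR_status * m_noncancer
    + excess_cancer_multiplier * m_cancer))`` — the smoking hazard ratio
    scales the non-cancer component while the (excess-scaled) cancer
    component is shared by both statuses.  With ``hr_on="total"`` the HR
    multiplies the combined cancer-patient hazard instead.
    """
    if excess_cancer_multiplier < 1.0:
        raise ValueError("excess_cancer_multiplier must be >= 1")
    if mp.hr_current_vs_never <= 0 or mp.hr_former_vs_never <= 0:
        raise ValueError("hazard ratios must be strictly positive")
    if hr_on not in ("noncancer", "total"):
        raise ValueError(f"hr_on must be 'noncancer' or 'total', got {hr_on!r}")

    hazards = split_mortality(lt, cs)
    m_nc = hazards["hazard_noncancer"].to_numpy()
    m_c = excess_cancer_multiplier * hazards["hazard_cancer"].to_numpy()
    hrs = {"current": mp.hr_current_vs_never, "former": mp.hr_former_vs_never}
    p_death: dict[tuple[int, str], float] = {}
    for status, hr in hrs.items():
        if hr_on == "noncancer":
            m_status = hr * m_nc + m_c
        else:
            m_status = hr * (m_nc + m_c)
        p = 1.0 - np.exp(-m_status)
        for age, pi in zip(hazards["age"], p):
            p_death[(int(age), status)] = float(min(pi, 1.0))
    m0 = m_nc + m_c
    logger.info(
        "derived adjusted mortality (%s): baseline hazard at %d = %.6f, "
        "p(current) = %.6f, p(former) = %.6f",
        lt.sex, int(hazards["age"].iloc[0]), m0[0],
        p_death[(int(hazards["age"].iloc[0]), "current")],
        p_death[(int(hazards["age"].iloc[0]), "former")],
    )
    return AdjustedMortality(sex=lt.sex, p_death=p_death)
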