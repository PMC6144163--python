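"""Model parameters: probabilities, costs, utilities, and run settings.

Every quantity that drives the model lives here as a typed, validated
parameter with a base value and an uncertainty range (interpreted as 95%
confidence bounds when fitting sampling distributions for probabilistic
sensitivity analysis).  The packaged defaults describe two smoking-cessation
strategies for a cohort of 65-year-old cancer patients:

* ``basic`` — screening, advice and referral only (one-time administration
  cost, low 12-month abstinence).
* ``best_practice`` — the basic program plus varenicline, nurse counseling
  and follow-up (higher one-time cost, higher 12-month abstinence).

Parameters load from a flat key-value YAML file; missing keys fall back to
the packaged defaults, so the whole pipeline runs with zero inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "DistKind",
    "ParamSpec",
    "CessationParams",
    "MortalityParams",
    "CostParams",
    "UtilityParams",
    "EconSettings",
    "ModelParams",
    "RELAPSE_BANDS",
    "default_params",
    "load_params",
    "save_params",
    "export_param_table",
]

#: Quit-duration bands for former smokers, with annual relapse probability
#: depending on years since quitting.  Band dwell times (years) drive the
#: tunnel-state expansion in the Markov engine.
RELAPSE_BANDS = ("1-2", "3-4", "5-8", "9-10", "10+")


class DistKind(str, Enum):
    """Sampling-distribution family assigned to a parameter for PSA."""

    beta = "beta"
    gamma = "gamma"
    lognormal = "lognormal"
    fixed = "fixed"


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


class ParseError(ValueError):
    """A parameter file entry could not be interpreted."""


@dataclass(frozen=True)
class ParamSpec:
    """One scalar parameter: base value, 95% bounds, distribution family."""

    name: str
    base: float
    lower: float
    upper: float
    dist_kind: DistKind = DistKind.fixed

    def __post_init__(self) -> None:
        if not (self.lower <= self.base <= self.upper):
            raise ValidationError(
                f"{self.name}: require lower <= base <= upper, "
                f"got ({self.lower}, {self.base}, {self.upper})"
            )
        if self.dist_kind is DistKind.beta:
            if not (0.0 <= self.lower and self.upper <= 1.0):
                raise ValidationError(f"{self.name}: beta-kind values must lie in [0, 1]")
        elif self.dist_kind is DistKind.gamma:
            if self.lower < 0.0:
                raise ValidationError(f"{self.name}: gamma-kind values must be >= 0")
        elif self.dist_kind is DistKind.lognormal:
            if self.lower <= 0.0:
                raise ValidationError(f"{self.name}: lognormal-kind values must be > 0")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name}={value!r} is not a probability in [0, 1]")


@dataclass(frozen=True)
class CessationParams:
    """Quit and relapse probabilities (annual)."""

    abstinence_bp_y1: float = 0.24
    abstinence_basic_y1: float = 0.04
    program_quit_y2: float = 0.02
    self_quit: float = 0.015
    relapse_by_band: tuple[float, ...] = (0.24, 0.10, 0.02, 0.021, 0.005)

    def __post_init__(self) -> None:
        for name in ("abstinence_bp_y1", "abstinence_basic_y1", "program_quit_y2", "self_quit"):
            _check_prob(name, getattr(self, name))
        if len(self.relapse_by_band) != len(RELAPSE_BANDS):
            raise ValidationError(
                f"relapse_by_band needs {len(RELAPSE_BANDS)} entries (bands {RELAPSE_BANDS})"
            )
        for band, p in zip(RELAPSE_BANDS, self.relapse_by_band):
            _check_prob(f"relapse_{band}", p)
        if self.relapse_by_band[-1] > self.relapse_by_band[0]:
            raise ValidationError("relapse for band 10+ must not exceed relapse for band 1-2")


@dataclass(frozen=True)
class MortalityParams:
    """Mortality hazard ratios versus never smokers (cancer patients)."""

    hr_current_vs_never: float = 1.50
    hr_former_vs_never: float = 1.30

    def __post_init__(self) -> None:
        if self.hr_current_vs_never <= 0 or self.hr_former_vs_never <= 0:
            raise ValidationError("hazard ratios must be strictly positive")


@dataclass(frozen=True)
class CostParams:
    """Costs in 2015 Canadian dollars.

    One-time costs are charged to the whole entering cohort at entry;
    annual costs accrue per cycle to the states indicated.
    """

    nurse_fee: float = 105.0  # counseling, one-time (best practice)
    bp_admin: float = 47.0  # program administration, one-time (best practice)
    basic_admin: float = 16.0  # program administration, one-time (basic)
    varenicline: float = 150.0  # pharmacotherapy, one-time (best practice)
    annual_cancer_cost: float = 25_058.0  # per alive patient-year
    smoking_attrib_cost: float = 403.0  # per current-smoker-year

    def __post_init__(self) -> None:
        for f in ("nurse_fee", "bp_admin", "basic_admin", "varenicline",
                  "annual_cancer_cost", "smoking_attrib_cost"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be >= 0")


#: Age bands over which utilities are constant.
UTILITY_AGE_BANDS = ((65, 74), (75, 100))


@dataclass(frozen=True)
class UtilityParams:
    """EQ-5D utility weights by sex, age band and smoking status.

    ``utility`` maps ``(sex, age_band, status)`` with sex in
    {"male", "female"}, age_band in {"65-74", "75-100"} and status in
    {"current", "former"}.  A fixed decrement is subtracted for cancer.
    """

    utility: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("female", "65-74", "former"): 0.7709,
            ("female", "75-100", "former"): 0.6981,
            ("female", "65-74", "current"): 0.7496,
            ("female", "75-100", "current"): 0.6753,
            ("male", "65-74", "former"): 0.7802,
            ("male", "75-100", "former"): 0.7358,
            ("male", "65-74", "current"): 0.7551,
            ("male", "75-100", "current"): 0.7089,
        }
    )
    cancer_decrement: float = 0.12

    def __post_init__(self) -> None:
        for key, u in self.utility.items():
            if not (0.0 <= u <= 1.0):
                raise ValidationError(f"utility{key}={u} outside [0, 1]")
        for sex in ("male", "female"):
            for band in ("65-74", "75-100"):
                cur = self.utility[(sex, band, "current")]
                fmr = self.utility[(sex, band, "former")]
                if fmr < cur:
                    raise ValidationError(
                        f"former-smoker utility below current-smoker utility for {sex} {band}"
                    )
        _check_prob("cancer_decrement", self.cancer_decrement)

    def lookup(self, sex: str, age: float, status: str) -> float:
        """Utility weight for an alive state, before the cancer decrement."""
        if 65 <= age <= 74:
            band = "65-74"
        elif 75 <= age <= 100:
            band = "75-100"
        else:
            raise ValidationError(f"age {age} outside utility bands 65-74 / 75-100")
        return self.utility[(sex, band, status)]


@dataclass(frozen=True)
class EconSettings:
    """Run configuration: horizon, discounting and accounting flags."""

    discount_rate: float = 0.05
    start_age: int = 65
    end_age: int = 100
    cycle_length: float = 1.0
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 105_000, 5_000))
    include_cancer_cost: bool = True
    half_cycle_correction: bool = False
    #: years of abstinence during which a former smoker still incurs the
    #: smoking-attributable annual cost (excess utilization decays over the
    #: first relapse bands rather than vanishing at the quit date)
    smoking_cost_decay_years: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate < 1.0):
            raise ValidationError("discount_rate must satisfy 0 <= r < 1")
        if self.end_age <= self.start_age:
            raise ValidationError("end_age must exceed start_age")
        if self.smoking_cost_decay_years < 0:
            raise ValidationError("smoking_cost_decay_years must be >= 0")

    @property
    def n_cycles(self) -> int:
        return int(round((self.end_age - self.start_age) / self.cycle_length))


@dataclass(frozen=True)
class ModelParams:
    """Aggregate of all model parameters."""

    cessation: CessationParams = field(default_factory=CessationParams)
    mortality: MortalityParams = field(default_factory=MortalityParams)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    settings: EconSettings = field(default_factory=EconSettings)

    # ------------------------------------------------------------------
    # named scalar access (drives tornado / PSA re-parameterisation)
    # ------------------------------------------------------------------
    def param_specs(self) -> dict[str, ParamSpec]:
        """The uncertain scalar parameters with their 95% ranges.

        Utilities carry no published ranges and are treated as fixed; the
        cancer utility decrement does have a range and is beta-distributed.
        The time-horizon scenario (2 / 4 years) is handled separately by the
        tornado analysis, not as a sampled scalar.
        """
        c = self.cessation
        specs = [
            ParamSpec("abstinence_bp_y1", c.abstinence_bp_y1, 0.14, 0.36, DistKind.beta),
            ParamSpec("abstinence_basic_y1", c.abstinence_basic_y1, 0.03, 0.05, DistKind.beta),
            ParamSpec("program_quit_y2", c.program_quit_y2, 0.02, 0.03, DistKind.beta),
            ParamSpec("self_quit", c.self_quit, 0.012, 0.018, DistKind.beta),
            ParamSpec("relapse_1_2", c.relapse_by_band[0], 0.19, 0.29, DistKind.beta),
            ParamSpec("relapse_3_4", c.relapse_by_band[1], 0.08, 0.12, DistKind.beta),
            ParamSpec("relapse_5_8", c.relapse_by_band[2], 0.016, 0.024, DistKind.beta),
            ParamSpec("relapse_9_10", c.relapse_by_band[3], 0.017, 0.025, DistKind.beta),
            ParamSpec("relapse_10plus", c.relapse_by_band[4], 0.004, 0.006, DistKind.beta),
            ParamSpec("hr_current_vs_never", self.mortality.hr_current_vs_never,
                      1.07, 1.50, DistKind.lognormal),
            ParamSpec("hr_former_vs_never", self.mortality.hr_former_vs_never,
                      0.95, 1.81, DistKind.lognormal),
            ParamSpec("nurse_fee", self.costs.nurse_fee, 95.0, 116.0, DistKind.gamma),
            ParamSpec("bp_admin", self.costs.bp_admin, 33.0, 61.0, DistKind.gamma),
            ParamSpec("basic_admin", self.costs.basic_admin, 15.0, 18.0, DistKind.gamma),
            ParamSpec("varenicline", self.costs.varenicline, 105.0, 195.0, DistKind.gamma),
            ParamSpec("annual_cancer_cost", self.costs.annual_cancer_cost,
                      24_897.0, 25_219.0, DistKind.gamma),
            ParamSpec("smoking_attrib_cost", self.costs.smoking_attrib_cost,
                      262.0, 486.0, DistKind.gamma),
            ParamSpec("cancer_decrement", self.utilities.cancer_decrement,
                      0.11, 0.13, DistKind.beta),
        ]
        # fixed utilities, so the exported parameter table is complete
        for (sex, band, status), u in sorted(self.utilities.utility.items()):
            name = f"utility_{sex}_{band.replace('-', '_')}_{status}"
            specs.append(ParamSpec(name, u, u, u, DistKind.fixed))
        return {s.name: s for s in specs}

    _BAND_KEYS = {
        "relapse_1_2": 0, "relapse_3_4": 1, "relapse_5_8": 2,
        "relapse_9_10": 3, "relapse_10plus": 4,
    }

    def with_value(self, name: str, value: float) -> "ModelParams":
        """A copy of this parameter set with one named scalar replaced."""
        if name in self._BAND_KEYS:
            bands = list(self.cessation.relapse_by_band)
            bands[self._BAND_KEYS[name]] = value
            return replace(self, cessation=replace(self.cessation, relapse_by_band=tuple(bands)))
        for attr in ("abstinence_bp_y1", "abstinence_basic_y1", "program_quit_y2", "self_quit"):
            if name == attr:
                return replace(self, cessation=replace(self.cessation, **{attr: value}))
        for attr in ("hr_current_vs_never", "hr_former_vs_never"):
            if name == attr:
                return replace(self, mortality=replace(self.mortality, **{attr: value}))
        for attr in ("nurse_fee", "bp_admin", "basic_admin", "varenicline",
                     "annual_cancer_cost", "smoking_attrib_cost"):
            if name == attr:
                return replace(self, costs=replace(self.costs, **{attr: value}))
        if name == "cancer_decrement":
            return replace(self, utilities=replace(self.utilities, cancer_decrement=value))
        if name.startswith("utility_"):
            sex, *band_parts, status = name[len("utility_"):].split("_")
            band = "-".join(band_parts)
            key = (sex, band, status)
            util = dict(self.utilities.utility)
            if key not in util:
                raise KeyError(name)
            util[key] = value
            return replace(self, utilities=replace(self.utilities, utility=util))
        raise KeyError(f"unknown parameter {name!r}")


def default_params() -> ModelParams:
    """The packaged default parameter set."""
    return ModelParams()


# ----------------------------------------------------------------------
# file IO: flat key-value YAML
# ----------------------------------------------------------------------

_FLAT_KEYS = {
    "abstinence_bp_y1": ("cessation", "abstinence_bp_y1"),
    "abstinence_basic_y1": ("cessation", "abstinence_basic_y1"),
    "program_quit_y2": ("cessation", "program_quit_y2"),
    "self_quit": ("cessation", "self_quit"),
    "hr_current_vs_never": ("mortality", "hr_current_vs_never"),
    "hr_former_vs_never": ("mortality", "hr_former_vs_never"),
    "nurse_fee": ("costs", "nurse_fee"),
    "bp_admin": ("costs", "bp_admin"),
    "basic_admin": ("costs", "basic_admin"),
    "varenicline": ("costs", "varenicline"),
    "annual_cancer_cost": ("costs", "annual_cancer_cost"),
    "smoking_attrib_cost": ("costs", "smoking_attrib_cost"),
    "cancer_decrement": ("utilities", "cancer_decrement"),
    "discount_rate": ("settings", "discount_rate"),
    "start_age": ("settings", "start_age"),
    "end_age": ("settings", "end_age"),
    "cycle_length": ("settings", "cycle_length"),
    "include_cancer_cost": ("settings", "include_cancer_cost"),
    "half_cycle_correction": ("settings", "half_cycle_correction"),
    "smoking_cost_decay_years": ("settings", "smoking_cost_decay_years"),
}

_RELAPSE_KEYS = {f"relapse_{b.replace('-', '_').replace('+', 'plus')}": i
                 for i, b in enumerate(RELAPSE_BANDS)}
# relapse_1_2, relapse_3_4, relapse_5_8, relapse_9_10, relapse_10plus

_INT_KEYS = {"start_age", "end_age", "smoking_cost_decay_years"}
_BOOL_KEYS = {"include_cancer_cost", "half_cycle_correction"}


def _coerce(key: str, raw: object) -> object:
    try:
        if key in _BOOL_KEYS:
            if isinstance(raw, bool):
                return raw
            if isinstance(raw, str) and raw.lower() in {"true", "false"}:
                return raw.lower() == "true"
            raise ValueError("expected a boolean")
        if key in _INT_KEYS:
            return int(raw)  # type: ignore[arg-type]
        if key == "wtp_grid":
            return tuple(float(x) for x in raw)  # type: ignore[union-attr]
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ParseError(f"cannot parse value for key {key!r}: {raw!r}") from exc


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter set from a flat key-value YAML file.

    Keys absent from the file fall back to the packaged defaults.
    ``path=None`` (or an empty file) yields the defaults unchanged.

    Raises
    ------
    ParseError
        A value could not be interpreted; the message names the key.
    ValidationError
        A value violates a model invariant; the message names the constraint.
    """
    if path is None:
        return default_params()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a flat key-value mapping")

    groups: dict[str, dict[str, object]] = {
        "cessation": {}, "mortality": {}, "costs": {}, "utilities": {}, "settings": {},
    }
    relapse = list(CessationParams().relapse_by_band)
    utility = dict(UtilityParams().utility)
    for key, raw_val in raw.items():
        if key in _FLAT_KEYS:
            group, attr = _FLAT_KEYS[key]
            groups[group][attr] = _coerce(key, raw_val)
        elif key in _RELAPSE_KEYS:
            relapse[_RELAPSE_KEYS[key]] = _coerce(key, raw_val)
        elif key == "wtp_grid":
            groups["settings"]["wtp_grid"] = _coerce(key, raw_val)
        elif key.startswith("utility_"):
            sex, *band_parts, status = key[len("utility_"):].split("_")
            ukey = (sex, "-".join(band_parts), status)
            if ukey not in utility:
                raise ParseError(f"unknown utility key {key!r}")
            utility[ukey] = _coerce(key, raw_val)
        else:
            raise ParseError(f"unknown parameter key {key!r}")
    groups["cessation"]["relapse_by_band"] = tuple(relapse)
    groups["utilities"]["utility"] = utility

    return ModelParams(
        cessation=CessationParams(**groups["cessation"]),
        mortality=MortalityParams(**groups["mortality"]),
        costs=CostParams(**groups["costs"]),
        utilities=UtilityParams(**groups["utilities"]),
        settings=EconSettings(**groups["settings"]),
    )


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as a flat key-value YAML file (round-trips)."""
    flat: dict[str, object] = {}
    for key, (group, attr) in _FLAT_KEYS.items():
        flat[key] = getattr(getattr(params, group), attr)
    for key, idx in _RELAPSE_KEYS.items():
        flat[key] = params.cessation.relapse_by_band[idx]
    for (sex, band, status), u in sorted(params.utilities.utility.items()):
        flat[f"utility_{sex}_{band.replace('-', '_')}_{status}"] = u
    flat["wtp_grid"] = list(params.settings.wtp_grid)
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


def export_param_table(params: ModelParams, path: str | Path | None = None) -> pd.DataFrame:
    """The resolved parameter table (name, base, lower, upper, dist_kind)."""
    rows = [
        {"name": s.name, "base": s.base, "lower": s.lower, "upper": s.upper,
         "dist_kind": s.dist_kind.value}
        for s in params.param_specs().values()
    ]
    df = pd.DataFrame(rows, columns=["name", "base", "lower", "upper", "dist_kind"])
    if path is not None:
        df.to_csv(path, index=False)
    return df
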