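"""Model parameters: validation, synthetic generation, scenarios and fixtures.

The cohort engine needs annual, age- and sex-specific disease incidence for
never-smokers and current smokers, post-quit excess-risk decay fractions,
case fatality, background mortality, yearly disease costs and state utility
weights.  The original calibration tables are not redistributable, so
:func:`generate_synthetic_parameters` produces a structurally equivalent,
order-of-magnitude-plausible parameter set that is deterministic in its seed.

Printed summary tables from the source trial (per-person quit benefits,
abstinence counts, intervention costs, logistic coefficients) are packaged as
CSV fixtures and exposed through :func:`load_fixture_table`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "SEXES",
    "STATES",
    "ModelParameters",
    "SensitivityScenario",
    "LOW_COST_LOW_RISK",
    "ParameterError",
    "generate_synthetic_parameters",
    "apply_scenario",
    "load_fixture_table",
    "list_fixtures",
    "write_parameters",
    "read_parameters",
]

logger = logging.getLogger(__name__)

DISEASES = ("lung_cancer", "copd", "chd", "stroke")
SEXES = ("female", "male")
STATES = ("well",) + DISEASES + ("dead",)

_FIXTURES = (
    "table3_per_person",
    "table3_counts",
    "table3_group_differences",
    "intervention_costs",
    "table1_counts",
    "table2_logistic",
    "table4",
    "random_person_estimates",
)


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class ModelParameters:
    """Complete input set for the cohort model.

    Arrays are indexed by single year of age from ``age_min`` to
    ``max_age - 1`` (the age at the start of each annual cycle).  Decay
    fractions are indexed by whole years since quitting and held at their
    last value beyond the stored horizon.
    """

    age_min: int
    max_age: int
    discount_rate: float
    incidence_never: dict[tuple[str, str], np.ndarray]
    incidence_smoker: dict[tuple[str, str], np.ndarray]
    case_fatality: dict[tuple[str, str], np.ndarray]
    background_mortality: dict[str, np.ndarray]
    decay_fraction: dict[str, np.ndarray]
    disease_cost: dict[str, float]
    utility: dict[str, float]
    diseases: tuple[str, ...] = DISEASES

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.max_age)

    @property
    def n_ages(self) -> int:
        return self.max_age - self.age_min

    def decay(self, disease: str, t_since_quit: int) -> float:
        """Remaining excess-risk fraction ``t_since_quit`` years after quitting."""
        arr = self.decay_fraction[disease]
        return float(arr[min(t_since_quit, len(arr) - 1)])

    def validate(self) -> None:
        """Check every invariant; raise :class:`ParameterError` on the first failure."""
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if not (self.age_min < self.max_age):
            raise ParameterError("age_min must be below max_age")
        n = self.n_ages
        for sex in SEXES:
            m = np.asarray(self.background_mortality[sex], dtype=float)
            if m.shape != (n,):
                raise ParameterError(f"background_mortality[{sex}] has wrong length")
            _check_prob(m, f"background_mortality[{sex}]")
        for d in self.diseases:
            for sex in SEXES:
                inn = np.asarray(self.incidence_never[(d, sex)], dtype=float)
                ism = np.asarray(self.incidence_smoker[(d, sex)], dtype=float)
                cf = np.asarray(self.case_fatality[(d, sex)], dtype=float)
                for name, arr in (
                    (f"incidence_never[{d},{sex}]", inn),
                    (f"incidence_smoker[{d},{sex}]", ism),
                    (f"case_fatality[{d},{sex}]", cf),
                ):
                    if arr.shape != (n,):
                        raise ParameterError(f"{name} has wrong length")
                    _check_prob(arr, name)
                if np.any(ism < inn - 1e-12):
                    raise ParameterError(
                        f"incidence_smoker < incidence_never for {d}/{sex}"
                    )
            dec = np.asarray(self.decay_fraction[d], dtype=float)
            # freshly generated sets start at exactly 1; scenario-perturbed
            # sets may start lower, so only an upper bound is enforced here
            if dec.size == 0 or dec[0] > 1.0 + 1e-12:
                raise ParameterError(f"decay_fraction[{d}] must start at <= 1")
            if np.any(np.diff(dec) > 1e-12):
                raise ParameterError(f"decay_fraction[{d}] must be non-increasing")
            _check_prob(dec, f"decay_fraction[{d}]")
            if self.disease_cost[d] < 0:
                raise ParameterError(f"disease_cost[{d}] must be >= 0")
        for state in ("well", "dead", *self.diseases):
            u = self.utility[state]
            if not (0.0 <= u <= 1.0):
                raise ParameterError(f"utility[{state}]={u} outside [0,1]")
        if self.utility["dead"] != 0.0:
            raise ParameterError("utility[dead] must be 0")

    def copy(self) -> "ModelParameters":
        return replace(
            self,
            incidence_never={k: v.copy() for k, v in self.incidence_never.items()},
            incidence_smoker={k: v.copy() for k, v in self.incidence_smoker.items()},
            case_fatality={k: v.copy() for k, v in self.case_fatality.items()},
            background_mortality={
                k: v.copy() for k, v in self.background_mortality.items()
            },
            decay_fraction={k: v.copy() for k, v in self.decay_fraction.items()},
            disease_cost=dict(self.disease_cost),
            utility=dict(self.utility),
        )


def _check_prob(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError(f"{name} outside [0,1]")


@dataclass(frozen=True)
class SensitivityScenario:
    """Multiplicative / subtractive perturbation of a parameter set."""

    cost_multiplier: float = 1.0
    disease_risk_multiplier: float = 1.0
    death_risk_multiplier: float = 1.0
    decay_fraction_delta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cost_multiplier", "disease_risk_multiplier", "death_risk_multiplier"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name}={v} must be in (0,1]")
        if not (0.0 <= self.decay_fraction_delta <= 1.0):
            raise ParameterError("decay_fraction_delta must be in [0,1]")


#: Most conservative multivariate scenario: costs -25%, disease risks -50%,
#: death risks -10%, post-quit residual-risk fractions reduced by 0.1.
LOW_COST_LOW_RISK = SensitivityScenario(
    cost_multiplier=0.75,
    disease_risk_multiplier=0.5,
    death_risk_multiplier=0.9,
    decay_fraction_delta=0.1,
)

SCENARIOS: Mapping[str, SensitivityScenario] = {
    "identity": SensitivityScenario(),
    "low_cost_low_risk": LOW_COST_LOW_RISK,
}

# Synthetic-generator default ranges.  Relative risks by disease are drawn
# within these bounds unless overridden; they only need to be plausible in
# order of magnitude, not calibrated.
_DEFAULT_RR_RANGE = {
    "lung_cancer": (8.0, 15.0),
    "copd": (6.0, 12.0),
    "chd": (2.0, 4.0),
    "stroke": (2.0, 3.0),
}
_BASE_INCIDENCE = {  # never-smoker incidence at age_min; moderate age slopes
    # keep enough excess risk in mid-life that quitting young pays off
    "lung_cancer": 8e-5,
    "copd": 2e-4,
    "chd": 8e-4,
    "stroke": 4e-4,
}
_INCIDENCE_SLOPE = {"lung_cancer": 0.060, "copd": 0.055, "chd": 0.045, "stroke": 0.050}
_CASE_FATALITY_BASE = {"lung_cancer": 0.25, "copd": 0.04, "chd": 0.05, "stroke": 0.06}
_COST_RANGE = {  # yearly societal cost in euro, log-uniform
    "lung_cancer": (20_000.0, 60_000.0),
    "copd": (5_000.0, 20_000.0),
    "chd": (5_000.0, 25_000.0),
    "stroke": (10_000.0, 40_000.0),
}
_UTILITY_RANGE = {
    "lung_cancer": (0.40, 0.60),
    "copd": (0.55, 0.75),
    "chd": (0.60, 0.80),
    "stroke": (0.45, 0.70),
}


def generate_synthetic_parameters(
    seed: int,
    *,
    relative_risk: Mapping[str, float] | None = None,
    decay_residual: Mapping[str, float] | float | None = None,
    decay_years: Mapping[str, float] | float | None = None,
    discount_rate: float = 0.03,
    age_min: int = 19,
    max_age: int = 95,
) -> ModelParameters:
    """Generate a valid synthetic parameter set, deterministic in ``seed``.

    Parameters
    ----------
    seed
        Non-negative integer seeding all random draws.
    relative_risk
        Optional per-disease smoker/never incidence ratio overrides
        (must be >= 1).  Defaults are drawn per disease from plausible
        epidemiological ranges.
    decay_residual, decay_years
        Remaining excess-risk fraction reached ``decay_years`` after
        quitting (exponential decline, flat thereafter).  Scalars apply to
        all diseases.
    """
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ParameterError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    ages = np.arange(age_min, max_age)
    n = len(ages)

    rr: dict[str, float] = {}
    for d in DISEASES:
        lo, hi = _DEFAULT_RR_RANGE[d]
        rr[d] = float(rng.uniform(lo, hi))
    if relative_risk:
        for d, v in relative_risk.items():
            if d not in DISEASES:
                raise ParameterError(f"relative_risk: unknown disease {d!r}")
            if v < 1.0:
                raise ParameterError(f"relative_risk[{d}]={v} must be >= 1")
            rr[d] = float(v)

    residual = _per_disease(decay_residual, rng, lambda: rng.uniform(0.02, 0.15))
    horizon_years = _per_disease(decay_years, rng, lambda: rng.uniform(10.0, 15.0))

    incidence_never: dict[tuple[str, str], np.ndarray] = {}
    incidence_smoker: dict[tuple[str, str], np.ndarray] = {}
    case_fatality: dict[tuple[str, str], np.ndarray] = {}
    decay_fraction: dict[str, np.ndarray] = {}
    disease_cost: dict[str, float] = {}

    for d in DISEASES:
        slope = _INCIDENCE_SLOPE[d] * rng.uniform(0.9, 1.1)
        base = _BASE_INCIDENCE[d] * rng.uniform(0.5, 2.0)
        for sex in SEXES:
            sex_mult = 1.0 if sex == "female" else rng.uniform(1.0, 1.6)
            inn = np.minimum(base * sex_mult * np.exp(slope * (ages - age_min)), 0.05)
            ism = np.minimum(rr[d] * inn, 0.5)
            cf = np.minimum(
                _CASE_FATALITY_BASE[d]
                * rng.uniform(0.8, 1.2)
                * np.exp(0.02 * (ages - age_min)),
                0.95,
            )
            incidence_never[(d, sex)] = inn
            incidence_smoker[(d, sex)] = ism
            case_fatality[(d, sex)] = cf
        # exponential decline to the residual fraction, then flat
        k = -np.log(residual[d]) / horizon_years[d]
        t = np.arange(n, dtype=float)
        decay_fraction[d] = np.maximum(np.exp(-k * t), residual[d])
        decay_fraction[d][0] = 1.0
        lo, hi = _COST_RANGE[d]
        disease_cost[d] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    background_mortality = {}
    for sex in SEXES:
        mult = 1.0 if sex == "female" else rng.uniform(1.1, 1.5)
        background_mortality[sex] = np.minimum(
            2e-4 * mult * np.exp(0.085 * (ages - age_min)), 1.0
        )

    utility = {"well": float(rng.uniform(0.86, 0.92)), "dead": 0.0}
    for d in DISEASES:
        lo, hi = _UTILITY_RANGE[d]
        utility[d] = float(rng.uniform(lo, hi))

    params = ModelParameters(
        age_min=age_min,
        max_age=max_age,
        discount_rate=discount_rate,
        incidence_never=incidence_never,
        incidence_smoker=incidence_smoker,
        case_fatality=case_fatality,
        background_mortality=background_mortality,
        decay_fraction=decay_fraction,
        disease_cost=disease_cost,
        utility=utility,
    )
    params.validate()
    return params


def _per_disease(value, rng, default_draw) -> dict[str, float]:
    if value is None:
        return {d: float(default_draw()) for d in DISEASES}
    if isinstance(value, Mapping):
        out = {}
        for d in DISEASES:
            out[d] = float(value.get(d, default_draw()))
        return out
    return {d: float(value) for d in DISEASES}


def apply_scenario(
    params: ModelParameters, scenario: SensitivityScenario
) -> ModelParameters:
    """Return a new parameter set with the scenario applied; input unchanged.

    Excess incidence (smoker minus never) is scaled, never-smoker incidence
    is left alone; both death-risk families (case fatality and background
    mortality) are scaled; decay fractions are shifted down and floored at
    zero; yearly disease costs are scaled.  Any probability pushed outside
    [0,1] is clamped with a warning.
    """
    out = params.copy()
    # unit multipliers are exact no-ops so the identity scenario is
    # bit-for-bit idempotent
    for d in out.diseases:
        if scenario.cost_multiplier != 1.0:
            out.disease_cost[d] = out.disease_cost[d] * scenario.cost_multiplier
        for sex in SEXES:
            key = (d, sex)
            if scenario.disease_risk_multiplier != 1.0:
                excess = out.incidence_smoker[key] - out.incidence_never[key]
                out.incidence_smoker[key] = _clamped(
                    out.incidence_never[key]
                    + scenario.disease_risk_multiplier * excess,
                    f"incidence_smoker[{d},{sex}]",
                )
            if scenario.death_risk_multiplier != 1.0:
                out.case_fatality[key] = _clamped(
                    out.case_fatality[key] * scenario.death_risk_multiplier,
                    f"case_fatality[{d},{sex}]",
                )
        if scenario.decay_fraction_delta != 0.0:
            # decay(0)=1 holds for unperturbed sets only; a perturbed set
            # intentionally starts below 1.
            out.decay_fraction[d] = np.maximum(
                out.decay_fraction[d] - scenario.decay_fraction_delta, 0.0
            )
    if scenario.death_risk_multiplier != 1.0:
        for sex in SEXES:
            out.background_mortality[sex] = _clamped(
                out.background_mortality[sex] * scenario.death_risk_multiplier,
                f"background_mortality[{sex}]",
            )
    return out


def _clamped(arr: np.ndarray, name: str) -> np.ndarray:
    if np.any(arr < 0) or np.any(arr > 1):
        logger.warning("%s clamped to [0,1] after scenario", name)
        warnings.warn(f"{name} clamped to [0,1] after scenario", stacklevel=3)
        return np.clip(arr, 0.0, 1.0)
    return arr


# ---------------------------------------------------------------------------
# fixture registry


def list_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by name.

    Raises :class:`KeyError` listing the available fixtures for unknown names.
    """
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}"
        )
    ref = resources.files("quitcea.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


# ---------------------------------------------------------------------------
# CSV round-trip for parameter sets


def write_parameters(params: ModelParameters, stem: str | Path) -> list[Path]:
    """Write a parameter set to ``<stem>_{risks,econ,mortality,decay}.csv``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    risks = pd.DataFrame(
        [
            {
                "disease": d,
                "sex": sex,
                "age": int(age),
                "incidence_never": params.incidence_never[(d, sex)][i],
                "incidence_smoker": params.incidence_smoker[(d, sex)][i],
                "case_fatality": params.case_fatality[(d, sex)][i],
            }
            for d in params.diseases
            for sex in SEXES
            for i, age in enumerate(params.ages)
        ]
    )
    econ_rows = [
        {"quantity": "disease_cost", "key": d, "value": params.disease_cost[d]}
        for d in params.diseases
    ]
    econ_rows += [
        {"quantity": "utility", "key": s, "value": params.utility[s]}
        for s in ("well", "dead", *params.diseases)
    ]
    econ_rows += [
        {"quantity": "discount_rate", "key": "", "value": params.discount_rate},
        {"quantity": "age_min", "key": "", "value": params.age_min},
        {"quantity": "max_age", "key": "", "value": params.max_age},
    ]
    econ = pd.DataFrame(econ_rows)
    mortality = pd.DataFrame(
        [
            {
                "sex": sex,
                "age": int(age),
                "background_mortality": params.background_mortality[sex][i],
            }
            for sex in SEXES
            for i, age in enumerate(params.ages)
        ]
    )
    decay = pd.DataFrame(
        [
            {"disease": d, "t_since_quit": t, "fraction": f}
            for d in params.diseases
            for t, f in enumerate(params.decay_fraction[d])
        ]
    )
    paths = []
    for suffix, frame in (
        ("risks", risks),
        ("econ", econ),
        ("mortality", mortality),
        ("decay", decay),
    ):
        p = stem.with_name(f"{stem.name}_{suffix}.csv")
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths


def read_parameters(stem: str | Path) -> ModelParameters:
    """Inverse of :func:`write_parameters`."""
    stem = Path(stem)
    risks = pd.read_csv(stem.with_name(f"{stem.name}_risks.csv"))
    econ = pd.read_csv(stem.with_name(f"{stem.name}_econ.csv"), keep_default_na=False)
    mortality = pd.read_csv(stem.with_name(f"{stem.name}_mortality.csv"))
    decay = pd.read_csv(stem.with_name(f"{stem.name}_decay.csv"))

    econ = econ.assign(value=pd.to_numeric(econ["value"]))
    scalars = econ.set_index(["quantity", "key"])["value"]
    age_min = int(scalars[("age_min", "")])
    max_age = int(scalars[("max_age", "")])
    discount_rate = float(scalars[("discount_rate", "")])
    diseases = tuple(dict.fromkeys(risks["disease"]))

    incidence_never, incidence_smoker, case_fatality = {}, {}, {}
    for (d, sex), grp in risks.groupby(["disease", "sex"], sort=False):
        grp = grp.sort_values("age")
        incidence_never[(d, sex)] = grp["incidence_never"].to_numpy(float)
        incidence_smoker[(d, sex)] = grp["incidence_smoker"].to_numpy(float)
        case_fatality[(d, sex)] = grp["case_fatality"].to_numpy(float)
    background_mortality = {
        sex: grp.sort_values("age")["background_mortality"].to_numpy(float)
        for sex, grp in mortality.groupby("sex", sort=False)
    }
    decay_fraction = {
        d: grp.sort_values("t_since_quit")["fraction"].to_numpy(float)
        for d, grp in decay.groupby("disease", sort=False)
    }
    disease_cost = {d: float(scalars[("disease_cost", d)]) for d in diseases}
    utility = {
        s: float(scalars[("utility", s)]) for s in ("well", "dead", *diseases)
    }
    return ModelParameters(
        age_min=age_min,
        max_age=max_age,
        discount_rate=discount_rate,
        incidence_never=incidence_never,
        incidence_smoker=incidence_smoker,
        case_fatality=case_fatality,
        background_mortality=background_mortality,
        decay_fraction=decay_fraction,
        disease_cost=disease_cost,
        utility=utility,
        diseases=diseases,
    )
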