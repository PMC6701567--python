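"""Logistic abstinence model: prediction, odds ratios, fitting and simulation.

Individual records are coded programme 1=high-intensity (HIT) / 0=low-
intensity (LIT), gender 1=male / 0=female, age in years.  The published
trial coefficients are packaged as a fixture and available via
:func:`trial_model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .parameters import load_fixture_table

__all__ = [
    "AGE_RANGE",
    "AbstinenceModel",
    "FittingError",
    "trial_model",
    "linear_predictor",
    "abstinence_probability",
    "odds_ratio",
    "fit_abstinence_model",
    "simulate_trial",
    "write_model",
    "read_model",
]

AGE_RANGE = (19, 71)  # trial inclusion ages; prediction outside warns
_TERMS = ("intercept", "programme", "gender", "age")


class FittingError(RuntimeError):
    """Raised when the logistic fit is degenerate or fails to converge."""


@dataclass(frozen=True)
class AbstinenceModel:
    """Logit-scale coefficients for sustained abstinence.

    ``standard_errors`` (keyed by term name) is present on fitted models and
    enables Wald confidence intervals for odds ratios.
    """

    intercept: float
    beta_programme: float
    beta_gender: float
    beta_age: float
    standard_errors: dict[str, float] | None = field(default=None, compare=False)

    def coefficient(self, term: str) -> float:
        if term not in _TERMS:
            raise KeyError(f"unknown term {term!r}; expected one of {_TERMS}")
        return {
            "intercept": self.intercept,
            "programme": self.beta_programme,
            "gender": self.beta_gender,
            "age": self.beta_age,
        }[term]


def trial_model() -> AbstinenceModel:
    """The published trial's fitted coefficients, loaded from the fixture table."""
    tab = load_fixture_table("table2_logistic").set_index("term")["coefficient"]
    return AbstinenceModel(
        intercept=float(tab["intercept"]),
        beta_programme=float(tab["programme"]),
        beta_gender=float(tab["gender"]),
        beta_age=float(tab["age"]),
    )


def linear_predictor(model: AbstinenceModel, programme, gender, age):
    """Logit of the abstinence probability; vectorised over the inputs."""
    age = np.asarray(age, dtype=float)
    if np.any(age < AGE_RANGE[0]) or np.any(age > AGE_RANGE[1]):
        warnings.warn(
            f"age outside the fitted range {AGE_RANGE}; extrapolating", stacklevel=2
        )
    out = (
        model.intercept
        + model.beta_programme * np.asarray(programme, dtype=float)
        + model.beta_gender * np.asarray(gender, dtype=float)
        + model.beta_age * age
    )
    return float(out) if out.ndim == 0 else out


def abstinence_probability(logit):
    """Inverse-logit transform, strictly inside (0, 1)."""
    p = expit(np.asarray(logit, dtype=float))
    return float(p) if p.ndim == 0 else p


def odds_ratio(
    model: AbstinenceModel, term: str, *, z: float = 1.96
) -> tuple[float, tuple[float, float] | None]:
    """``exp(coefficient)`` for ``term`` plus a Wald CI when an SE is available."""
    beta = model.coefficient(term)
    ci = None
    if model.standard_errors and term in model.standard_errors:
        se = model.standard_errors[term]
        ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    return float(np.exp(beta)), ci


def fit_abstinence_model(records: pd.DataFrame) -> AbstinenceModel:
    """Maximum-likelihood logistic fit of abstinence on programme, gender and age.

    ``records`` needs columns programme, gender, age, abstinent with the
    module's codings.  Raises :class:`FittingError` on separation-like
    degeneracy or non-convergence.
    """
    required = {"programme", "gender", "age", "abstinent"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    y = records["abstinent"].to_numpy(dtype=float)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise FittingError(
            "degenerate outcomes: need at least 2 records in each abstinence class "
            f"(got {counts.to_dict()})"
        )
    X = sm.add_constant(records[["programme", "gender", "age"]].astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            result = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # statsmodels raises several error types here
        raise FittingError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise FittingError("logistic fit did not converge")
    if np.any(np.abs(result.params.to_numpy()) > 50):
        raise FittingError("coefficients diverged; data are likely separated")
    params = result.params
    bse = result.bse
    name_map = {"const": "intercept", "programme": "programme", "gender": "gender", "age": "age"}
    ses = {name_map[k]: float(v) for k, v in bse.items()}
    return AbstinenceModel(
        intercept=float(params["const"]),
        beta_programme=float(params["programme"]),
        beta_gender=float(params["gender"]),
        beta_age=float(params["age"]),
        standard_errors=ses,
    )


def simulate_trial(
    n_per_arm: int,
    model: AbstinenceModel,
    seed: int,
    *,
    age_mean: float = 48.6,
    age_sd: float = 10.0,
    female_fraction: float = 0.78,
    age_range: tuple[float, float] = AGE_RANGE,
) -> pd.DataFrame:
    """Draw a synthetic two-arm trial with Bernoulli abstinence outcomes.

    Ages are normal(age_mean, age_sd) truncated to ``age_range`` by
    resampling; gender is Bernoulli(1 - female_fraction) for male.  The same
    simulated participants are assigned to each arm position-wise apart from
    the programme code, which keeps arm covariate distributions exchangeable.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for programme in (0, 1):
        age = _truncated_normal(rng, age_mean, age_sd, age_range, n_per_arm)
        gender = (rng.random(n_per_arm) >= female_fraction).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = abstinence_probability(
                linear_predictor(model, programme, gender, age)
            )
        abstinent = (rng.random(n_per_arm) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "programme": programme,
                    "gender": gender,
                    "age": np.round(age).astype(int),
                    "abstinent": abstinent,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _truncated_normal(rng, mean, sd, bounds, n) -> np.ndarray:
    lo, hi = bounds
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def write_model(model: AbstinenceModel, path) -> None:
    """Serialise coefficients (and SEs when present) to a small CSV."""
    rows = [
        {"term": t, "coefficient": model.coefficient(t)} for t in _TERMS
    ]
    if model.standard_errors:
        for row in rows:
            row["standard_error"] = model.standard_errors.get(row["term"], np.nan)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_model(path) -> AbstinenceModel:
    tab = pd.read_csv(path).set_index("term")
    ses = None
    if "standard_error" in tab.columns:
        ses = {t: float(tab.loc[t, "standard_error"]) for t in _TERMS}
    return AbstinenceModel(
        intercept=float(tab.loc["intercept", "coefficient"]),
        beta_programme=float(tab.loc["programme", "coefficient"]),
        beta_gender=float(tab.loc["gender", "coefficient"]),
        beta_age=float(tab.loc["age", "coefficient"]),
        standard_errors=ses,
    )
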