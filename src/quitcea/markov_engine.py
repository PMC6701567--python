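"""Annual-cycle cohort model of smoking-attributable disease.

States: well, one absorbing-except-death state per disease, dead.  A cohort
of one smoking status (lifelong smoker, or quitter with time-decaying excess
risk) is propagated from its start age to the horizon, accumulating
discounted societal costs and QALYs.  Differencing smoker and quitter runs
yields the per-person benefit of quitting.

Conventions (documented choices, not derivable from the data):
no half-cycle correction — costs and utilities accrue at cycle start;
first incident disease wins, with competing incident risks allocated
proportionally if they would exceed the cycle budget; the quitter clock
starts at the cohort start age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import SEXES, ModelParameters

__all__ = [
    "CohortProfile",
    "LifetimeOutcome",
    "QuitBenefit",
    "discount_factor",
    "transition_matrix",
    "simulate_cohort",
    "quit_benefit",
    "quit_benefit_sweep",
]

_OCC_TOL = 1e-9


@dataclass(frozen=True)
class CohortProfile:
    """A (sex, start age, smoking status) cohort definition."""

    sex: str
    start_age: int
    status: str  # "smoker" or "quitter"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.status not in ("smoker", "quitter"):
            raise ValueError(f"status must be 'smoker' or 'quitter', got {self.status!r}")


@dataclass
class LifetimeOutcome:
    """Discounted totals plus the per-cycle state-occupancy trace."""

    discounted_cost: float
    discounted_qalys: float
    occupancy_trace: pd.DataFrame  # index: age at cycle start; columns: states


@dataclass(frozen=True)
class QuitBenefit:
    """Per-person differences: smoker cost minus quitter cost, quitter QALYs minus smoker QALYs."""

    costs_avoided: float
    qalys_gained: float


def discount_factor(year_index: int, rate: float) -> float:
    """``(1 + rate) ** -year_index`` with year 0 undiscounted."""
    if year_index < 0:
        raise ValueError(f"year_index must be >= 0, got {year_index}")
    return float((1.0 + rate) ** (-year_index))


def transition_matrix(
    profile: CohortProfile, params: ModelParameters, cycle: int
) -> np.ndarray:
    """One-cycle transition matrix for ``cycle`` years after start.

    Rows/columns follow ``["well", *params.diseases, "dead"]``.  From the
    well state, death from background causes takes priority; surviving
    cohort members split between incident disease states and staying well.
    Disease states exit only to death, combining cause-specific fatality
    with background mortality.
    """
    age = profile.start_age + cycle
    i = age - params.age_min
    diseases = params.diseases
    n_states = len(diseases) + 2
    m = float(params.background_mortality[profile.sex][i])

    inc = np.empty(len(diseases))
    for j, d in enumerate(diseases):
        never = params.incidence_never[(d, profile.sex)][i]
        smoker = params.incidence_smoker[(d, profile.sex)][i]
        if profile.status == "smoker":
            inc[j] = smoker
        else:
            inc[j] = never + params.decay(d, cycle) * (smoker - never)
    total = inc.sum()
    if total > 1.0:  # proportional allocation when incident risks compete
        inc *= 1.0 / total
        total = 1.0

    P = np.zeros((n_states, n_states))
    P[0, -1] = m
    P[0, 1:-1] = (1.0 - m) * inc
    P[0, 0] = (1.0 - m) * (1.0 - total)
    for j, d in enumerate(diseases):
        cf = float(params.case_fatality[(d, profile.sex)][i])
        p_die = 1.0 - (1.0 - cf) * (1.0 - m)
        P[1 + j, -1] = p_die
        P[1 + j, 1 + j] = 1.0 - p_die
    P[-1, -1] = 1.0

    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise RuntimeError(f"transition rows do not sum to 1: {rows}")
    return P


def simulate_cohort(profile: CohortProfile, params: ModelParameters) -> LifetimeOutcome:
    """Propagate the cohort annually from ``start_age`` to ``params.max_age``.

    Costs and utilities accrue at the start of each cycle (ages
    ``start_age .. max_age-1``) and are discounted by whole years since
    start; the trace additionally records occupancy at the horizon.
    """
    params.validate()
    if not (params.age_min <= profile.start_age < params.max_age):
        raise ValueError(
            f"start_age {profile.start_age} outside [{params.age_min}, {params.max_age})"
        )
    diseases = params.diseases
    states = ["well", *diseases, "dead"]
    state_cost = np.array([0.0, *(params.disease_cost[d] for d in diseases), 0.0])
    state_util = np.array(
        [params.utility["well"], *(params.utility[d] for d in diseases), 0.0]
    )

    n_cycles = params.max_age - profile.start_age
    occ = np.zeros(len(states))
    occ[0] = 1.0
    trace = np.empty((n_cycles + 1, len(states)))
    cost = 0.0
    qalys = 0.0
    for t in range(n_cycles):
        trace[t] = occ
        df = discount_factor(t, params.discount_rate)
        cost += df * float(occ @ state_cost)
        qalys += df * float(occ @ state_util)
        occ = occ @ transition_matrix(profile, params, t)
        if abs(occ.sum() - 1.0) > _OCC_TOL:
            raise RuntimeError(f"occupancy not conserved at cycle {t}: sum={occ.sum()}")
    trace[n_cycles] = occ

    trace_df = pd.DataFrame(
        trace,
        index=pd.Index(
            range(profile.start_age, params.max_age + 1), name="age"
        ),
        columns=states,
    )
    return LifetimeOutcome(
        discounted_cost=cost, discounted_qalys=qalys, occupancy_trace=trace_df
    )


def quit_benefit(sex: str, start_age: int, params: ModelParameters) -> QuitBenefit:
    """Discounted per-person societal costs avoided and QALYs gained by quitting at ``start_age``."""
    smoker = simulate_cohort(CohortProfile(sex, start_age, "smoker"), params)
    quitter = simulate_cohort(CohortProfile(sex, start_age, "quitter"), params)
    return QuitBenefit(
        costs_avoided=smoker.discounted_cost - quitter.discounted_cost,
        qalys_gained=quitter.discounted_qalys - smoker.discounted_qalys,
    )


def quit_benefit_sweep(
    params: ModelParameters,
    band_width: int = 5,
    age_start: int = 20,
    age_stop: int = 70,
) -> pd.DataFrame:
    """Per-person quit benefits by sex and 5-year age band (band midpoint run).

    Returns a frame with columns (sex, age_group, costs_avoided, qalys_gained),
    the shape used downstream for group-wise aggregation.
    """
    rows = []
    for sex in SEXES:
        for lo in range(age_start, age_stop, band_width):
            hi = lo + band_width - 1
            mid = (lo + hi) // 2
            qb = quit_benefit(sex, mid, params)
            rows.append(
                {
                    "sex": sex,
                    "age_group": f"{lo}-{hi}",
                    "costs_avoided": qb.costs_avoided,
                    "qalys_gained": qb.qalys_gained,
                }
            )
    return pd.DataFrame(rows)
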