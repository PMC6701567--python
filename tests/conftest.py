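import numpy as np
import pytest

from quitcea import parameters as par


@pytest.fixture(scope="session")
def synth_params():
    return par.generate_synthetic_parameters(1)


@pytest.fixture(scope="session")
def trial_model():
    from quitcea import effectiveness as eff

    return eff.trial_model()


def make_toy_params(
    *,
    diseases=("copd",),
    age_min=60,
    max_age=63,
    incidence_never=0.0,
    incidence_smoker=0.0,
    case_fatality=0.0,
    background_mortality=0.0,
    decay=None,
    disease_cost=0.0,
    utility_well=1.0,
    utility_disease=0.5,
    discount_rate=0.0,
):
    """Hand-built minimal parameter set for closed-form and oracle tests.

    Scalar inputs are broadcast over all ages/sexes/diseases; ``decay`` is a
    full per-year array when given, else all ones.
    """
    n = max_age - age_min

    def arr(x):
        return np.full(n, float(x))

    sexes = ("female", "male")
    if decay is None:
        decay = np.ones(n)
    return par.ModelParameters(
        age_min=age_min,
        max_age=max_age,
        discount_rate=discount_rate,
        incidence_never={(d, s): arr(incidence_never) for d in diseases for s in sexes},
        incidence_smoker={(d, s): arr(incidence_smoker) for d in diseases for s in sexes},
        case_fatality={(d, s): arr(case_fatality) for d in diseases for s in sexes},
        background_mortality={s: arr(background_mortality) for s in sexes},
        decay_fraction={d: np.asarray(decay, dtype=float) for d in diseases},
        disease_cost={d: float(disease_cost) for d in diseases},
        utility={"well": utility_well, "dead": 0.0, **{d: utility_disease for d in diseases}},
        diseases=tuple(diseases),
    )


def enumerate_lifetime(matrices, cost_by_state, utility_by_state, rate, start_state=0):
    """Brute-force expectation over every state path of a finite chain.

    ``matrices`` holds one transition matrix per cycle; rewards accrue at
    cycle start (before the transition) discounted by whole cycles.  This is
    the independent oracle for the matrix cohort engine: it never multiplies
    occupancy vectors, it sums path probabilities.
    """
    n_cycles = len(matrices)
    totals = {"cost": 0.0, "qalys": 0.0}

    def visit(state, cycle, prob):
        df = (1.0 + rate) ** (-cycle)
        totals["cost"] += prob * cost_by_state[state] * df
        totals["qalys"] += prob * utility_by_state[state] * df
        if cycle == n_cycles - 1:
            return
        row = matrices[cycle][state]
        for nxt, p in enumerate(row):
            if p > 0.0:
                visit(nxt, cycle + 1, prob * p)

    visit(start_state, 0, 1.0)
    return totals["cost"], totals["qalys"]
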