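"""Incremental cost-effectiveness layer.

Combines programme delivery costs, group-wise abstinence differentials and
per-person quit benefits into incremental costs, incremental QALYs and an
ICER (or a dominance flag when the intervention is both cheaper and more
effective).  Currency is rounded to whole euro at reporting only; internal
arithmetic is unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effectiveness import AbstinenceModel, abstinence_probability, linear_predictor
from .parameters import load_fixture_table

__all__ = [
    "InterventionCosts",
    "GroupDifferential",
    "IncrementalResult",
    "intervention_costs_from_fixture",
    "aggregate_benefits",
    "sum_group_differences",
    "differentials_from_counts",
    "incremental_analysis",
    "incremental_from_difference",
    "intervention_cost_difference",
    "quit_probability_difference",
    "per_person_cea",
    "adjust_costs",
]


@dataclass(frozen=True)
class InterventionCosts:
    """Programme-specific delivery cost and its per-participant share."""

    programme: str
    total_specific_cost: float
    n_participants: int

    @property
    def per_participant_cost(self) -> int:
        return int(round(self.total_specific_cost / self.n_participants))


@dataclass(frozen=True)
class GroupDifferential:
    """Abstinent-count difference (HIT minus LIT) for one sex/age group."""

    sex: str
    age_group: str
    n_hit: int
    n_lit: int

    @property
    def n_diff(self) -> int:
        return self.n_hit - self.n_lit


@dataclass(frozen=True)
class IncrementalResult:
    """One column of an incremental CEA table.

    ``icer`` is euro per QALY when defined; ``dominant`` marks strategies
    that save costs while gaining QALYs (displayed ``<0``, never as a
    negative ratio); ``undefined`` marks a nonzero net cost with zero QALY
    difference.
    """

    delta_intervention_cost: float
    societal_costs_avoided: float
    incremental_qalys: float
    icer: float | None
    dominant: bool = False
    undefined: bool = False

    @property
    def incremental_net_cost(self) -> float:
        return self.delta_intervention_cost - self.societal_costs_avoided

    def icer_display(self, digits: int = 0) -> str:
        if self.dominant:
            return "<0"
        if self.undefined:
            return "undefined"
        return f"{round(self.icer, digits):g}" if digits else f"{round(self.icer)}"

    def rounded(self) -> dict:
        """Reporting view: whole euro, QALYs to 2 d.p., ICER in euro/QALY."""
        return {
            "intervention_cost_diff": round(self.delta_intervention_cost),
            "societal_costs_avoided": round(self.societal_costs_avoided),
            "incremental_cost": round(self.incremental_net_cost),
            "incremental_qalys": round(self.incremental_qalys, 2),
            "icer": self.icer_display(),
        }


def intervention_costs_from_fixture() -> dict[str, InterventionCosts]:
    tab = load_fixture_table("intervention_costs")
    return {
        row.programme: InterventionCosts(
            programme=row.programme,
            total_specific_cost=float(row.total_specific_cost),
            n_participants=int(row.n_participants),
        )
        for row in tab.itertuples()
    }


def aggregate_benefits(
    differentials, benefits: pd.DataFrame
) -> tuple[float, float]:
    """Sum ``n_diff``-weighted per-person benefits over sex/age groups.

    ``differentials`` is an iterable of :class:`GroupDifferential`;
    ``benefits`` a frame with columns (sex, age_group, costs_avoided,
    qalys_gained).  Groups present in only one arm contribute via the sign
    of ``n_diff``.  A differential whose group is missing from ``benefits``
    raises ``KeyError`` naming it.
    """
    lut = benefits.set_index(["sex", "age_group"])
    total_cost = 0.0
    total_qalys = 0.0
    for g in differentials:
        key = (g.sex, g.age_group)
        try:
            row = lut.loc[key]
        except KeyError:
            raise KeyError(f"no per-person benefit for group {key}") from None
        total_cost += g.n_diff * float(row["costs_avoided"])
        total_qalys += g.n_diff * float(row["qalys_gained"])
    return total_cost, total_qalys


def sum_group_differences(horizon: str) -> tuple[float, float]:
    """Total costs avoided and QALYs gained from the published group-difference cells.

    The published group cells were computed from unrounded per-person
    values, so their sums reproduce the published totals where multiplying
    rounded per-person fixtures by count differences can drift by a few
    euro / 0.01 QALY.
    """
    tab = load_fixture_table("table3_group_differences")
    sel = tab[tab["horizon"] == horizon]
    if sel.empty:
        raise KeyError(f"unknown horizon {horizon!r}; expected 'short' or 'long'")
    return float(sel["costs"].sum()), float(sel["qalys"].sum())


def differentials_from_counts(horizon: str) -> list[GroupDifferential]:
    """Group differentials from the published abstinence-count table."""
    if horizon not in ("short", "long"):
        raise KeyError(f"unknown horizon {horizon!r}; expected 'short' or 'long'")
    tab = load_fixture_table("table3_counts")
    return [
        GroupDifferential(
            sex=row.sex,
            age_group=row.age_group,
            n_hit=int(getattr(row, f"n_hit_{horizon}")),
            n_lit=int(getattr(row, f"n_lit_{horizon}")),
        )
        for row in tab.itertuples()
    ]


def incremental_analysis(
    cost_hit: float, cost_lit: float, avoided: float, qalys: float
) -> IncrementalResult:
    """Build the incremental column from per-arm intervention costs.

    Note: the published per-arm totals are individually rounded to whole
    euro, so their difference can sit €1 below the published difference
    cell; :func:`incremental_from_difference` accepts the difference
    directly when reproducing published cells.
    """
    return incremental_from_difference(cost_hit - cost_lit, avoided, qalys)


def incremental_from_difference(
    delta: float, avoided: float, qalys: float
) -> IncrementalResult:
    """Incremental column from an intervention-cost difference and modelled benefits."""
    net = delta - avoided
    dominant = False
    undefined = False
    icer: float | None
    if qalys > 0:
        # net == 0 with positive QALYs reports ICER 0; only strictly
        # cost-saving strategies carry the "<0" dominance flag
        if net < 0:
            dominant = True
            icer = None
        else:
            icer = net / qalys
    elif qalys < 0:
        if net < 0:
            icer = net / qalys  # south-west quadrant: ratio is meaningful
        else:
            icer = None
            undefined = True
    else:
        if net == 0:
            icer = 0.0
        else:
            icer = None
            undefined = True
    return IncrementalResult(
        delta_intervention_cost=delta,
        societal_costs_avoided=avoided,
        incremental_qalys=qalys,
        icer=icer,
        dominant=dominant,
        undefined=undefined,
    )


def intervention_cost_difference() -> float:
    """Published HIT-minus-LIT intervention-cost difference cell.

    Kept as a fixture value rather than recomputed because the per-arm
    totals are rounded independently and differ by €1 from this cell.
    """
    tab = load_fixture_table("table4").set_index(["scenario", "field"])["value"]
    return float(tab[("short", "intervention_cost_diff")])


def quit_probability_difference(
    model: AbstinenceModel, gender: int, age
) -> float:
    """Mean HIT-minus-LIT abstinence-probability difference over ``age`` (scalar or array)."""
    p_hit = abstinence_probability(linear_predictor(model, 1, gender, age))
    p_lit = abstinence_probability(linear_predictor(model, 0, gender, age))
    return float(np.mean(p_hit - p_lit))


def per_person_cea(
    per_participant_cost_diff: float,
    per_person_benefit: tuple[float, float],
    *,
    probability_difference: float | None = None,
    model: AbstinenceModel | None = None,
    gender: int | None = None,
    age=None,
) -> IncrementalResult:
    """Population-level per-person incremental analysis.

    The HIT-minus-LIT abstinence-probability difference scales the
    per-quitter benefit ``(costs avoided €, QALYs)``; the result is offset
    against the per-participant intervention-cost difference.  Supply either
    ``probability_difference`` directly or ``model``/``gender``/``age`` to
    compute it from the logistic layer.
    """
    if probability_difference is None:
        if model is None or gender is None or age is None:
            raise ValueError(
                "need either probability_difference or (model, gender, age)"
            )
        probability_difference = quit_probability_difference(model, gender, age)
    costs_pp, qalys_pp = per_person_benefit
    avoided = probability_difference * costs_pp
    qalys = probability_difference * qalys_pp
    return incremental_from_difference(per_participant_cost_diff, avoided, qalys)


def adjust_costs(amount: float, cpi_ratio: float, ppp_rate: float) -> float:
    """Inflate then currency-convert: ``amount × cpi_ratio × ppp_rate``."""
    if cpi_ratio <= 0 or ppp_rate <= 0:
        raise ValueError("cpi_ratio and ppp_rate must be positive")
    return amount * cpi_ratio * ppp_rate
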