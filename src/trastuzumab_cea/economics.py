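"""Discounted costs, life-years and QALYs from a cohort trace, and
incremental comparison of two strategies.

Reward conventions
------------------
No half-cycle correction is applied.  State-membership rewards (life-years,
utilities, follow-up and metastatic annual costs, the loco-regional episode
cost) accrue at cycle start on the start-of-cycle occupancy; one-off
treatment costs land in cycle 1 on the full cohort.  Cycle ``c`` is
discounted by ``(1+r)**-(c-1)`` — cycle-1 events are undiscounted, so the
trastuzumab acquisition cost enters the incremental comparison at face
value.  Because the loco-regional state lasts exactly one cycle, charging
its episode cost per occupied cycle is the same as charging it per incident
entry, one discount period after entry.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .markov import CohortTrace, HealthState, Strategy
from .parameters import (CostParameters, EconomicSettings, ParameterSet,
                         UtilityParameters)

__all__ = [
    "StrategyOutcome",
    "Dominance",
    "ICERResult",
    "discount_factor",
    "accumulate_rewards",
    "evaluate_strategy",
    "compute_icer",
    "ce_verdict",
]


def discount_factor(cycle: int, rate: float) -> float:
    """Present-value factor for cycle ``cycle`` (1-based): (1+r)^-(cycle-1)."""
    if cycle < 1:
        raise ValueError("cycle index is 1-based")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-(cycle - 1))


@dataclass(frozen=True)
class StrategyOutcome:
    """Total (per-patient expected) cost, life-years and QALYs of one arm."""

    strategy: Strategy
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


def accumulate_rewards(trace: CohortTrace, costs: CostParameters,
                       utilities: UtilityParameters,
                       settings: EconomicSettings) -> StrategyOutcome:
    """Fold a cohort trace into discounted and undiscounted totals."""
    s = HealthState
    horizon = trace.occupancy.shape[0] - 1
    cost_d = ly_d = qaly_d = 0.0
    cost_u = ly_u = qaly_u = 0.0
    chf = trace.chf_fraction

    for c in range(1, horizon + 1):
        occ = trace.occupancy[c - 1]
        df_c = discount_factor(c, settings.discount_rate_costs)
        df_e = discount_factor(c, settings.discount_rate_effects)

        alive = 1.0 - occ[s.DEAD]

        u_dfs = utilities.u_dfs
        if c == 1:
            # Adjuvant-treatment cycle: treatment utility in both arms, with
            # the CHF fraction at the heart-failure weight instead.
            u_dfs = (1.0 - chf) * utilities.u_treatment + chf * utilities.u_chf
        q = (occ[s.DFS] * u_dfs
             + occ[s.LOCAL] * utilities.u_local
             + occ[s.METASTATIC] * utilities.u_metastatic
             + occ[s.DEAD] * utilities.u_death)

        cost = 0.0
        if c == 1:
            cost += costs.act_regimen_total
            if trace.strategy is Strategy.ACTH:
                cost += costs.trastuzumab_drug + costs.trastuzumab_admin
            cost += chf * costs.chf_episode
        if c <= costs.dfs_followup_years:
            cost += costs.dfs_followup_annual * occ[s.DFS]
        cost += costs.locoregional_episode * occ[s.LOCAL]
        cost += costs.metastatic_annual * occ[s.METASTATIC]

        ly_u += alive
        qaly_u += q
        cost_u += cost
        ly_d += alive * df_e
        qaly_d += q * df_e
        cost_d += cost * df_c

    return StrategyOutcome(strategy=trace.strategy,
                           cost=float(cost_d), ly=float(ly_d),
                           qaly=float(qaly_d),
                           cost_undiscounted=float(cost_u),
                           ly_undiscounted=float(ly_u),
                           qaly_undiscounted=float(qaly_u))


def evaluate_strategy(strategy: Strategy, params: ParameterSet,
                      life_table) -> StrategyOutcome:
    """Convenience: run the cohort and accumulate rewards in one call."""
    from .markov import run_cohort
    trace = run_cohort(strategy, params, life_table)
    return accumulate_rewards(trace, params.costs, params.utilities,
                              params.economics)


class Dominance(enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention dominant"
    INTERVENTION_DOMINATED = "intervention dominated"


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of intervention vs comparator.

    ``icer_per_qaly``/``icer_per_ly`` are NaN when the ratio is not
    meaningful (dominance, or a zero effect difference); check
    ``icer_defined``.
    """

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float
    icer_per_ly: float
    icer_defined: bool
    dominance: Dominance
    cost_effective_at_threshold: bool
    threshold: float


_EPS = 1e-12


def compute_icer(intervention: StrategyOutcome, comparator: StrategyOutcome,
                 settings: EconomicSettings) -> ICERResult:
    """Incremental cost-effectiveness of ``intervention`` over ``comparator``.

    The ratio is reported only in the trade-off quadrant (costlier and more
    effective).  A dominant intervention (cheaper, at least as effective) is
    cost-effective at any threshold; a dominated one at none.  An ICER
    exactly at the threshold counts as cost-effective.
    """
    dc = intervention.cost - comparator.cost
    dq = intervention.qaly - comparator.qaly
    dly = intervention.ly - comparator.ly

    if abs(dc) < _EPS and abs(dq) < _EPS:
        dominance = Dominance.NONE
    elif dc <= _EPS and dq >= -_EPS:
        dominance = Dominance.INTERVENTION_DOMINANT
    elif dc >= -_EPS and dq <= _EPS:
        dominance = Dominance.INTERVENTION_DOMINATED
    else:
        dominance = Dominance.NONE

    defined = dq > _EPS and dc > _EPS
    icer_q = dc / dq if defined else math.nan
    icer_l = dc / dly if defined and dly > _EPS else math.nan

    if dominance is Dominance.INTERVENTION_DOMINANT:
        ce = True
    elif dominance is Dominance.INTERVENTION_DOMINATED:
        ce = False
    else:
        ce = defined and icer_q <= settings.wtp_threshold

    return ICERResult(delta_cost=dc, delta_qaly=dq, delta_ly=dly,
                      icer_per_qaly=icer_q, icer_per_ly=icer_l,
                      icer_defined=defined, dominance=dominance,
                      cost_effective_at_threshold=ce,
                      threshold=settings.wtp_threshold)


def ce_verdict(result: ICERResult, threshold: float | None = None
               ) -> tuple[bool, str]:
    """Boolean cost-effectiveness verdict plus a human-readable line."""
    thr = result.threshold if threshold is None else threshold
    if result.dominance is Dominance.INTERVENTION_DOMINANT:
        return True, f"intervention dominates: cost-effective at any threshold (threshold {thr:,.0f} USD/QALY)"
    if result.dominance is Dominance.INTERVENTION_DOMINATED:
        return False, f"intervention dominated: not cost-effective at any threshold (threshold {thr:,.0f} USD/QALY)"
    if not result.icer_defined:
        return False, f"ICER undefined (no meaningful difference); not cost-effective at {thr:,.0f} USD/QALY"
    ok = result.icer_per_qaly <= thr
    word = "cost-effective" if ok else "not cost-effective"
    return ok, (f"ICER {result.icer_per_qaly:,.0f} USD/QALY vs threshold "
                f"{thr:,.0f} USD/QALY: {word}")
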