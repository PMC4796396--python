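"""Four-state Markov cohort engine.

States are disease-free survival (DFS), loco-regional recurrence (LOCAL, a
one-cycle episode), distant/metastatic recurrence (METASTATIC, occupied
until death), and DEAD (absorbing).  The cohort starts disease-free at age
50 and is iterated over twenty one-year cycles; a per-cycle transition
matrix is rebuilt each year because background mortality is age-specific
and the recurrence hazard is piecewise in time since treatment.

Congestive heart failure, the principal trastuzumab cardiotoxicity, does
not alter transitions (its excess mortality is zero in this model); it is
carried on the trace as a first-cycle incidence fraction and priced/
weighted by the economics layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .parameters import LifeTable, ParameterSet, ClinicalParameters

__all__ = [
    "HealthState",
    "Strategy",
    "CohortTrace",
    "annual_event_prob_from_cumulative_survival",
    "apply_hazard_ratio",
    "prob_to_rate",
    "rate_to_prob",
    "recurrence_prob",
    "background_death_prob",
    "metastatic_death_prob",
    "build_matrix",
    "transition_matrices",
    "run_cohort",
    "overall_survival",
]


class HealthState(enum.IntEnum):
    DFS = 0
    LOCAL = 1
    METASTATIC = 2
    DEAD = 3


class Strategy(str, enum.Enum):
    """The two compared arms: chemotherapy alone vs chemotherapy + 52 weeks
    of trastuzumab."""

    ACT = "AC-T"
    ACTH = "AC-TH"


N_STATES = len(HealthState)


def annual_event_prob_from_cumulative_survival(S: float, years: int) -> float:
    """Constant annual event probability whose ``years``-fold survival is S.

    Solves (1-p)**years = S, i.e. ``p = 1 - S**(1/years)``.
    """
    if not 0.0 < S <= 1.0:
        raise ValueError("cumulative survival must lie in (0, 1]")
    if years < 1:
        raise ValueError("years must be >= 1")
    return 1.0 - S ** (1.0 / years)


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale an annual event probability by a hazard ratio on the hazard
    scale: ``1 - (1-p)**hr``.

    Equivalent to multiplying the instantaneous rate by ``hr`` and
    converting back; exact under constant hazards within the cycle, and the
    convention under which a 5-year disease-free survival of 0.75 maps to
    0.75**0.64 ≈ 0.832 under a hazard ratio of 0.64.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must lie in [0, 1)")
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return 1.0 - (1.0 - p) ** hr


def prob_to_rate(p: float) -> float:
    """Annual probability → instantaneous rate, ``-ln(1-p)``."""
    if not 0.0 <= p < 1.0:
        raise ValueError("probability must lie in [0, 1)")
    return -math.log1p(-p)


def rate_to_prob(r: float) -> float:
    """Instantaneous rate → annual probability, ``1 - exp(-r)``."""
    if r < 0:
        raise ValueError("rate must be >= 0")
    return -math.expm1(-r)


def recurrence_prob(cycle: int, strategy: Strategy,
                    clinical: ClinicalParameters) -> float:
    """Annual probability of any recurrence from DFS during ``cycle``.

    Cycles 1–5 derive from the trial's cumulative 5-year disease-free
    survival in the chemotherapy arm, with the trastuzumab hazard ratio
    applied while the benefit lasts; cycles 6–9, 10–14 and 15–20 use the
    pooled annual recurrence rates by time band (treated as annual
    probabilities), with the post-benefit hazard ratio (default 1).
    """
    if not 1 <= cycle <= clinical.horizon:
        raise ValueError(f"cycle {cycle} outside 1..{clinical.horizon}")
    if cycle <= clinical.benefit_duration:
        p = annual_event_prob_from_cumulative_survival(
            clinical.p_dfs_5y_act, clinical.benefit_duration)
        hr = clinical.hr_dfs
    else:
        if cycle <= 9:
            p = clinical.recur_rate_y5_9
        elif cycle <= 14:
            p = clinical.recur_rate_y10_14
        else:
            p = clinical.recur_rate_y15plus
        hr = clinical.hr_post_benefit
    if strategy is Strategy.ACTH and hr != 1.0:
        p = apply_hazard_ratio(p, hr)
    return p


def background_death_prob(age: int, life_table: LifeTable) -> float:
    """Age-specific annual probability of death from other causes."""
    return life_table.lookup(age)


def metastatic_death_prob(clinical: ClinicalParameters) -> float:
    """Annual probability of breast-cancer death from the metastatic state.

    The published 0.328 is used directly as an annual probability; with
    ``metastatic_death_is_rate`` it is instead read as an instantaneous
    rate and converted (→ 0.2796).
    """
    if clinical.metastatic_death_is_rate:
        return rate_to_prob(clinical.metastatic_death_rate)
    return clinical.metastatic_death_rate


def build_matrix(cycle: int, strategy: Strategy, params: ParameterSet,
                 life_table: LifeTable) -> np.ndarray:
    """Row-stochastic 4×4 transition matrix for one cycle and strategy.

    Background death is applied first in the DFS and LOCAL rows, with
    disease transitions competing among survivors; in the METASTATIC row
    disease and background mortality combine multiplicatively
    (``1-(1-p_bc)(1-q)``).  Rows therefore sum to one by construction.
    """
    clin = params.clinical
    age = clin.start_age + cycle - 1
    q = background_death_prob(age, life_table)
    p_rec = recurrence_prob(cycle, strategy, clin)
    p_bc = metastatic_death_prob(clin)

    m = np.zeros((N_STATES, N_STATES))
    s = HealthState

    # DFS: die of other causes, else recur (split local/distant), else stay.
    m[s.DFS, s.DEAD] = q
    m[s.DFS, s.LOCAL] = (1 - q) * p_rec * clin.frac_locoregional
    m[s.DFS, s.METASTATIC] = (1 - q) * p_rec * (1 - clin.frac_locoregional)
    m[s.DFS, s.DFS] = 1.0 - m[s.DFS, 1:].sum()

    # LOCAL is a one-cycle episode: survivors exit to DFS or METASTATIC.
    m[s.LOCAL, s.DEAD] = q
    m[s.LOCAL, s.METASTATIC] = (1 - q) * clin.local_to_metastatic_annual
    m[s.LOCAL, s.DFS] = (1 - q) * (1 - clin.local_to_metastatic_annual)

    # METASTATIC: until-death state; competing disease/background mortality.
    m[s.METASTATIC, s.DEAD] = 1.0 - (1 - p_bc) * (1 - q)
    m[s.METASTATIC, s.METASTATIC] = 1.0 - m[s.METASTATIC, s.DEAD]

    m[s.DEAD, s.DEAD] = 1.0

    if np.any((m < -1e-15) | (m > 1 + 1e-15)):
        raise ValueError(f"inconsistent parameters: transition probability "
                         f"outside [0,1] at cycle {cycle}")
    return m


def transition_matrices(strategy: Strategy, params: ParameterSet,
                        life_table: LifeTable) -> list[np.ndarray]:
    """Matrices for cycles 1..horizon, in order."""
    return [build_matrix(c, strategy, params, life_table)
            for c in range(1, params.clinical.horizon + 1)]


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy of one strategy's cohort.

    ``occupancy[t]`` is the distribution over (DFS, LOCAL, METASTATIC,
    DEAD) after ``t`` completed cycles; row 0 is the initial (1,0,0,0).
    ``chf_fraction`` is the strategy's first-cycle congestive-heart-failure
    incidence, carried here for the economics layer.
    """

    strategy: Strategy
    occupancy: np.ndarray  # shape (horizon+1, 4)
    chf_fraction: float


def run_cohort(strategy: Strategy, params: ParameterSet,
               life_table: LifeTable) -> CohortTrace:
    """Iterate the cohort distribution over the full horizon."""
    clin = params.clinical
    occ = np.zeros((clin.horizon + 1, N_STATES))
    occ[0, HealthState.DFS] = 1.0
    for cycle in range(1, clin.horizon + 1):
        m = build_matrix(cycle, strategy, params, life_table)
        occ[cycle] = occ[cycle - 1] @ m
    chf = (clin.chf_incidence_acth if strategy is Strategy.ACTH
           else clin.chf_incidence_act)
    return CohortTrace(strategy=strategy, occupancy=occ, chf_fraction=chf)


def overall_survival(trace: CohortTrace, year: int) -> float:
    """Proportion of the cohort alive after ``year`` completed cycles."""
    horizon = trace.occupancy.shape[0] - 1
    if not 0 <= year <= horizon:
        raise ValueError(f"year {year} outside 0..{horizon}")
    return float(1.0 - trace.occupancy[year, HealthState.DEAD])
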