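"""Tabular and plain-text presentation of model results."""

from __future__ import annotations

import math

import pandas as pd

from .calibration import TornadoRow
from .economics import ICERResult, StrategyOutcome, ce_verdict


def base_case_frame(comparator: StrategyOutcome, intervention: StrategyOutcome,
                    icer: ICERResult) -> pd.DataFrame:
    """Base-case results: one row per outcome, arms and increments as columns."""
    def icer_cell(x: float) -> float:
        return x if icer.icer_defined else math.nan

    return pd.DataFrame(
        {
            comparator.strategy.value: [comparator.cost, comparator.ly,
                                        comparator.qaly],
            intervention.strategy.value: [intervention.cost, intervention.ly,
                                          intervention.qaly],
            "difference": [icer.delta_cost, icer.delta_ly, icer.delta_qaly],
            "ICER (USD)": [math.nan, icer_cell(icer.icer_per_ly),
                           icer_cell(icer.icer_per_qaly)],
        },
        index=["20-year treatment and follow-up costs (USD)",
               "Life years gained (LYs)",
               "Quality-adjusted life years gained (QALYs)"],
    )


def tornado_frame(rows: list[TornadoRow]) -> pd.DataFrame:
    """One-way sensitivity results, one row per varied input."""
    return pd.DataFrame(
        {
            "variable": [r.name for r in rows],
            "icer_lower": [r.icer_at_lower for r in rows],
            "icer_upper": [r.icer_at_upper for r in rows],
            "icer_base": [r.icer_base for r in rows],
            "spread": [r.spread for r in rows],
        }
    )


def base_case_summary(comparator: StrategyOutcome,
                      intervention: StrategyOutcome,
                      icer: ICERResult) -> str:
    """Human-readable base-case report with the cost-effectiveness verdict."""
    _, verdict = ce_verdict(icer)
    lines = [
        "Base-case results (discounted)",
        "-" * 34,
    ]
    for o in (comparator, intervention):
        lines.append(f"{o.strategy.value:6s} cost {o.cost:10,.0f} USD   "
                     f"LY {o.ly:6.2f}   QALY {o.qaly:6.2f}")
    lines += [
        f"Incremental: cost {icer.delta_cost:,.0f} USD, "
        f"LY {icer.delta_ly:.2f}, QALY {icer.delta_qaly:.2f}",
    ]
    if icer.icer_defined:
        lines.append(f"ICER: {icer.icer_per_qaly:,.0f} USD/QALY, "
                     f"{icer.icer_per_ly:,.0f} USD/LY")
    else:
        lines.append(f"ICER: not applicable ({icer.dominance.value})")
    lines.append(verdict)
    return "\n".join(lines)
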