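"""Base-case cost-effectiveness of 12-month adjuvant trastuzumab.

Evaluates both strategies over the 20-year horizon under the calibrated
profile and prints per-arm discounted totals, the incremental results, and
the cost-effectiveness verdict at the 15,000 USD/QALY willingness-to-pay
threshold.
"""

from trastuzumab_cea import (Strategy, calibrated, ce_verdict, compute_icer,
                             evaluate_strategy)
from trastuzumab_cea.report import base_case_summary

params, life_table = calibrated()
act = evaluate_strategy(Strategy.ACT, params, life_table)
acth = evaluate_strategy(Strategy.ACTH, params, life_table)
icer = compute_icer(acth, act, params.economics)

print(base_case_summary(act, acth, icer))
print()
print("Reading: adding 52 weeks of trastuzumab buys about "
      f"{icer.delta_qaly:.2f} quality-adjusted life-years per patient at an "
      f"extra {icer.delta_cost:,.0f} USD, i.e. {icer.icer_per_qaly:,.0f} USD "
      "per QALY - several times the willingness-to-pay threshold, so the "
      "regimen is not cost-effective in this setting.")
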