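"""Fit the model's two unpublished quantities by deterministic grid search.

The local→metastatic progression probability and the background-mortality
hazard scale are not published; they are chosen to minimise the sum of
squared relative errors against the published per-arm discounted costs and
QALYs.  The run reproduces the frozen values shipped with the package.
"""

from trastuzumab_cea import Strategy, evaluate_strategy, recalibrate
from trastuzumab_cea.calibration import BASE_CASE_TARGETS
from trastuzumab_cea.profiles import calibration_base
from trastuzumab_cea.synthetic import make_life_table

fit = recalibrate()
print(f"fitted local->metastatic progression: {fit.local_to_metastatic_annual:.4f}")
print(f"fitted life-table hazard scale:       {fit.life_table_scale:.4f}")
print(f"loss (sum sq. rel. errors, 4 targets): {fit.loss:.5f} "
      f"after {fit.n_evaluations} model evaluations\n")

params = fit.apply(calibration_base())
life_table = make_life_table(scale=fit.life_table_scale)
for (arm, qty), target in sorted(BASE_CASE_TARGETS.items(),
                                 key=lambda kv: str(kv[0])):
    model = getattr(evaluate_strategy(arm, params, life_table), qty)
    print(f"{arm.value:6s} {qty:5s} model {model:10.2f} vs published "
          f"{target:10.2f} ({(model - target) / target:+.1%})")

print("\nReading: all four calibration targets are matched within a few "
      "percent; the residual is the structural misfit that the two free "
      "parameters cannot absorb.")
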