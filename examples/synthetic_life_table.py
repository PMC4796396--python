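"""Generate and inspect the synthetic female background-mortality table.

A two-parameter Gompertz law stands in for the unavailable national life
table: annual death probability about 0.004 at age 50, hazard doubling
every ~8.5 years of age, with a multiplicative hazard scale exposed to
calibration.  The table is written in the `age,qx` CSV dialect the model
reads.
"""

import math

from trastuzumab_cea import DEFAULT_MORTALITY, load_life_table, make_life_table

life_table = make_life_table(DEFAULT_MORTALITY, age_lo=50, age_hi=100)
for age in (50, 55, 60, 65, 70):
    print(f"age {age}: q = {life_table.lookup(age):.5f}")
h50 = -math.log(1 - life_table.lookup(50))
h58 = -math.log(1 - life_table.lookup(58))
print(f"hazard ratio age 58/50: {h58 / h50:.2f} "
      "(about 2x per Gompertz doubling time)")

path = "scratch_life_table.csv" if __name__ == "__main__" else None
if path:
    life_table.to_csv(path)
    reread = load_life_table(path)
    print(f"round-trip through {path}: {len(reread)} rows, "
          f"q(70) = {reread.lookup(70):.5f}")
    print("\nReading: a smooth, monotone table covering ages 50-100; the "
          "model clamps lookups beyond the last row.")
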