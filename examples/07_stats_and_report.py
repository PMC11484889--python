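"""Group comparisons, the nested mixed model, and the run report.

Neural statistics respect the nesting of neurons within birds:
response ~ 1 + condition + (1 | bird) + (1 | bird:cell), fitted by maximum
likelihood.  Simple comparisons use the rank-sum test (exact for small
samples), t tests and Fisher's exact test.
"""

import numpy as np
import pandas as pd

import finchcall as fc
from finchcall.stats import LmmSpec

rng = np.random.default_rng(0)

# two-group comparison: e.g. similarity of birds raised with vs without a female
with_female = rng.normal(46, 15, 18)
alone = rng.normal(28, 12, 15)
res = fc.compare_groups(with_female, alone, method="rank_sum")
print(f"rank-sum: statistic {res.statistic:.0f}, p = {res.p_value:.4f}, "
      f"median difference {res.effect:.1f}")

# one-sample: syllable rate against the tutor template's rate
rates = rng.normal(5.6, 1.2, 18)
res1 = fc.one_sample_test(rates, 5.88)
print(f"one-sample t vs 5.88 syll/s: t = {res1.statistic:.2f}, p = {res1.p_value:.3f}")

# responsive instances, juveniles vs adults
fisher = fc.fisher_2x2([[6, 16], [0, 98]])
print(f"Fisher 2x2 (responsive/total instances): p = {fisher.p_value:.2e}")

# nested LMM: firing-rate change with condition, neurons within birds
rows = []
for b in range(6):
    bird_eff = rng.normal(0, 1)
    for c in range(4):
        cell_eff = rng.normal(0, 1)
        for trial in range(10):
            cond = trial % 2
            y = 2.0 + bird_eff + cell_eff + 1.5 * cond + rng.normal(0, 1.5)
            rows.append((f"bird{b}", f"cell{c}", cond, y))
df = pd.DataFrame(rows, columns=["bird", "cell", "condition", "rate"])
lmm = fc.fit_nested_lmm(
    df, LmmSpec(response="rate", condition="condition", outer="bird", inner="cell")
)
print(f"LMM condition effect: {lmm.estimate:.2f} +/- {lmm.se:.2f} Hz, "
      f"p = {lmm.p_value:.2e}")
print(f"variance components: bird {lmm.var_outer:.2f}, "
      f"cell-in-bird {lmm.var_inner:.2f}, residual {lmm.var_resid:.2f}")

# assemble everything into one Markdown report
report = fc.build_report(
    {"tests": [res, res1, fisher], "sessions": None}, config=fc.RunConfig(), seed=0
)
print(f"\nreport: {len(report.splitlines())} lines, sections absent: "
      f"{report.count('_absent_')}")
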