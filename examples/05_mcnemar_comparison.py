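"""Compare two classifiers on the same subjects with McNemar's test.

The test looks only at discordant predictions: cases one classifier gets
right and the other wrong.  Below 25 discordant pairs an exact two-sided
binomial p-value is used; otherwise the continuity-corrected χ².
"""

import numpy as np

from petstage.evaluate import mcnemar

rng = np.random.default_rng(0)
y = rng.choice(["AD", "NC"], size=100)

# classifier A is right 85% of the time, B 75%, errors partly overlapping
a_ok = rng.uniform(size=100) < 0.85
b_ok = rng.uniform(size=100) < 0.75
pred_a = np.where(a_ok, y, np.where(y == "AD", "NC", "AD"))
pred_b = np.where(b_ok, y, np.where(y == "AD", "NC", "AD"))

res = mcnemar(pred_a, pred_b, y)
print(f"discordant counts: A-right/B-wrong n01={res.n01}, A-wrong/B-right n10={res.n10}")
print(f"method={res.method}  statistic={res.statistic:.3f}  p={res.p_value:.4f}")
print("\np < 0.05 would mean the two classifiers' error patterns differ")
print("beyond what coin-flip asymmetry on the discordant cases explains.")
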