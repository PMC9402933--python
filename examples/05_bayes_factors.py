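"""Paired t-tests with default JZS Bayes factors.

Recomputes evidence categories from summary statistics alone and runs a
full paired test on simulated per-participant Nogo accuracies.
"""

import numpy as np

from flickersart.classify import corrected_chance
from flickersart.stats import interpret_bf, jzs_bf10, paired_test

# Bayes factors are functions of (t, n) only: recompute a few from printed
# paired-t statistics (n = df + 1 pairs)
for t, n in [(3.06, 31), (0.18, 31), (2.34, 31), (11.27, 40)]:
    bf = jzs_bf10(t, n)
    print(f"t({n - 1}) = {t:>6}: BF10 = {bf:.3g}  -> {interpret_bf(bf)}")
# BF10 > 3: evidence for a difference; < 0.3: evidence for no difference;
# in between the data are inconclusive.

# a full paired comparison: Nogo accuracy, less vs more sticky, 31
# simulated participants with a 10-point true difference
rng = np.random.default_rng(0)
less = rng.binomial(40, 0.68, size=31) / 40
more = rng.binomial(40, 0.58, size=31) / 40
res = paired_test(less, more)
print(f"\nNogo accuracy less-vs-more sticky: t({res.df}) = {res.t:.2f}, "
      f"p = {res.p:.4f}, BF10 = {res.bf10:.2f} ({res.interpretation})")

print(f"\ncorrected chance, binary, alpha 0.01, n = 159: "
      f"{corrected_chance(0.01, 159):.2f}%")
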