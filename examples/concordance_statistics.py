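"""Agreement statistics on paired binary verdicts.

Shows the three statistical tools on worked inputs: Cohen's kappa with its
95% CI and agreement band, the exact McNemar test on discordant pairs, and
t-based confidence intervals from summary statistics (n, mean, SD).
"""

from planeqc import (
    PairedRatings2x2,
    UndefinedKappaError,
    cohen_kappa,
    mcnemar_exact,
    mean_ci_t,
)

# 30 paired verdicts: rater agrees with the reference on 28 (18 correct,
# 10 incorrect) and each rater flips one case the other got right.
table = PairedRatings2x2(a=18, b=1, c=1, d=10)
result = cohen_kappa(table)
print(f"observed agreement po = {(table.a + table.d) / table.n:.4f}")
print(f"kappa = {result.kappa:.4f} ({result.category} agreement)")
print(f"95% CI = ({result.ci95[0]:.3f}, {result.ci95[1]:.3f}), p = {result.p:.2e}")
print(f"McNemar exact p = {mcnemar_exact(table):.4f} "
      "(b = c: no marginal asymmetry to detect)")
print()

# One-sided disagreement: the rater misses 5 cases the reference calls
# correct and never errs the other way -> p = 2 * (1/2)^5.
skewed = PairedRatings2x2(a=20, b=5, c=0, d=5)
print(f"skewed disagreements (b=5, c=0): McNemar exact p = "
      f"{mcnemar_exact(skewed):.4f}")
print()

# Both raters rate every case 'correct': agreement is perfect but chance
# agreement is too, so kappa is not estimable (reported as missing).
try:
    cohen_kappa(PairedRatings2x2(a=30, b=0, c=0, d=0))
except UndefinedKappaError as exc:
    print(f"constant raters: {exc}")
print()

# Descriptive 95% CI from summary statistics, e.g. age 46.1 +/- 13.9 (n=30).
lo, hi = mean_ci_t(30, 46.1, 13.9)
print(f"mean 46.1, SD 13.9, n=30 -> 95% CI ({lo:.1f}, {hi:.1f})")
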