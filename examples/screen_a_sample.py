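"""Screen a small laboratory-style sample for a discordant outlier.

Applies all four single-outlier discordancy tests (Grubbs N2, Dixon N8,
skewness N14, kurtosis N15) two-sidedly to one measurement series at the
99% confidence level, with critical values simulated on the fly.
"""

from discordancy import ALL_TESTS, TailMode, build_cv_table, compute_statistic

# replicate determinations of the same quantity; 14.2 looks suspicious
values = [10.12, 10.31, 9.94, 10.02, 9.87, 10.21, 14.20]
n = len(values)

cv_table = build_cv_table(ALL_TESTS, [n], 0.99, reps=500_000, base_seed=0)

print(f"sample (n={n}): {values}")
print(f"{'test':5s} {'TN':>8s} {'CV99':>8s}  tested   verdict")
for test in ALL_TESTS:
    res = compute_statistic(values, test, TailMode.TWO_SIDED)
    cv = cv_table.cv(test, n, 0.99)
    verdict = "discordant" if res.statistic > cv else "not significant"
    print(f"{test.value:5s} {res.statistic:8.4f} {cv:8.4f}  {res.tested_rank.value:8s} {verdict}")

# Every statistic exceeds its critical value: at the 99% level all four
# tests agree that the highest observation (14.20) is discordant with a
# normal model for the remaining data.
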