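"""Compare the power functions of the four tests under location slippage.

Simulates n = 10 samples where one observation slips to N(delta, 1),
runs all four tests on the same replications (paired design), and
reports the Power of Test (Omega = pi_DCbar + pi_DC) with its u99
uncertainty over independent experiments, plus each test's percent
difference from the Grubbs reference N2.
"""

from discordancy import (
    ALL_TESTS,
    ContaminationSpec,
    ExperimentGrid,
    TestId,
    build_cv_table,
    percent_difference,
    run_grid,
)

N = 10
grid = ExperimentGrid(
    n_values=(N,),
    contamination_specs=tuple(ContaminationSpec.location(d) for d in (2.0, 4.0, 6.0)),
    tests=ALL_TESTS,
    M=200_000,
    E=4,
    base_seed=7,
)
cv_table = build_cv_table(ALL_TESTS, [N], 0.99, reps=2_000_000, base_seed=7)
summaries = run_grid(grid, cv_table)

print(f"n={N}, M={grid.M:,} x E={grid.E} per cell")
print(f"{'delta':>5s} {'test':>5s} {'Omega':>9s} {'u99':>9s} {'vs N2 %':>8s}")
for delta in (2.0, 4.0, 6.0):
    cells = {s.test: s for s in summaries if s.spec.parameter == delta}
    ref = cells[TestId.N2].means["omega"]
    for test in ALL_TESTS:
        s = cells[test]
        dpct = percent_difference(s.means["omega"], ref)
        print(f"{delta:5.1f} {test.value:>5s} {s.means['omega']:9.5f} "
              f"{s.u99['omega']:9.5f} {dpct:8.2f}")

# The Dixon ratio N8 loses several percent of power relative to N2 as
# delta grows (masking by the second-largest observation), the skewness
# test N14 a smaller amount, while the kurtosis test N15 stays within a
# fraction of a percent of the Grubbs reference.
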