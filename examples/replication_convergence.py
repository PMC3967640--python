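"""How many replications does a stable power estimate need?

Scans the mean Power of Test and its u99 half-width over a doubling
schedule of replication counts for one simulation cell.  The mean
settles while the uncertainty shrinks like 1/sqrt(M) — the basis for
choosing a production replication count.
"""

from discordancy import (
    ContaminationSpec,
    TestId,
    build_cv_table,
    convergence_scan,
    simulation_error,
)

cv_table = build_cv_table([TestId.N2], [5], 0.99, reps=2_000_000, base_seed=3)
rows = convergence_scan(
    n=5,
    spec=ContaminationSpec.location(10.0),
    test=TestId.N2,
    M_schedule=[50_000, 100_000, 200_000, 400_000],
    E=6,
    cv_table=cv_table,
    base_seed=3,
)

print("n=5, delta=10, test N2, E=6 experiments per row")
print(f"{'M':>8s} {'mean Omega':>11s} {'u99':>9s} {'2*sqrt(pq/M)':>13s}")
for r in rows:
    print(f"{r.M:8d} {r.mean_omega:11.5f} {r.u99_omega:9.5f} "
          f"{simulation_error(r.M):13.5f}")

# Successive means agree within their u99 half-widths while u99 roughly
# halves per 4x replications; the last column is the worst-case binomial
# error bound for a single experiment at that M.
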