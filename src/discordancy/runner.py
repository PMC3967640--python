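"""Orchestration of simulation experiments over (n, slippage, test) grids.

One *experiment* is M replications drawn from its own set of random
streams; a *cell* of the design is one (sample size, contamination)
combination, evaluated for every requested test on the **same** M
replications (paired design — comparisons between tests are therefore
within-sample, which reduces the variance of percent differences and
cannot bias the means).  Each test is applied two-sided at its critical
value, and the C / C-bar classification follows the extreme that test's
statistic points at, so the split can differ between tests on the same
sample.

Aggregation over E independent experiments reports the mean of each
probability and its u99 half-width: the 99% confidence interval of the
mean, ``t_{0.995, E-1} * sd / sqrt(E)`` with Student's t (at small E the
t quantile matters; at large E it converges to the normal 2.576).

+/- parameter cells are simulated once on the positive branch and
reported as pooled rows; by the reflection symmetry of the design the
negative branch is distribution-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .contamination import ContaminationSpec, classify_events, draw_samples, experiment_streams
from .critical_values import CriticalValueTable
from .outcomes import (
    OutcomeTally,
    PerformanceMetrics,
    ProbabilityEstimates,
    estimate_probabilities,
    performance_metrics,
    tally_from_arrays,
)
from .stats import ALL_TESTS, TestId, bulk_statistics_with_side

__all__ = [
    "ExperimentGrid",
    "CellResult",
    "CellSummary",
    "run_cell",
    "run_grid",
    "u99_of_mean",
    "percent_difference",
    "simulation_error",
    "convergence_scan",
    "ConvergenceRow",
]

_DEFAULT_CHUNK = 500_000

#: Quantities summarized for a contaminated cell, in reporting order.
CONTAMINATED_QUANTITIES = (
    "pi_DbarCbar",
    "pi_DCbar",
    "pi_DbarC",
    "pi_DC",
    "omega",
    "pi_D_given_C",
)
#: Quantities summarized for an uncontaminated cell.
UNCONTAMINATED_QUANTITIES = ("pi_Dbar", "pi_D")


@dataclass(frozen=True)
class ExperimentGrid:
    """Full specification of a simulation campaign."""

    n_values: tuple[int, ...]
    contamination_specs: tuple[ContaminationSpec, ...]
    tests: tuple[TestId, ...] = ALL_TESTS
    M: int = 1_000_000
    E: int = 10
    confidence: float = 0.99
    base_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "n_values", tuple(int(n) for n in self.n_values))
        object.__setattr__(
            self, "contamination_specs", tuple(self.contamination_specs)
        )
        object.__setattr__(self, "tests", tuple(TestId(t) for t in self.tests))
        if not self.n_values:
            raise ValueError("n_values: at least one sample size required")
        for n in self.n_values:
            if not 3 <= n <= 1000:
                raise ValueError(f"n_values: n must lie in [3, 1000], got {n}")
        if not self.contamination_specs:
            raise ValueError("contamination_specs: at least one spec required")
        if not self.tests:
            raise ValueError("tests: at least one test required")
        if self.M < 1_000:
            raise ValueError(f"M: at least 1000 replications required, got {self.M}")
        if self.E < 2:
            raise ValueError(f"E: at least 2 experiments required (u99), got {self.E}")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must lie in (0, 1), got {self.confidence}")


@dataclass(frozen=True)
class CellResult:
    """One experiment's outcome for one test within a cell."""

    test: TestId
    tally: OutcomeTally
    probabilities: ProbabilityEstimates
    metrics: PerformanceMetrics


def run_cell(
    n: int,
    spec: ContaminationSpec,
    tests: Sequence[TestId],
    cv_table: CriticalValueTable,
    M: int,
    base_seed: int,
    experiment_id: int = 0,
    confidence: float = 0.99,
    chunk_size: int = _DEFAULT_CHUNK,
) -> dict[TestId, CellResult]:
    """Run one experiment of M replications, evaluating all tests paired.

    Deterministic for fixed (base_seed, experiment_id); every test sees
    the identical samples.
    """
    tests = [TestId(t) for t in tests]
    if M < 1:
        raise ValueError(f"M must be positive, got {M}")
    cvs = {t: cv_table.cv(t, n, confidence) for t in tests}
    streams = experiment_streams(base_seed, experiment_id)
    tallies = {t: OutcomeTally(contaminated=spec.contaminated) for t in tests}
    done = 0
    while done < M:
        m = min(chunk_size, M - done)
        block, cont_idx = draw_samples(m, n, spec, *streams)
        c_event = None
        if spec.contaminated:
            # the evaluated outlier of the array: the extreme farther
            # from the mean (one classification shared by all tests)
            mean = block.mean(axis=1)
            dev_upper = (block.max(axis=1) - mean) >= (mean - block.min(axis=1))
            c_event = classify_events(block, cont_idx, dev_upper)
        for t in tests:
            stat, _ = bulk_statistics_with_side(block, t)
            tally_from_arrays(stat > cvs[t], c_event, tallies[t])
        done += m
    out: dict[TestId, CellResult] = {}
    for t in tests:
        probs = estimate_probabilities(tallies[t])
        out[t] = CellResult(
            test=t,
            tally=tallies[t],
            probabilities=probs,
            metrics=performance_metrics(probs),
        )
    return out


def u99_of_mean(values: Sequence[float]) -> float:
    """99% confidence half-width of the mean over independent experiments."""
    arr = np.asarray(values, dtype=float)
    e = arr.size
    if e < 2:
        raise ValueError(f"u99 needs at least 2 experiments, got {e}")
    if np.all(arr == arr[0]):  # exact zero for degenerate duplication
        return 0.0
    t_crit = sps.t.ppf(0.995, e - 1)
    return float(t_crit * arr.std(ddof=1) / math.sqrt(e))


def percent_difference(x_nj: float, x_n2: float) -> float:
    """Percent difference of a test's mean relative to the reference N2."""
    if x_n2 == 0.0:
        raise ValueError("reference mean is zero; percent difference undefined")
    return (x_nj - x_n2) / x_n2 * 100.0


def simulation_error(M: int) -> float:
    """Worst-case binomial simulation error 2*sqrt(0.5*0.5/M)."""
    return 2.0 * math.sqrt(0.25 / M)


def _quantity_values(result: CellResult, quantity: str) -> float | None:
    p = result.probabilities
    if quantity == "pi_DbarCbar":
        return p.pi_spurious_type2
    if quantity == "pi_DCbar":
        return p.pi_spurious_power
    if quantity == "pi_DbarC":
        return p.pi_nonspurious_type2
    if quantity == "pi_DC":
        return p.pi_nonspurious_power
    if quantity == "pi_Dbar":
        return p.pi_true_negative
    if quantity == "pi_D":
        return p.pi_type1
    if quantity == "omega":
        return result.metrics.omega
    if quantity == "pi_D_given_C":
        return result.metrics.conditional_power
    raise KeyError(quantity)


@dataclass(frozen=True)
class CellSummary:
    """Aggregate of E experiments for one (n, spec, test) cell."""

    n: int
    spec: ContaminationSpec
    test: TestId
    M: int
    E: int
    means: Mapping[str, float]
    u99: Mapping[str, float]

    @property
    def quantities(self) -> tuple[str, ...]:
        return (
            CONTAMINATED_QUANTITIES if self.spec.contaminated else UNCONTAMINATED_QUANTITIES
        )


def run_grid(
    grid: ExperimentGrid,
    cv_table: CriticalValueTable,
    progress: Callable[[str], None] | None = None,
) -> list[CellSummary]:
    """Run every cell of the grid, E experiments each, and aggregate.

    Experiment stream identifiers run globally over (cell, experiment)
    so no two experiments anywhere in the grid share a stream.
    """
    summaries: list[CellSummary] = []
    exp_counter = 0
    for n in grid.n_values:
        for spec in grid.contamination_specs:
            per_test: dict[TestId, list[CellResult]] = {t: [] for t in grid.tests}
            for _ in range(grid.E):
                results = run_cell(
                    n,
                    spec,
                    grid.tests,
                    cv_table,
                    grid.M,
                    grid.base_seed,
                    experiment_id=exp_counter,
                    confidence=grid.confidence,
                )
                for t in grid.tests:
                    per_test[t].append(results[t])
                exp_counter += 1
            if progress is not None:
                progress(
                    f"cell n={n} {spec.kind.value} {spec.parameter:g}: "
                    f"{grid.E} experiments x {grid.M} replications done "
                    f"(base_seed={grid.base_seed}, experiment ids "
                    f"{exp_counter - grid.E}..{exp_counter - 1})"
                )
            quantities = (
                CONTAMINATED_QUANTITIES if spec.contaminated else UNCONTAMINATED_QUANTITIES
            )
            for t in grid.tests:
                means: dict[str, float] = {}
                u99s: dict[str, float] = {}
                for q in quantities:
                    vals = [
                        v
                        for r in per_test[t]
                        if (v := _quantity_values(r, q)) is not None
                    ]
                    if not vals:
                        means[q] = math.nan
                        u99s[q] = math.nan
                        continue
                    means[q] = float(np.mean(vals))
                    u99s[q] = u99_of_mean(vals) if len(vals) >= 2 else math.nan
                summaries.append(
                    CellSummary(
                        n=n, spec=spec, test=t, M=grid.M, E=grid.E,
                        means=means, u99=u99s,
                    )
                )
    return summaries


@dataclass(frozen=True)
class ConvergenceRow:
    M: int
    mean_omega: float
    u99_omega: float


def convergence_scan(
    n: int,
    spec: ContaminationSpec,
    test: TestId,
    M_schedule: Sequence[int],
    E: int,
    cv_table: CriticalValueTable,
    base_seed: int = 0,
    confidence: float = 0.99,
) -> list[ConvergenceRow]:
    """Mean Omega and u99 as a function of replications M.

    Reproduces the replication-stability check used to pick an optimum M:
    the mean settles while u99 shrinks like 1/sqrt(M).  Fresh experiment
    streams are used for every (M, experiment) so rows are independent.
    """
    if any(m2 <= m1 for m1, m2 in zip(M_schedule, M_schedule[1:])):
        raise ValueError("M_schedule must be strictly increasing")
    if not spec.contaminated:
        raise ValueError("convergence scan is defined for contaminated cells (Omega)")
    rows = []
    exp_counter = 0
    for M in M_schedule:
        omegas = []
        for _ in range(E):
            res = run_cell(
                n, spec, [test], cv_table, int(M), base_seed,
                experiment_id=exp_counter, confidence=confidence,
            )
            omegas.append(res[TestId(test)].metrics.omega)
            exp_counter += 1
        rows.append(
            ConvergenceRow(
                M=int(M),
                mean_omega=float(np.mean(omegas)),
                u99_omega=u99_of_mean(omegas) if E >= 2 else math.nan,
            )
        )
    return rows
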