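"""Monte Carlo critical values for the discordancy statistics.

Critical values are the empirical quantiles of each statistic's null
distribution — the statistic evaluated on i.i.d. N(0, 1) samples.  The
null form is the two-sided one (max-form for N2 and N8, |skewness| for
N14, kurtosis for N15); the same critical value is then used when an
application is forced to a single tail, which is what makes a 99%
critical value correspond to a 1% two-sided type I error.

Quantiles use linear interpolation between order statistics (the
"type 7" rule, numpy's default); tables record the replication count,
seed and method of every entry so they can be regenerated bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .stats import TailMode, TestId, bulk_statistics

__all__ = [
    "CVEntry",
    "CriticalValueTable",
    "simulate_null_statistics",
    "estimate_critical_value",
    "quantile_standard_error",
    "build_cv_table",
]

PERCENTILE_METHOD = "linear"

# Stable per-test codes for the per-entry seed derivation.
_TEST_CODE = {TestId.N2: 2, TestId.N8: 8, TestId.N14: 14, TestId.N15: 15}

_DEFAULT_CHUNK = 1_000_000


@dataclass(frozen=True)
class CVEntry:
    """One critical value plus the provenance needed to regenerate it."""

    cv: float
    reps: int
    seed: int
    confidence: float
    percentile_method: str = PERCENTILE_METHOD


@dataclass
class CriticalValueTable:
    """Map (test, n, confidence) -> critical value with provenance."""

    entries: dict[tuple[TestId, int, float], CVEntry] = field(default_factory=dict)

    def get(self, test: TestId, n: int, confidence: float) -> CVEntry:
        key = (TestId(test), int(n), float(confidence))
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"no critical value for test={key[0].value}, n={key[1]}, "
                f"confidence={key[2]}"
            ) from None

    def cv(self, test: TestId, n: int, confidence: float) -> float:
        return self.get(test, n, confidence).cv

    def put(self, test: TestId, n: int, confidence: float, entry: CVEntry) -> None:
        self.entries[(TestId(test), int(n), float(confidence))] = entry

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": test.value,
                "n": n,
                "confidence": conf,
                "cv": e.cv,
                "reps": e.reps,
                "seed": e.seed,
                "percentile_method": e.percentile_method,
            }
            for (test, n, conf), e in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
            )
        ]
        return pd.DataFrame(
            rows,
            columns=["test", "n", "confidence", "cv", "reps", "seed", "percentile_method"],
        )

    def write_csv(self, path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def read_csv(cls, path) -> "CriticalValueTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        required = {"test", "n", "confidence", "cv", "reps", "seed", "percentile_method"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"critical value file {path}: missing columns {sorted(missing)}")
        table = cls()
        for row in frame.itertuples(index=False):
            table.put(
                TestId(row.test),
                int(row.n),
                float(row.confidence),
                CVEntry(
                    cv=float(row.cv),
                    reps=int(row.reps),
                    seed=int(row.seed),
                    confidence=float(row.confidence),
                    percentile_method=str(row.percentile_method),
                ),
            )
        return table


def simulate_null_statistics(
    test: TestId,
    n: int,
    reps: int,
    seed: int,
    chunk_size: int = _DEFAULT_CHUNK,
) -> np.ndarray:
    """Draw ``reps`` values of the two-sided null statistic at sample size n.

    Samples are i.i.d. N(0, 1); generation is chunked so memory stays flat
    at large replication counts, and is reproducible for a fixed seed.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    if reps < 1:
        raise ValueError(f"reps must be positive, got {reps}")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    done = 0
    while done < reps:
        m = min(chunk_size, reps - done)
        block = rng.standard_normal((m, n))
        out[done : done + m] = bulk_statistics(block, test, TailMode.TWO_SIDED)
        done += m
    return out


def estimate_critical_value(null_stats: np.ndarray, confidence: float) -> float:
    """Empirical quantile of the null statistics at the given confidence."""
    stats_arr = np.asarray(null_stats, dtype=float)
    if stats_arr.size == 0:
        raise ValueError("empty null statistic array")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    return float(np.quantile(stats_arr, confidence, method=PERCENTILE_METHOD))


def quantile_standard_error(
    null_stats: np.ndarray, confidence: float, half_width: float = 0.002
) -> float:
    """Monte Carlo standard error of the empirical quantile.

    Uses the asymptotic form sqrt(q(1-q)/R) / f(Q(q)), with the density at
    the quantile estimated by a central difference of empirical quantiles
    (slope dQ/dq over ``2 * half_width``).
    """
    stats_arr = np.asarray(null_stats, dtype=float)
    reps = stats_arr.size
    lo = max(confidence - half_width, 0.0)
    hi = min(confidence + half_width, 1.0)
    slope = (
        np.quantile(stats_arr, hi, method=PERCENTILE_METHOD)
        - np.quantile(stats_arr, lo, method=PERCENTILE_METHOD)
    ) / (hi - lo)
    return float(slope * math.sqrt(confidence * (1.0 - confidence) / reps))


def entry_seed(base_seed: int, test: TestId, n: int) -> int:
    """Deterministic per-entry seed: hash of (base_seed, test code, n).

    Uses numpy's SeedSequence mixing so entries are decorrelated; the
    resulting 31-bit integer is recorded in the table entry.
    """
    state = np.random.SeedSequence([int(base_seed), _TEST_CODE[TestId(test)], int(n)])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


def build_cv_table(
    tests: Iterable[TestId],
    n_values: Iterable[int],
    confidence: float | Iterable[float] = 0.99,
    reps: int = 20_000_000,
    base_seed: int = 0,
    chunk_size: int = _DEFAULT_CHUNK,
) -> CriticalValueTable:
    """Simulate a full critical-value table.

    One null simulation is run per (test, n); all requested confidence
    levels are read off the same null sample, which guarantees the
    monotonicity of cv in confidence within an entry.
    """
    confidences = (
        [float(confidence)]
        if isinstance(confidence, (int, float))
        else [float(c) for c in confidence]
    )
    table = CriticalValueTable()
    for test in [TestId(t) for t in tests]:
        for n in n_values:
            seed = entry_seed(base_seed, test, n)
            null = simulate_null_statistics(test, int(n), reps, seed, chunk_size)
            for conf in confidences:
                table.put(
                    test,
                    int(n),
                    conf,
                    CVEntry(
                        cv=estimate_critical_value(null, conf),
                        reps=int(reps),
                        seed=seed,
                        confidence=conf,
                    ),
                )
    return table
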