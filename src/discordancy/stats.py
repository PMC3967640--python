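"""Single extreme outlier discordancy statistics for normal samples.

Implements the four classical statistics in Barnett & Lewis's nomenclature:

* **N2** — Grubbs's extreme studentized deviate, ``(x_(n) - mean)/s`` or
  ``(mean - x_(1))/s``.
* **N8** — Dixon's ratio of the outer gap to the range.
* **N14** — sample skewness ``|sqrt(n) * m3_sum / m2_sum**1.5|``.
* **N15** — sample kurtosis ``n * m4_sum / m2_sum**2``.

Each statistic can be *applied* to the highest observation, the lowest
observation, or two-sidedly (whichever extreme is more discrepant).  For
N14 and N15 the numeric value is identical in every mode; the application
mode only decides which extreme the verdict refers to.

The sample standard deviation uses the ``n - 1`` denominator throughout,
the convention of Grubbs's original tables; the same convention is used
when the null distributions are simulated, so verdicts are insensitive to
the choice as long as it is applied consistently.

Scalar entry points operate on one sample and return rich results; the
``bulk_statistics`` kernel evaluates one statistic on a 2-D block of
samples (rows) and is the hot path of the Monte Carlo simulations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TestId",
    "TailMode",
    "TestedRank",
    "OrderedArray",
    "TestStatisticResult",
    "InvalidInputError",
    "DegenerateSampleError",
    "order_sample",
    "grubbs_n2",
    "dixon_n8",
    "skewness_n14",
    "kurtosis_n15",
    "compute_statistic",
    "bulk_statistics",
    "bulk_statistics_with_side",
    "ALL_TESTS",
]


class InvalidInputError(ValueError):
    """Raised for samples that violate the preconditions (n < 3, non-finite)."""


class DegenerateSampleError(ValueError):
    """Raised when a statistic is undefined (zero spread)."""


class TestId(str, enum.Enum):
    """Barnett & Lewis test labels."""

    N2 = "N2"
    N8 = "N8"
    N14 = "N14"
    N15 = "N15"


ALL_TESTS: tuple[TestId, ...] = (TestId.N2, TestId.N8, TestId.N14, TestId.N15)


class TailMode(str, enum.Enum):
    """Which extreme the test application evaluates."""

    UPPER = "upper"
    LOWER = "lower"
    TWO_SIDED = "two_sided"


class TestedRank(str, enum.Enum):
    HIGHEST = "highest"
    LOWEST = "lowest"


@dataclass(frozen=True)
class OrderedArray:
    """A sample together with its ascending rearrangement.

    ``order_map[i]`` is the rank (0-based position in ``sorted_values``) of
    the observation that sat at original index ``i``.  Ties are ranked
    stably, i.e. equal values keep their original relative order.
    """

    sorted_values: np.ndarray
    order_map: np.ndarray

    @property
    def n(self) -> int:
        return self.sorted_values.size


@dataclass(frozen=True)
class TestStatisticResult:
    test_id: TestId
    statistic: float
    tested_rank: TestedRank


def _as_valid_array(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D sample, got shape {x.shape}")
    if x.size < 3:
        raise InvalidInputError(f"need at least 3 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("sample contains non-finite values")
    return x


def order_sample(values) -> OrderedArray:
    """Sort a sample ascending and keep the original-index -> rank map."""
    x = _as_valid_array(values)
    perm = np.argsort(x, kind="stable")
    order_map = np.empty_like(perm)
    order_map[perm] = np.arange(x.size)
    return OrderedArray(sorted_values=x[perm], order_map=order_map)


def _ordered(values) -> OrderedArray:
    if isinstance(values, OrderedArray):
        return values
    return order_sample(values)


def grubbs_n2(values, tail: TailMode = TailMode.TWO_SIDED) -> TestStatisticResult:
    """Grubbs's N2: studentized distance of an extreme from the mean.

    Two-sided mode takes the larger of the upper and lower deviations;
    an exact tie (perfectly symmetric sample) resolves to the highest
    observation, a probability-zero event under continuous sampling.
    """
    ordered = _ordered(values)
    xs = ordered.sorted_values
    mean = xs.mean()
    s = xs.std(ddof=1)
    if s == 0.0:
        raise DegenerateSampleError("zero sample standard deviation")
    upper = (xs[-1] - mean) / s
    lower = (mean - xs[0]) / s
    if tail is TailMode.UPPER:
        stat, rank = upper, TestedRank.HIGHEST
    elif tail is TailMode.LOWER:
        stat, rank = lower, TestedRank.LOWEST
    else:
        if upper >= lower:
            stat, rank = upper, TestedRank.HIGHEST
        else:
            stat, rank = lower, TestedRank.LOWEST
    return TestStatisticResult(TestId.N2, float(stat), rank)


def dixon_n8(values, tail: TailMode = TailMode.TWO_SIDED) -> TestStatisticResult:
    """Dixon's N8: outer gap over range.

    For n = 3 the upper and lower ratios sum to one exactly, so the
    two-sided statistic is always >= 0.5 there.
    """
    ordered = _ordered(values)
    xs = ordered.sorted_values
    rng = xs[-1] - xs[0]
    if rng == 0.0:
        raise DegenerateSampleError("zero sample range")
    upper = (xs[-1] - xs[-2]) / rng
    lower = (xs[1] - xs[0]) / rng
    if tail is TailMode.UPPER:
        stat, rank = upper, TestedRank.HIGHEST
    elif tail is TailMode.LOWER:
        stat, rank = lower, TestedRank.LOWEST
    else:
        if upper >= lower:
            stat, rank = upper, TestedRank.HIGHEST
        else:
            stat, rank = lower, TestedRank.LOWEST
    return TestStatisticResult(TestId.N8, float(stat), rank)


def skewness_n14(values, tail: TailMode = TailMode.TWO_SIDED) -> TestStatisticResult:
    """Sample skewness N14, evaluated as an absolute value.

    The magnitude is tail-independent; the tested extreme follows the
    application mode, and in two-sided mode the sign of the skewness
    decides it (positive skew points at the highest observation).
    """
    ordered = _ordered(values)
    xs = ordered.sorted_values
    c = xs - xs.mean()
    m2 = np.sum(c * c)
    if m2 == 0.0:
        raise DegenerateSampleError("zero second central moment")
    signed = np.sqrt(xs.size) * np.sum(c**3) / m2**1.5
    if tail is TailMode.UPPER:
        rank = TestedRank.HIGHEST
    elif tail is TailMode.LOWER:
        rank = TestedRank.LOWEST
    else:
        rank = TestedRank.HIGHEST if signed >= 0 else TestedRank.LOWEST
    return TestStatisticResult(TestId.N14, float(abs(signed)), rank)


def kurtosis_n15(values, tail: TailMode = TailMode.TWO_SIDED) -> TestStatisticResult:
    """Sample kurtosis N15 (not excess; minimum 1, maximum n).

    Tail-independent in value; in two-sided mode the more distant extreme
    (larger deviation from the mean) is the tested observation.
    """
    ordered = _ordered(values)
    xs = ordered.sorted_values
    mean = xs.mean()
    c = xs - mean
    m2 = np.sum(c * c)
    if m2 == 0.0:
        raise DegenerateSampleError("zero second central moment")
    stat = xs.size * np.sum(c**4) / m2**2
    if tail is TailMode.UPPER:
        rank = TestedRank.HIGHEST
    elif tail is TailMode.LOWER:
        rank = TestedRank.LOWEST
    else:
        rank = (
            TestedRank.HIGHEST
            if (xs[-1] - mean) >= (mean - xs[0])
            else TestedRank.LOWEST
        )
    return TestStatisticResult(TestId.N15, float(stat), rank)


_SCALAR_FUNCS = {
    TestId.N2: grubbs_n2,
    TestId.N8: dixon_n8,
    TestId.N14: skewness_n14,
    TestId.N15: kurtosis_n15,
}


def compute_statistic(
    values, test: TestId, tail: TailMode = TailMode.TWO_SIDED
) -> TestStatisticResult:
    """Dispatch to one of the four statistics by test id."""
    return _SCALAR_FUNCS[TestId(test)](values, tail)


def bulk_statistics(block: np.ndarray, test: TestId, tail: TailMode) -> np.ndarray:
    """Evaluate one statistic on every row of an (m, n) block.

    Vectorized equivalent of the scalar functions (identical values up to
    floating-point associativity).  Rows violating the spread precondition
    produce ``nan`` rather than raising; the Monte Carlo callers draw from
    continuous distributions where that event has probability zero.
    """
    test = TestId(test)
    tail = TailMode(tail)
    x = np.asarray(block, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InvalidInputError(f"expected an (m, n>=3) block, got shape {x.shape}")
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        if test is TestId.N2:
            mean = x.mean(axis=1)
            s = x.std(axis=1, ddof=1)
            hi = x.max(axis=1)
            lo = x.min(axis=1)
            if tail is TailMode.UPPER:
                return (hi - mean) / s
            if tail is TailMode.LOWER:
                return (mean - lo) / s
            return np.maximum(hi - mean, mean - lo) / s
        if test is TestId.N8:
            xs = np.sort(x, axis=1)
            rng = xs[:, -1] - xs[:, 0]
            upper = (xs[:, -1] - xs[:, -2]) / rng
            lower = (xs[:, 1] - xs[:, 0]) / rng
            if tail is TailMode.UPPER:
                return upper
            if tail is TailMode.LOWER:
                return lower
            return np.maximum(upper, lower)
        c = x - x.mean(axis=1, keepdims=True)
        c2 = c * c
        m2 = c2.sum(axis=1)
        if test is TestId.N14:
            m3 = (c2 * c).sum(axis=1)
            return np.abs(np.sqrt(n) * m3 / m2**1.5)
        m4 = (c2 * c2).sum(axis=1)
        return n * m4 / m2**2


def bulk_statistics_with_side(
    block: np.ndarray, test: TestId
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided statistic of every row plus the extreme it tests.

    Returns ``(stats, tested_upper)`` where ``tested_upper[i]`` is True
    when row i's two-sided application evaluates the highest observation
    (N2/N8: the larger of the two one-sided forms; N14: nonnegative
    skewness; N15: the extreme farther from the mean).  Exact ties point
    upward, matching the scalar functions.
    """
    test = TestId(test)
    x = np.asarray(block, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise InvalidInputError(f"expected an (m, n>=3) block, got shape {x.shape}")
    n = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        if test is TestId.N2:
            mean = x.mean(axis=1)
            s = x.std(axis=1, ddof=1)
            upper = (x.max(axis=1) - mean) / s
            lower = (mean - x.min(axis=1)) / s
            return np.maximum(upper, lower), upper >= lower
        if test is TestId.N8:
            xs = np.sort(x, axis=1)
            rng = xs[:, -1] - xs[:, 0]
            upper = (xs[:, -1] - xs[:, -2]) / rng
            lower = (xs[:, 1] - xs[:, 0]) / rng
            return np.maximum(upper, lower), upper >= lower
        mean = x.mean(axis=1)
        c = x - mean[:, None]
        c2 = c * c
        m2 = c2.sum(axis=1)
        if test is TestId.N14:
            signed = np.sqrt(n) * (c2 * c).sum(axis=1) / m2**1.5
            return np.abs(signed), signed >= 0
        stat = n * (c2 * c2).sum(axis=1) / m2**2
        tested_upper = (x.max(axis=1) - mean) >= (mean - x.min(axis=1))
        return stat, tested_upper
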