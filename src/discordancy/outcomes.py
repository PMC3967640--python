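"""Outcome classification and performance criteria.

Each test application is two-sided: the statistic's max-form value is
compared to the critical value, and the *tested* observation is the
extreme the statistic points at.  The verdict is *significant* only for
a strict exceedance, TN > CV; TN = CV counts as not significant.

For a contaminated run every replication is a C event (the tested
observation is the contaminant) or a C-bar event (the tested extreme is
legitimate), and the four outcome probabilities are **conditional** on
that split::

    pi_DbarCbar = #(not significant, C-bar) / #C-bar
    pi_DCbar    = #(significant, C-bar)     / #C-bar   (spurious power)
    pi_DbarC    = #(not significant, C)     / #C
    pi_DC       = #(significant, C)         / #C       (nonspurious power)

so pi_DbarCbar + pi_DCbar = 1 and pi_DbarC + pi_DC = 1 exactly.  When a
conditioning class is empty (no C-bar events at large slippage) its two
rates are reported as 0.  For an uncontaminated run the two rates are
plain fractions of M.  Counts are integers until the final division.

Performance criteria:

* Power of Test  Omega = pi_DCbar + pi_DC  — the sum of the spurious and
  nonspurious conditional significant rates.
* Conditional power  pi_D|C = pi_DC / (pi_DC + pi_DbarC)  — the P5
  criterion; equals pi_DC since the denominator is 1, and is undefined
  (None) when no C events occurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contamination import EventType, SimulatedSample
from .critical_values import CriticalValueTable
from .stats import TailMode, TestId, compute_statistic

__all__ = [
    "OutcomeTally",
    "ProbabilityEstimates",
    "PerformanceMetrics",
    "apply_test",
    "tally_outcome",
    "tally_from_arrays",
    "estimate_probabilities",
    "omega",
    "conditional_power",
    "performance_metrics",
]


@dataclass
class OutcomeTally:
    """Integer counts of the six outcome cells.

    A contaminated run populates only the four C / C-bar cells; an
    uncontaminated run only the two 'absent' cells.
    """

    contaminated: bool
    spurious_type2: int = 0      # C-bar, not significant
    spurious_power: int = 0      # C-bar, significant
    nonspurious_type2: int = 0   # C, not significant
    nonspurious_power: int = 0   # C, significant
    true_negative: int = 0       # absent, not significant
    type1: int = 0               # absent, significant

    @property
    def n_cbar(self) -> int:
        return self.spurious_type2 + self.spurious_power

    @property
    def n_c(self) -> int:
        return self.nonspurious_type2 + self.nonspurious_power

    @property
    def total(self) -> int:
        return self.n_cbar + self.n_c + self.true_negative + self.type1

    def check(self) -> None:
        if self.contaminated:
            if self.true_negative or self.type1:
                raise ValueError("contaminated tally has counts in absent cells")
        else:
            if self.n_cbar or self.n_c:
                raise ValueError("uncontaminated tally has counts in C / C-bar cells")


def apply_test(
    sample: SimulatedSample,
    test: TestId,
    cv: float | CriticalValueTable,
    confidence: float = 0.99,
) -> bool:
    """True when the two-sided statistic strictly exceeds the critical value.

    ``cv`` may be a number or a table (looked up at the sample's size and
    the given confidence).
    """
    if isinstance(cv, CriticalValueTable):
        cv = cv.cv(test, sample.values.size, confidence)
    result = compute_statistic(sample.values, test, TailMode.TWO_SIDED)
    return bool(result.statistic > cv)


def tally_outcome(event: EventType, significant: bool, tally: OutcomeTally) -> OutcomeTally:
    """Increment exactly one cell of the tally (mutated and returned)."""
    event = EventType(event)
    if (event is EventType.ABSENT) == tally.contaminated:
        raise ValueError(
            f"event {event.value!r} does not match tally mode "
            f"(contaminated={tally.contaminated})"
        )
    if event is EventType.C_BAR:
        if significant:
            tally.spurious_power += 1
        else:
            tally.spurious_type2 += 1
    elif event is EventType.C:
        if significant:
            tally.nonspurious_power += 1
        else:
            tally.nonspurious_type2 += 1
    else:
        if significant:
            tally.type1 += 1
        else:
            tally.true_negative += 1
    return tally


def tally_from_arrays(
    significant: np.ndarray,
    c_event: np.ndarray | None,
    tally: OutcomeTally | None = None,
) -> OutcomeTally:
    """Bulk tally of a block of replications.

    ``c_event`` is the boolean C/C-bar classification, or None for an
    uncontaminated block.  An existing tally can be passed to accumulate
    across chunks.
    """
    significant = np.asarray(significant, dtype=bool)
    if c_event is None:
        if tally is None:
            tally = OutcomeTally(contaminated=False)
        elif tally.contaminated:
            raise ValueError("cannot add uncontaminated block to a contaminated tally")
        sig = int(np.count_nonzero(significant))
        tally.type1 += sig
        tally.true_negative += significant.size - sig
        return tally
    c_event = np.asarray(c_event, dtype=bool)
    if c_event.shape != significant.shape:
        raise ValueError("significant and c_event must have the same shape")
    if tally is None:
        tally = OutcomeTally(contaminated=True)
    elif not tally.contaminated:
        raise ValueError("cannot add contaminated block to an uncontaminated tally")
    c_sig = int(np.count_nonzero(c_event & significant))
    c_tot = int(np.count_nonzero(c_event))
    sig_tot = int(np.count_nonzero(significant))
    tally.nonspurious_power += c_sig
    tally.nonspurious_type2 += c_tot - c_sig
    tally.spurious_power += sig_tot - c_sig
    tally.spurious_type2 += significant.size - c_tot - (sig_tot - c_sig)
    return tally


@dataclass(frozen=True)
class ProbabilityEstimates:
    """The six outcome probabilities.

    Contaminated runs carry the conditional rates (each C / C-bar pair
    sums to 1; an empty class yields zeros); uncontaminated runs carry
    the plain fractions of M.
    """

    contaminated: bool
    pi_spurious_type2: float = 0.0   # pi_DbarCbar
    pi_spurious_power: float = 0.0   # pi_DCbar
    pi_nonspurious_type2: float = 0.0  # pi_DbarC
    pi_nonspurious_power: float = 0.0  # pi_DC
    pi_true_negative: float = 0.0    # pi_Dbar
    pi_type1: float = 0.0            # pi_D
    m: int = 0
    n_c: int = 0
    n_cbar: int = 0

    def as_dict(self) -> dict[str, float]:
        if self.contaminated:
            return {
                "pi_DbarCbar": self.pi_spurious_type2,
                "pi_DCbar": self.pi_spurious_power,
                "pi_DbarC": self.pi_nonspurious_type2,
                "pi_DC": self.pi_nonspurious_power,
            }
        return {"pi_Dbar": self.pi_true_negative, "pi_D": self.pi_type1}


def estimate_probabilities(tally: OutcomeTally) -> ProbabilityEstimates:
    """Conditional (contaminated) or plain (uncontaminated) fractions."""
    tally.check()
    m = tally.total
    if m == 0:
        raise ValueError("empty tally")
    if tally.contaminated:
        n_c, n_cbar = tally.n_c, tally.n_cbar
        return ProbabilityEstimates(
            contaminated=True,
            pi_spurious_type2=tally.spurious_type2 / n_cbar if n_cbar else 0.0,
            pi_spurious_power=tally.spurious_power / n_cbar if n_cbar else 0.0,
            pi_nonspurious_type2=tally.nonspurious_type2 / n_c if n_c else 0.0,
            pi_nonspurious_power=tally.nonspurious_power / n_c if n_c else 0.0,
            m=m, n_c=n_c, n_cbar=n_cbar,
        )
    return ProbabilityEstimates(
        contaminated=False,
        pi_true_negative=tally.true_negative / m,
        pi_type1=tally.type1 / m,
        m=m,
    )


def omega(p: ProbabilityEstimates) -> float:
    """Power of Test: spurious plus nonspurious conditional power."""
    return p.pi_spurious_power + p.pi_nonspurious_power


def conditional_power(p: ProbabilityEstimates) -> float | None:
    """P5 criterion pi_DC / (pi_DC + pi_DbarC); None when no C events."""
    denom = p.pi_nonspurious_power + p.pi_nonspurious_type2
    if denom == 0.0:
        return None
    return p.pi_nonspurious_power / denom


@dataclass(frozen=True)
class PerformanceMetrics:
    omega: float
    conditional_power: float | None


def performance_metrics(p: ProbabilityEstimates) -> PerformanceMetrics:
    return PerformanceMetrics(omega=omega(p), conditional_power=conditional_power(p))
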