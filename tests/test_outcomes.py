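"""Tests for outcome tallies, probability estimates and criteria."""

import math

import numpy as np
import pytest

from discordancy import (
    ContaminationSpec,
    EventType,
    OutcomeTally,
    SimulatedSample,
    TestId,
    apply_test,
    conditional_power,
    estimate_probabilities,
    omega,
    performance_metrics,
    tally_from_arrays,
    tally_outcome,
)
from discordancy.stats import TailMode, compute_statistic


def _sample(values, spec=None):
    spec = spec or ContaminationSpec.none()
    idx = 0 if spec.contaminated else None
    return SimulatedSample(values=np.asarray(values, dtype=float),
                           spec=spec, contaminant_index=idx)


class TestApplyTest:
    def test_statistic_equal_to_cv_is_not_significant(self):
        sample = _sample([-1.0, 0.0, 1.0, 2.0, 5.0])
        stat = compute_statistic(sample.values, TestId.N2, TailMode.TWO_SIDED).statistic
        assert apply_test(sample, TestId.N2, cv=stat) is False
        assert apply_test(sample, TestId.N2, cv=stat - 1e-12) is True

    def test_zero_cv_always_significant_for_n2(self, rng):
        for _ in range(20):
            sample = _sample(rng.normal(size=6))
            assert apply_test(sample, TestId.N2, cv=0.0) is True

    def test_infinite_cv_never_significant(self, rng):
        sample = _sample(rng.normal(size=6))
        assert apply_test(sample, TestId.N2, cv=math.inf) is False

    def test_two_sided_application_flags_either_extreme(self, cv_table_small):
        # the two-sided application catches a gross outlier on both sides
        low = _sample([-50.0, 0.1, 0.2, -0.1, 0.3])
        high = _sample([50.0, 0.1, 0.2, -0.1, 0.3])
        assert apply_test(low, TestId.N2, cv_table_small) is True
        assert apply_test(high, TestId.N2, cv_table_small) is True


class TestTally:
    @pytest.mark.parametrize(
        "event,significant,cell",
        [
            (EventType.C_BAR, False, "spurious_type2"),
            (EventType.C_BAR, True, "spurious_power"),
            (EventType.C, False, "nonspurious_type2"),
            (EventType.C, True, "nonspurious_power"),
        ],
    )
    def test_contaminated_cells(self, event, significant, cell):
        tally = OutcomeTally(contaminated=True)
        tally_outcome(event, significant, tally)
        assert getattr(tally, cell) == 1
        assert tally.total == 1

    @pytest.mark.parametrize(
        "significant,cell", [(False, "true_negative"), (True, "type1")]
    )
    def test_absent_cells(self, significant, cell):
        tally = OutcomeTally(contaminated=False)
        tally_outcome(EventType.ABSENT, significant, tally)
        assert getattr(tally, cell) == 1

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tally_outcome(EventType.ABSENT, True, OutcomeTally(contaminated=True))
        with pytest.raises(ValueError):
            tally_outcome(EventType.C, True, OutcomeTally(contaminated=False))

    def test_bulk_tally_matches_scalar_loop(self, rng):
        sig = rng.random(1000) < 0.3
        c = rng.random(1000) < 0.6
        bulk = tally_from_arrays(sig, c)
        loop = OutcomeTally(contaminated=True)
        for s, ci in zip(sig, c):
            tally_outcome(EventType.C if ci else EventType.C_BAR, bool(s), loop)
        assert bulk == loop
        assert bulk.total == 1000

    def test_bulk_tally_accumulates_across_chunks(self, rng):
        sig = rng.random(500) < 0.5
        t = tally_from_arrays(sig[:200], None)
        t = tally_from_arrays(sig[200:], None, t)
        assert t.total == 500
        assert t.type1 == int(sig.sum())


class TestProbabilities:
    def test_contaminated_rates_are_conditional(self):
        tally = OutcomeTally(
            contaminated=True,
            spurious_type2=10, spurious_power=20,
            nonspurious_type2=30, nonspurious_power=40,
        )
        p = estimate_probabilities(tally)
        assert p.pi_spurious_type2 == pytest.approx(10 / 30)
        assert p.pi_spurious_power == pytest.approx(20 / 30)
        assert p.pi_nonspurious_type2 == pytest.approx(30 / 70)
        assert p.pi_nonspurious_power == pytest.approx(40 / 70)
        # each conditioning class partitions to one
        assert p.pi_spurious_type2 + p.pi_spurious_power == pytest.approx(1.0)
        assert p.pi_nonspurious_type2 + p.pi_nonspurious_power == pytest.approx(1.0)

    def test_empty_cbar_class_reports_zero_rates(self):
        tally = OutcomeTally(contaminated=True, nonspurious_type2=40,
                             nonspurious_power=60)
        p = estimate_probabilities(tally)
        assert p.pi_spurious_type2 == p.pi_spurious_power == 0.0
        assert p.pi_nonspurious_power == pytest.approx(0.6)
        assert omega(p) == pytest.approx(0.6)  # only the C side contributes

    def test_uncontaminated_fractions(self):
        tally = OutcomeTally(contaminated=False, true_negative=99, type1=1)
        p = estimate_probabilities(tally)
        assert p.pi_true_negative == 0.99
        assert p.pi_type1 == 0.01

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            estimate_probabilities(OutcomeTally(contaminated=True))

    def test_partition_of_unity_exact_for_random_counts(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 10_000, size=4)
            if counts.sum() == 0:
                continue
            tally = OutcomeTally(
                contaminated=True,
                spurious_type2=int(counts[0]), spurious_power=int(counts[1]),
                nonspurious_type2=int(counts[2]), nonspurious_power=int(counts[3]),
            )
            p = estimate_probabilities(tally)
            # each nonempty conditioning class partitions exactly to one
            if tally.n_cbar:
                assert p.pi_spurious_type2 + p.pi_spurious_power == pytest.approx(
                    1.0, abs=1e-15
                )
            if tally.n_c:
                assert p.pi_nonspurious_type2 + p.pi_nonspurious_power == pytest.approx(
                    1.0, abs=1e-15
                )


class TestCriteria:
    def test_omega_sums_the_conditional_significant_rates(self):
        tally = OutcomeTally(
            contaminated=True,
            spurious_type2=986, spurious_power=14,
            nonspurious_type2=514, nonspurious_power=486,
        )
        p = estimate_probabilities(tally)
        assert omega(p) == pytest.approx(14 / 1000 + 486 / 1000)
        assert omega(p) == pytest.approx(p.pi_spurious_power + p.pi_nonspurious_power)

    def test_omega_zero_when_nothing_significant(self):
        tally = OutcomeTally(contaminated=True, spurious_type2=5, nonspurious_type2=5)
        assert omega(estimate_probabilities(tally)) == 0.0

    def test_conditional_power_ratio(self):
        tally = OutcomeTally(
            contaminated=True,
            spurious_type2=500, spurious_power=100,
            nonspurious_type2=100, nonspurious_power=300,
        )
        assert conditional_power(estimate_probabilities(tally)) == pytest.approx(0.75)

    def test_conditional_power_zero_with_only_misses(self):
        tally = OutcomeTally(contaminated=True, spurious_type2=90, nonspurious_type2=10)
        assert conditional_power(estimate_probabilities(tally)) == 0.0

    def test_conditional_power_undefined_without_c_events(self):
        tally = OutcomeTally(contaminated=True, spurious_type2=90, spurious_power=10)
        p = estimate_probabilities(tally)
        assert conditional_power(p) is None
        assert performance_metrics(p).conditional_power is None
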