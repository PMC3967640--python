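"""Tests for grid orchestration, u99 aggregation and comparisons."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from discordancy import (
    ContaminationSpec,
    ExperimentGrid,
    TestId,
    convergence_scan,
    percent_difference,
    run_cell,
    run_grid,
    simulation_error,
    u99_of_mean,
)


class TestU99:
    def test_constant_values_give_zero(self):
        assert u99_of_mean([0.4, 0.4, 0.4]) == 0.0

    def test_two_values_closed_form(self):
        # sd of (0, 1) is 1/sqrt(2); half-width t_{0.995,1} * sd / sqrt(2)
        expected = sps.t.ppf(0.995, 1) * (1 / math.sqrt(2)) / math.sqrt(2)
        assert u99_of_mean([0.0, 1.0]) == pytest.approx(expected)

    def test_scaling_linearity(self, rng):
        vals = rng.random(8)
        assert u99_of_mean(3.5 * vals) == pytest.approx(3.5 * u99_of_mean(vals))

    def test_single_experiment_rejected(self):
        with pytest.raises(ValueError):
            u99_of_mean([0.5])


class TestPercentDifference:
    def test_relative_difference_to_reference(self):
        assert percent_difference(0.49503, 0.50044) == pytest.approx(-1.08, abs=0.005)

    def test_equal_means_give_zero(self):
        assert percent_difference(0.7, 0.7) == 0.0

    def test_ten_percent(self):
        assert percent_difference(1.1, 1.0) == pytest.approx(10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.5, 0.0)


def test_simulation_error_formula():
    assert round(simulation_error(20_000_000), 5) == 0.00022


class TestRunCell:
    def test_single_replication_yields_degenerate_probabilities(self, cv_table_small):
        res = run_cell(
            5, ContaminationSpec.location(4.0), [TestId.N2], cv_table_small,
            M=1, base_seed=0,
        )
        p = res[TestId.N2].probabilities
        values = list(p.as_dict().values())
        assert all(v in (0.0, 1.0) for v in values)
        assert sum(values) == 1.0

    def test_reproducible_counts_for_fixed_seed(self, cv_table_small):
        kwargs = dict(M=5_000, base_seed=42, experiment_id=3)
        a = run_cell(5, ContaminationSpec.location(4.0),
                     [TestId.N2, TestId.N8], cv_table_small, **kwargs)
        b = run_cell(5, ContaminationSpec.location(4.0),
                     [TestId.N2, TestId.N8], cv_table_small, **kwargs)
        for t in (TestId.N2, TestId.N8):
            assert a[t].tally == b[t].tally

    def test_paired_design_is_independent_of_test_selection(self, cv_table_small):
        """All tests see the same samples, so adding tests never changes
        another test's counts."""
        spec = ContaminationSpec.location(4.0)
        alone = run_cell(5, spec, [TestId.N2], cv_table_small, M=5_000, base_seed=1)
        together = run_cell(
            5, spec, [TestId.N2, TestId.N8, TestId.N14, TestId.N15],
            cv_table_small, M=5_000, base_seed=1,
        )
        assert alone[TestId.N2].tally == together[TestId.N2].tally

    def test_chunking_does_not_change_counts(self, cv_table_small):
        spec = ContaminationSpec.scale(3.0)
        a = run_cell(5, spec, [TestId.N15], cv_table_small, M=9_000,
                     base_seed=2, chunk_size=1_000)
        b = run_cell(5, spec, [TestId.N15], cv_table_small, M=9_000,
                     base_seed=2, chunk_size=9_000)
        assert a[TestId.N15].tally == b[TestId.N15].tally

    def test_partition_of_unity_on_simulated_counts(self, cv_table_small):
        res = run_cell(
            10, ContaminationSpec.location(3.0),
            [TestId.N2, TestId.N8, TestId.N14, TestId.N15],
            cv_table_small, M=20_000, base_seed=6,
        )
        for r in res.values():
            t = r.tally
            assert (t.spurious_type2 + t.spurious_power
                    + t.nonspurious_type2 + t.nonspurious_power) == 20_000
            assert t.true_negative == t.type1 == 0

    def test_missing_cv_entry_is_a_configuration_error(self, cv_table_small):
        with pytest.raises(KeyError):
            run_cell(7, ContaminationSpec.none(), [TestId.N2], cv_table_small,
                     M=1_000, base_seed=0)


class TestGrid:
    def test_validation(self):
        spec = (ContaminationSpec.location(4.0),)
        with pytest.raises(ValueError, match="M"):
            ExperimentGrid(n_values=(5,), contamination_specs=spec, M=10)
        with pytest.raises(ValueError, match="E"):
            ExperimentGrid(n_values=(5,), contamination_specs=spec, E=1)
        with pytest.raises(ValueError, match="n_values"):
            ExperimentGrid(n_values=(2,), contamination_specs=spec)

    def test_small_grid_summary_shape(self, cv_table_small):
        grid = ExperimentGrid(
            n_values=(5,),
            contamination_specs=(ContaminationSpec.none(), ContaminationSpec.location(4.0)),
            tests=(TestId.N2, TestId.N8),
            M=2_000, E=3, base_seed=5,
        )
        summaries = run_grid(grid, cv_table_small)
        assert len(summaries) == 4  # 2 specs x 2 tests
        clean = [s for s in summaries if not s.spec.contaminated]
        assert set(clean[0].means) == {"pi_Dbar", "pi_D"}
        dirty = [s for s in summaries if s.spec.contaminated]
        assert "omega" in dirty[0].means and "pi_D_given_C" in dirty[0].means
        for s in summaries:
            for q in s.quantities:
                assert s.u99[q] >= 0.0

    def test_null_calibration_within_binomial_error(self, cv_table_small):
        # at delta=0 the significant fraction estimates 1 - confidence
        grid = ExperimentGrid(
            n_values=(5,), contamination_specs=(ContaminationSpec.none(),),
            tests=(TestId.N2,), M=50_000, E=2, base_seed=8,
        )
        (s,) = [x for x in run_grid(grid, cv_table_small) if x.test is TestId.N2]
        se = math.sqrt(0.01 * 0.99 / (grid.M * grid.E))
        # the small-reps CV table adds its own quantile error on top
        assert s.means["pi_D"] == pytest.approx(0.01, abs=3 * se + 2e-3)

    def test_omega_equals_significant_fraction_decomposition(self, cv_table_small):
        grid = ExperimentGrid(
            n_values=(5,), contamination_specs=(ContaminationSpec.location(5.0),),
            tests=(TestId.N2,), M=5_000, E=2, base_seed=9,
        )
        (s,) = run_grid(grid, cv_table_small)
        assert s.means["omega"] == pytest.approx(
            s.means["pi_DCbar"] + s.means["pi_DC"], abs=1e-12
        )


class TestConvergence:
    def test_schedule_must_increase(self, cv_table_small):
        with pytest.raises(ValueError):
            convergence_scan(5, ContaminationSpec.location(4.0), TestId.N2,
                             [1000, 1000], 2, cv_table_small)

    def test_single_m_gives_single_row(self, cv_table_small):
        rows = convergence_scan(5, ContaminationSpec.location(4.0), TestId.N2,
                                [2_000], 3, cv_table_small, base_seed=1)
        assert len(rows) == 1 and rows[0].M == 2_000

    def test_u99_shrinks_roughly_like_inverse_sqrt_m(self, cv_table_small):
        rows = convergence_scan(
            5, ContaminationSpec.location(6.0), TestId.N2,
            [2_000, 32_000], 12, cv_table_small, base_seed=3,
        )
        ratio = rows[0].u99_omega / rows[1].u99_omega
        # expect ~4 (sqrt of 16x replications), generously bracketed
        assert 2.0 < ratio < 8.0
        # the means agree within combined uncertainty at convergence
        assert abs(rows[0].mean_omega - rows[1].mean_omega) < (
            rows[0].u99_omega + rows[1].u99_omega
        ) * 1.5
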