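import logging

import numpy as np
import pytest

from clustercorr import (
    CCCConfig,
    ccc,
    ccc_matrix,
    ccc_pair,
    condensed_index,
    condensed_to_pair,
)
from clustercorr.partitioning import as_data_vector


class TestCCCPair:
    def test_perfect_monotone_relationship(self):
        x = np.arange(1, 21, dtype=float)
        result = ccc_pair(x, 2 * x)
        assert result.value == 1.0

    def test_symmetry_in_value(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal(60)
            y = rng.standard_normal(60)
            assert ccc_pair(x, y).value == ccc_pair(y, x).value

    def test_value_is_clamped_to_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            v = ccc_pair(rng.standard_normal(30), rng.standard_normal(30)).value
            assert 0.0 <= v <= 1.0

    def test_constant_variable_is_undefined_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="clustercorr"):
            result = ccc_pair(np.full(10, 3.0), np.arange(10.0))
        assert np.isnan(result.value)
        assert not result.is_defined
        assert "constant" in caplog.text

    def test_outlier_only_variable_scores_zero_not_undefined(self, anscombe_quartet):
        # ten identical values + one outlier: no valid quantile split exists,
        # but the variable is not constant, so the score is a hard 0
        result = ccc_pair(anscombe_quartet["IV"].x, anscombe_quartet["IV"].y)
        assert result.value == 0.0
        assert result.is_defined

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        assert ccc_pair(np.exp(x), y).value == pytest.approx(ccc_pair(x, y).value, abs=1e-14)

    def test_kmax_monotonicity(self):
        """The maximum over a superset of partition pairs cannot decrease."""
        rng = np.random.default_rng(13)
        for seed in range(3):
            r = np.random.default_rng(seed)
            x, y = r.standard_normal(50), r.standard_normal(50)
            vals = [ccc_pair(x, y, CCCConfig(kmax=k)).value for k in (2, 5, 10)]
            assert vals[0] <= vals[1] <= vals[2]

    def test_mixed_numerical_categorical_pair(self):
        # the single category partition is compared against every numerical one
        z = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        y = np.concatenate([np.zeros(30), np.ones(30)])
        result = ccc_pair(as_data_vector(z), as_data_vector(y))
        assert result.value == 1.0
        assert {result.kx, result.ky} == {2}

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ccc_pair(np.arange(5.0), np.arange(6.0))

    def test_missing_values_raise_by_default(self):
        x = np.array([1.0, np.nan, 3.0, 4.0])
        y = np.arange(4.0)
        with pytest.raises(ValueError):
            ccc_pair(x, y)

    def test_pairwise_complete_drops_missing_objects(self):
        x = np.concatenate([np.arange(20.0), [np.nan]])
        y = np.concatenate([np.arange(20.0), [99.0]])
        result = ccc_pair(x, y, na_action="pairwise_complete")
        assert result.value == ccc_pair(np.arange(20.0), np.arange(20.0)).value

    def test_single_pair_result_independent_of_jobs(self):
        rng = np.random.default_rng(23)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        r1 = ccc_pair(x, y, CCCConfig(jobs=1))
        r3 = ccc_pair(x, y, CCCConfig(jobs=3))
        assert r1.value == r3.value
        assert (r1.kx, r1.ky) == (r3.kx, r3.ky)

    def test_maximizing_partitions_are_reported(self):
        x = np.arange(1, 21, dtype=float)
        result = ccc_pair(x, 2 * x)
        assert result.labels_x is not None
        np.testing.assert_array_equal(result.labels_x, result.labels_y)
        assert result.kx == result.ky == 2  # smallest-complexity tie-break


class TestCondensedIndexing:
    def test_first_and_last_pairs(self):
        assert condensed_index(0, 1, 4) == 0
        assert condensed_index(2, 3, 4) == 5

    def test_round_trip_bijection(self):
        n = 10
        seen = set()
        for i in range(n):
            for j in range(i + 1, n):
                idx = condensed_index(i, j, n)
                assert condensed_to_pair(idx, n) == (i, j)
                seen.add(idx)
        assert seen == set(range(n * (n - 1) // 2))

    def test_invalid_pairs_error(self):
        with pytest.raises(ValueError):
            condensed_index(2, 2, 4)
        with pytest.raises(ValueError):
            condensed_index(3, 1, 4)
        with pytest.raises(ValueError):
            condensed_to_pair(6, 4)


class TestCCCMatrix:
    def test_condensed_length_and_pairwise_agreement(self):
        rng = np.random.default_rng(31)
        rows = [rng.standard_normal(40) for _ in range(3)]
        cm = ccc_matrix(rows)
        assert cm.condensed.shape == (3,)
        for i in range(3):
            for j in range(i + 1, 3):
                expected = ccc_pair(rows[i], rows[j])
                idx = condensed_index(i, j, 3)
                assert cm.condensed[idx] == expected.value
                assert (cm.kx[idx], cm.ky[idx]) == (expected.kx, expected.ky)

    def test_duplicated_row_scores_one(self):
        rng = np.random.default_rng(37)
        row = rng.standard_normal(40)
        cm = ccc_matrix([row, rng.standard_normal(40), row.copy()])
        assert cm.value(0, 2) == 1.0

    def test_output_identical_for_any_worker_count(self):
        rng = np.random.default_rng(41)
        rows = [rng.standard_normal(50) for _ in range(6)]
        serial = ccc_matrix(rows, CCCConfig(jobs=1))
        parallel = ccc_matrix(rows, CCCConfig(jobs=3))
        np.testing.assert_array_equal(serial.condensed, parallel.condensed)
        np.testing.assert_array_equal(serial.kx, parallel.kx)
        np.testing.assert_array_equal(serial.ky, parallel.ky)

    def test_constant_row_yields_nan_pairs_and_warning(self, caplog):
        rng = np.random.default_rng(43)
        with caplog.at_level(logging.WARNING, logger="clustercorr"):
            cm = ccc_matrix([np.full(30, 1.0), rng.standard_normal(30), rng.standard_normal(30)])
        assert np.isnan(cm.value(0, 1))
        assert np.isnan(cm.value(0, 2))
        assert not np.isnan(cm.value(1, 2))
        assert "constant" in caplog.text

    def test_ragged_rows_error(self):
        with pytest.raises(ValueError):
            ccc_matrix([np.arange(5.0), np.arange(6.0)])

    def test_square_form_is_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(47)
        cm = ccc_matrix([rng.standard_normal(30) for _ in range(4)])
        square = cm.to_square()
        np.testing.assert_array_equal(square.values, square.values.T)
        np.testing.assert_array_equal(np.diag(square.values), np.ones(4))


def test_ccc_convenience_wrapper():
    x = np.arange(30.0)
    assert ccc(x, x**3) == 1.0
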