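"""Applicability-domain math: standardization, outlier flags, Tanimoto."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qsarize as q
from conftest import make_matrix


def stats_from(values, names=None):
    return q.StandardizationStats.from_training(make_matrix(values, names))


class TestStandardize:
    def test_mean_maps_to_zero_and_one_sd_to_one(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(12, 2))
        stats = stats_from(train)
        probe = np.array([stats.means, stats.means + stats.sds])
        s = q.standardize(probe, stats)
        np.testing.assert_allclose(s[0], [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(s[1], [1.0, 1.0], atol=1e-12)

    def test_training_matrix_standardizes_to_unit_columns(self):
        rng = np.random.default_rng(1)
        train = rng.normal(loc=5.0, scale=3.0, size=(20, 4))
        s = q.standardize(train, stats_from(train))
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(s.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_affine_shift_consistency(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(15, 3))
        query = rng.normal(size=(4, 3))
        s0 = q.standardize(query, stats_from(train))
        c = np.array([10.0, -3.0, 0.5])
        s1 = q.standardize(query + c, stats_from(train + c))
        np.testing.assert_allclose(s0, s1, atol=1e-10)

    def test_descriptor_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        stats = stats_from(rng.normal(size=(10, 3)))
        other = make_matrix(rng.normal(size=(4, 3)), names=["A", "B", "C"])
        with pytest.raises(ValueError):
            q.standardize(other, stats)

    def test_zero_variance_training_rejected(self):
        vals = np.ones((8, 2))
        with pytest.raises(ValueError):
            stats_from(vals)


class TestAdFlags:
    def test_large_standardized_value_is_flagged_with_detail(self):
        s = np.array([[0.2, 8.63], [0.1, -0.5]])
        report = q.flag_ad_outliers(s, threshold=3.0,
                                    compound_ids=["n25", "n26"],
                                    descriptor_names=["d1", "d2"])
        assert list(report.outlier_flags) == [True, False]
        assert report.outlier_details == [("n25", "d2", 8.63)]

    def test_all_within_three_sd_no_flags(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(-2.9, 2.9, size=(10, 4))
        assert q.flag_ad_outliers(s, threshold=3.0).n_outliers == 0

    def test_boundary_value_is_flagged(self):
        report = q.flag_ad_outliers(np.array([[3.0]]), threshold=3.0)
        assert report.outlier_flags[0]

    def test_negative_values_count_by_magnitude(self):
        report = q.flag_ad_outliers(np.array([[-3.5]]), threshold=3.0)
        assert report.outlier_flags[0]

    def test_flags_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        s = rng.normal(scale=2.0, size=(30, 3))
        counts = [q.flag_ad_outliers(s, threshold=t).n_outliers
                  for t in (1.0, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestTanimoto:
    def test_identical_fingerprints(self):
        a = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        assert q.tanimoto(a, a) == 1.0

    def test_disjoint_fingerprints(self):
        a = np.array([1, 1, 0, 0], dtype=np.uint8)
        b = np.array([0, 0, 1, 1], dtype=np.uint8)
        assert q.tanimoto(a, b) == 0.0

    def test_closed_form_quarter(self):
        # N_a = 4, N_b = 6, N_ab = 2 -> 2 / (4 + 6 - 2) = 0.25
        a = np.zeros(16, dtype=np.uint8)
        b = np.zeros(16, dtype=np.uint8)
        a[:4] = 1
        b[2:8] = 1
        assert q.tanimoto(a, b) == pytest.approx(0.25)

    def test_all_zero_convention(self):
        z = np.zeros(8, dtype=np.uint8)
        assert q.tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            q.tanimoto(np.ones(4, dtype=np.uint8), np.ones(5, dtype=np.uint8))

    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.data())
    def test_symmetry_and_range(self, bits_a, data):
        bits_b = data.draw(st.lists(st.booleans(), min_size=len(bits_a),
                                    max_size=len(bits_a)))
        a = np.array(bits_a, dtype=np.uint8)
        b = np.array(bits_b, dtype=np.uint8)
        ab = q.tanimoto(a, b)
        assert ab == q.tanimoto(b, a)
        assert 0.0 <= ab <= 1.0


class TestSimilarityToTrain:
    @staticmethod
    def random_fps(n, n_bits, seed):
        rng = np.random.default_rng(seed)
        bits = (rng.random((n, n_bits)) < 0.3).astype(np.uint8)
        return q.FingerprintSet(compound_ids=[f"c{i}" for i in range(n)],
                                bits=bits, n_bits=n_bits)

    def test_matches_brute_force_double_loop(self):
        qf = self.random_fps(5, 64, seed=6)
        tf = self.random_fps(9, 64, seed=7)
        report = q.similarity_to_train(qf, tf)
        for i in range(5):
            for j in range(9):
                assert report.matrix[i, j] == pytest.approx(
                    q.tanimoto(qf.bits[i], tf.bits[j]), abs=1e-12)
        np.testing.assert_allclose(report.max, report.matrix.max(axis=1))
        np.testing.assert_allclose(report.mean, report.matrix.mean(axis=1))

    def test_query_present_in_training_has_max_one(self):
        tf = self.random_fps(6, 64, seed=8)
        qf = q.FingerprintSet(compound_ids=["probe"], bits=tf.bits[2:3],
                              n_bits=64)
        assert q.similarity_to_train(qf, tf).max[0] == 1.0

    def test_single_training_compound_collapses_summary(self):
        tf = self.random_fps(1, 32, seed=9)
        qf = self.random_fps(3, 32, seed=10)
        r = q.similarity_to_train(qf, tf)
        np.testing.assert_array_equal(r.max, r.min)
        np.testing.assert_array_equal(r.max, r.mean)

    def test_empty_training_set_rejected(self):
        qf = self.random_fps(2, 16, seed=11)
        empty = q.FingerprintSet(compound_ids=[], bits=np.zeros((0, 16)),
                                 n_bits=16)
        with pytest.raises(ValueError):
            q.similarity_to_train(qf, empty)
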