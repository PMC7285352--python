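import numpy as np
import pytest
from scipy import stats as sps

from lolichemo import (
    compute_stats,
    cross_validate,
    paired_t_test,
    rpd_ratio,
    t_outlier_elimination,
)
from lolichemo.errors import DomainError, GroupingError
from lolichemo.mpls import fit_mpls, predict


def _linear_problem(seed=0, n=30, p=20, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestCrossValidate:
    def test_perfect_linear_data_has_near_zero_secv(self):
        X, y = _linear_problem(0, n=40, p=10)
        cv = cross_validate(X, y, n_factors=10, n_groups=6, seed=1)
        assert cv.secv < 1e-6 * np.std(y)

    def test_leave_one_out_matches_brute_force_oracle(self):
        X, y = _linear_problem(1, n=12, p=8, noise=0.5)
        cv = cross_validate(X, y, n_factors=4, n_groups=12, seed=0)
        preds = np.empty(12)
        for i in range(12):
            mask = np.arange(12) != i
            m = fit_mpls(X[mask], y[mask], n_factors=4)
            preds[i] = predict(m, X[i][None, :])[0]
        np.testing.assert_allclose(np.sort(cv.predictions), np.sort(preds), atol=1e-9)
        np.testing.assert_allclose(
            cv.secv, np.sqrt(np.mean((y - preds) ** 2)), rtol=1e-9
        )

    def test_same_seed_reproduces_assignments_and_secv(self):
        X, y = _linear_problem(2, n=30, p=10, noise=0.3)
        a = cross_validate(X, y, n_factors=3, seed=7)
        b = cross_validate(X, y, n_factors=3, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.secv == b.secv

    def test_groups_are_balanced_and_exhaustive(self):
        X, y = _linear_problem(3, n=32, p=10, noise=0.3)
        cv = cross_validate(X, y, n_factors=3, n_groups=6, seed=0)
        counts = np.bincount(cv.assignments, minlength=6)
        assert counts.sum() == 32
        assert counts.max() - counts.min() <= 1

    def test_too_many_groups_is_an_error(self):
        X, y = _linear_problem(4, n=5, p=4, noise=0.1)
        with pytest.raises(GroupingError):
            cross_validate(X, y, n_factors=2, n_groups=6)


class TestTOutlierElimination:
    def test_clean_residuals_remove_nothing(self):
        X, y = _linear_problem(5, n=40, p=10, noise=0.2)
        keep, cv, removed = t_outlier_elimination(X, y, n_factors=8, seed=0)
        assert removed == []
        assert keep.size == 40

    def test_corrupted_reference_is_removed_in_round_one(self):
        X, y = _linear_problem(6, n=40, p=10, noise=0.2)
        y = y.copy()
        y[17] += 10 * np.std(y)
        keep, cv, removed = t_outlier_elimination(
            X, y, n_factors=8, seed=0, sample_index=np.arange(40)
        )
        assert 17 in removed[0]
        assert 17 not in keep

    def test_zero_rounds_is_identity(self):
        X, y = _linear_problem(7, n=30, p=10, noise=0.2)
        y = y.copy()
        y[3] += 10 * np.std(y)
        keep, cv, removed = t_outlier_elimination(X, y, max_rounds=0, n_factors=5, seed=0)
        assert keep.size == 30
        assert removed == []

    def test_at_most_two_rounds(self):
        X, y = _linear_problem(8, n=50, p=10, noise=1.0)
        _, _, removed = t_outlier_elimination(X, y, n_factors=5, seed=0)
        assert len(removed) <= 2


class TestComputeStats:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = compute_stats(y, y, context="internal_validation", n_factors=1)
        assert s.rsq == pytest.approx(1.0)
        assert s.sep == pytest.approx(0.0)
        assert s.bias == pytest.approx(0.0)
        assert s.t_test_p == 1.0

    def test_constant_shift_gives_pure_bias(self):
        rng = np.random.default_rng(9)
        y = rng.standard_normal(20)
        s = compute_stats(y, y + 2.0, context="external_validation")
        assert s.bias == pytest.approx(-2.0)
        assert s.sepc == pytest.approx(0.0, abs=1e-12)
        assert s.rsq == pytest.approx(1.0)

    def test_sep_sepc_bias_formula_identity(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(25)
        pred = y + 0.3 * rng.standard_normal(25) + 0.1
        s = compute_stats(y, pred, context="external_validation")
        n = s.n
        sse = n * s.sep**2
        assert s.sepc**2 * (n - 1) + n * s.bias**2 == pytest.approx(sse, rel=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        y = rng.standard_normal(30)
        pred = y + 0.2 * rng.standard_normal(30)
        a = compute_stats(y, pred, context="external_validation")
        b = compute_stats(y + 100.0, pred + 100.0, context="external_validation")
        for attr in ("sd", "rsq", "bias", "sep", "sepc", "rmse"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), rel=1e-9)

    def test_calibration_context_uses_dof_corrected_sec(self):
        rng = np.random.default_rng(12)
        y = rng.standard_normal(20)
        pred = y + 0.5 * rng.standard_normal(20)
        s = compute_stats(y, pred, context="calibration", n_factors=4)
        sse = ((y - pred) ** 2).sum()
        assert s.sec == pytest.approx(np.sqrt(sse / (20 - 4 - 1)))
        assert s.sep is None

    def test_zero_variance_is_rejected(self):
        with pytest.raises(DomainError):
            compute_stats(np.ones(5), np.arange(5.0))


class TestRPD:
    def test_ratio(self):
        assert rpd_ratio(1008.0, 310.0) == pytest.approx(3.252, abs=1e-3)

    def test_zero_error_is_rejected(self):
        with pytest.raises(DomainError):
            rpd_ratio(1.0, 0.0)

    def test_secv_variant(self):
        rng = np.random.default_rng(13)
        y = rng.standard_normal(20) * 100
        pred = y + 5 * rng.standard_normal(20)
        s = compute_stats(
            y, pred, context="internal_validation", secv=8.0, rpd_denominator="secv"
        )
        assert s.rpd == pytest.approx(np.std(y, ddof=1) / 8.0)


class TestPairedTTest:
    def test_identical_vectors_give_p_one(self):
        y = np.arange(5.0)
        assert paired_t_test(y, y) == 1.0

    def test_known_differences_match_t_distribution_oracle(self):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        pred = ref - np.array([1.0, 2.0, 3.0, 4.0])
        d = ref - pred
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        p_oracle = 2 * sps.t.sf(abs(t_stat), df=3)
        assert paired_t_test(ref, pred) == pytest.approx(p_oracle, rel=1e-12)

    def test_single_pair_is_an_error(self):
        with pytest.raises(DomainError):
            paired_t_test([1.0], [2.0])
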