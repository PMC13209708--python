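"""OLS engine, LOO Q², best-subset search, and the frozen published model."""

import numpy as np
import pytest

from sunqsar.data import CompoundRecord
from sunqsar.mlr import (
    FitError,
    FitStats,
    LinearModel,
    PUBLISHED_MODEL,
    aggregate_means,
    best_subset_search,
    evaluate_test,
    fit_ols,
    predict_published,
    q2_loo,
    round_half_up,
)
from tests.conftest import PRINTED_PREDICTIONS


def ols_normal_equations(X, y):
    """Independent oracle: explicit normal equations with classical SEs."""
    n, k = X.shape
    D = np.column_stack([np.ones(n), X])
    XtX = D.T @ D
    beta = np.linalg.solve(XtX, D.T @ y)
    resid = y - D @ beta
    sigma2 = resid @ resid / (n - k - 1)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se


def loo_brute_force(X, y):
    """Independent oracle: refit n times, one point left out each time."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        D = np.column_stack([np.ones(keep.sum()), X[keep]])
        beta = np.linalg.lstsq(D, y[keep], rcond=None)[0]
        pred = np.concatenate([[1.0], X[i]]) @ beta
        press += (y[i] - pred) ** 2
    tss = np.sum((y - y.mean()) ** 2)
    return 1 - press / tss


class TestFitOls:
    def test_exact_linear_data(self):
        x = np.linspace(0, 5, 12).reshape(-1, 1)
        m = fit_ols((x, 2 + 3 * x[:, 0]), subset=("x",))
        assert m.intercept == pytest.approx(2.0, abs=1e-10)
        assert m.coef["x"][0] == pytest.approx(3.0, abs=1e-10)
        assert m.stats.r2 == pytest.approx(1.0)

    def test_minimal_n_has_finite_stats(self, rng):
        X = rng.standard_normal((5, 3))  # n = k + 2
        y = rng.standard_normal(5)
        m = fit_ols((X, y), subset=("a", "b", "c"))
        assert np.isfinite(m.intercept_se)
        assert all(np.isfinite(se) for _, se in m.coef.values())
        assert np.isfinite(m.stats.r2_adj)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((40, 3))
            beta_true = np.array([1.0, -2.0, 0.5])
            y = 0.3 + X @ beta_true + 0.5 * rng.standard_normal(40)
            m = fit_ols((X, y), subset=("a", "b", "c"))
            beta, se = ols_normal_equations(X, y)
            assert m.intercept == pytest.approx(beta[0], abs=1e-8)
            for i, nm in enumerate(("a", "b", "c")):
                assert m.coef[nm][0] == pytest.approx(beta[i + 1], abs=1e-8)
                assert m.coef[nm][1] == pytest.approx(se[i + 1], abs=1e-8)
                # estimate within 3 SE of truth
                assert abs(m.coef[nm][0] - beta_true[i]) < 3 * m.coef[nm][1]

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((20, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(FitError, match="collinear"):
            fit_ols((X, rng.standard_normal(20)), subset=("a", "b", "dup"))


class TestQ2Loo:
    def test_noise_free_is_one(self):
        x = np.linspace(0, 1, 15).reshape(-1, 1)
        assert q2_loo((x, 1 + 2 * x[:, 0]), subset=("x",)) == pytest.approx(1.0)

    def test_unrelated_response_not_predictive(self, rng):
        X = rng.standard_normal((500, 3))
        y = rng.standard_normal(500)
        assert q2_loo((X, y), subset=("a", "b", "c")) < 0.1

    def test_matches_brute_force_refits(self, rng):
        X = rng.standard_normal((25, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + rng.standard_normal(25)
        got = q2_loo((X, y), subset=("a", "b", "c"))
        assert got == pytest.approx(loo_brute_force(X, y), abs=1e-8)


class TestEvaluateTest:
    def test_perfect_predictions(self):
        x = np.array([[1.0], [2.0]])
        m = fit_ols((np.linspace(0, 3, 10).reshape(-1, 1),
                     2 * np.linspace(0, 3, 10)), subset=("x",))
        assert evaluate_test(m, (x, 2 * x[:, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_single_point_offset(self):
        m = LinearModel(names=("x",), intercept=0.0, intercept_se=0.0,
                        coef={"x": (1.0, 0.0)})
        assert evaluate_test(m, (np.array([[2.0]]), np.array([2.59])
                                 )) == pytest.approx(0.59)

    def test_noise_scale_recovered(self, rng):
        # 21 points with N(0, 0.6^2) errors: RMSE near 0.6
        m = LinearModel(names=("x",), intercept=0.0, intercept_se=0.0,
                        coef={"x": (1.0, 0.0)})
        x = rng.standard_normal((21, 1))
        y = x[:, 0] + 0.6 * rng.standard_normal(21)
        assert 0.4 < evaluate_test(m, (x, y)) < 0.8

    def test_empty_test_set_rejected(self):
        m = LinearModel(names=("x",), intercept=0.0, intercept_se=0.0,
                        coef={"x": (1.0, 0.0)})
        with pytest.raises(FitError):
            evaluate_test(m, (np.empty((0, 1)), np.empty(0)))


class TestFitStatsConsistency:
    def test_published_statistics_self_consistent(self):
        # adjusted R^2 and F recomputed from the printed R^2, n, k
        assert FitStats.adjusted_r2(0.706, 100, 6) == pytest.approx(0.687,
                                                                    abs=1e-3)
        assert FitStats.f_statistic(0.706, 100, 6) == pytest.approx(37.15,
                                                                    abs=0.15)


class TestBestSubsetSearch:
    def test_single_candidate_pool(self, rng):
        X = rng.standard_normal((30, 2))
        y = X @ np.array([1.0, 2.0]) + 0.1 * rng.standard_normal(30)
        res = best_subset_search((X, y), pool=("a", "b"), kmin=2, kmax=2)
        assert res.ranked == [(("a", "b"), pytest.approx(res.ranked[0][1]))]
        assert res.best_model.stats.r2 > 0.9

    def test_duplicated_column_never_retained_together(self, rng):
        X = rng.standard_normal((50, 3))
        X = np.column_stack([X, X[:, 0]])
        y = X[:, 0] + X[:, 1] + 0.2 * rng.standard_normal(50)
        res = best_subset_search((X, y), pool=("a", "b", "c", "a_copy"),
                                 kmin=2, kmax=4)
        for subset, _ in res.ranked:
            assert not {"a", "a_copy"} <= set(subset)

    def test_recovers_generating_descriptors(self, rng):
        n = 500
        X = rng.standard_normal((n, 6))  # 3 informative + 3 pure noise
        y = X[:, :3] @ np.array([1.0, -1.5, 0.8]) + 0.5 * rng.standard_normal(n)
        res = best_subset_search((X, y), pool=tuple("abcdef"), kmin=3, kmax=3)
        assert set(res.best_subset) == {"a", "b", "c"}
        # and with the size range open, every true descriptor is retained
        open_res = best_subset_search((X, y), pool=tuple("abcdef"),
                                      kmin=2, kmax=6)
        assert {"a", "b", "c"} <= set(open_res.best_subset)

    def test_empty_admissible_set_rejected(self, rng):
        x = rng.standard_normal(40)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(FitError, match="tolerance"):
            best_subset_search((X, x), pool=("a", "a2"), kmin=2, kmax=2)


class TestPublishedModel:
    def test_reproduces_printed_predictions(self, sunscreens):
        for rec in sunscreens:
            printed_mlr = PRINTED_PREDICTIONS[rec.id][0]
            assert predict_published(rec) == pytest.approx(printed_mlr,
                                                           abs=0.02), rec.id

    def test_all_zero_descriptors_give_intercept(self):
        rec = {n: 0.0 for n in PUBLISHED_MODEL.names}
        assert predict_published(rec) == pytest.approx(1.68)

    def test_missing_descriptor_named(self):
        rec = CompoundRecord(id="partial", descriptors={"nRot": 3.0})
        with pytest.raises(FitError, match="Flex"):
            predict_published(rec)

    def test_serialization_round_trip(self):
        back = LinearModel.from_json(PUBLISHED_MODEL.to_json())
        assert back.names == PUBLISHED_MODEL.names
        assert back.coef == PUBLISHED_MODEL.coef
        assert back.stats.r2 == PUBLISHED_MODEL.stats.r2


class TestAggregateMeans:
    def test_printed_mean_rows(self):
        ocr = aggregate_means({"MLR": 6.13, "ANN1": 5.78, "SVR": 5.91},
                              {"mean1": ("MLR", "ANN1", "SVR")})
        assert round_half_up(ocr["mean1"]) == 5.94
        dhhb = aggregate_means({"MLR": 5.57, "ANN1": 4.97, "SVR": 5.37},
                               {"mean1": ("MLR", "ANN1", "SVR")})
        assert dhhb["mean1"] == pytest.approx(5.3033, abs=1e-4)
        assert round_half_up(dhhb["mean1"]) == 5.30

    def test_identical_predictions_unchanged(self):
        out = aggregate_means({"MLR": 4.2, "ANN1": 4.2, "SVR": 4.2},
                              {"mean1": ("MLR", "ANN1", "SVR")})
        assert out["mean1"] == pytest.approx(4.2)

    def test_missing_member_rejected(self):
        with pytest.raises(FitError, match="SVR"):
            aggregate_means({"MLR": 4.0, "ANN1": 4.1},
                            {"mean1": ("MLR", "ANN1", "SVR")})
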