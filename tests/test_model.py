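import numpy as np
import pytest

from mixproc import (
    FitResult,
    ModelSpec,
    RunCondition,
    anova_regression,
    fit_response,
    predict,
    replicate_variance,
    simulate_responses,
)
from mixproc.dataset import ResponseRecord, StudyDataset
from mixproc.design import matrix_from_arrays, model_matrix
from mixproc.errors import ArgumentError, DataError, DegenerateResponseError, FittingError


class TestFixtureFit:
    """The model-validation fit uses the 63 distinct design runs; the
    printed summary statistics are reproduced exactly on that subset."""

    def test_r2_ps(self, fits63):
        assert round(fits63["ps_nm"].r2, 2) == 0.80

    def test_r2_pdi(self, fits63):
        assert round(fits63["pdi"].r2, 2) == 0.67

    def test_r2_zp(self, fits63):
        assert round(fits63["zp_abs_mv"].r2, 2) == 0.98

    def test_p_values_printed_as_percentages(self, fits63):
        # the reported p values are percentages: 0.0005, 0.4199, <=0.0000
        assert round(fits63["ps_nm"].p_value * 100, 4) == 0.0005
        assert round(fits63["pdi"].p_value * 100, 4) == 0.4199
        assert round(fits63["zp_abs_mv"].p_value * 100, 4) == 0.0

    def test_zp_significance(self, fits63):
        assert fits63["zp_abs_mv"].p_value <= 1e-4

    def test_df_resid_66(self, fits66):
        assert all(f.df_resid == 66 - 28 for f in fits66.values())
        assert all(f.df_model == 27 for f in fits66.values())

    def test_residual_orthogonality(self, dataset, fits66, spec28):
        X = model_matrix([rec.condition for rec in dataset], spec28)
        for fit in fits66.values():
            scale = np.abs(X).max() * np.abs(fit.residuals).max()
            assert np.max(np.abs(X.T @ fit.residuals)) <= 1e-6 * max(scale, 1.0)

    def test_r2_in_unit_interval(self, fits66, fits63):
        for fits in (fits66, fits63):
            for f in fits.values():
                assert 0.0 <= f.r2 <= 1.0


class TestOlsOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations(self, seed):
        # independent oracle: explicit normal-equations solve
        rng = np.random.default_rng(seed)
        n, p = 30, 10
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(scale=0.3, size=n)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        ours, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(ours, oracle, atol=1e-8)

    def test_fit_matches_normal_equations_on_design(self, dataset63, spec7):
        X = model_matrix([rec.condition for rec in dataset63], spec7)
        y = dataset63.response_values("pdi")
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_response(dataset63, spec7, "pdi")
        np.testing.assert_allclose(fit.coeffs, oracle, atol=1e-8)


class TestFitContracts:
    def test_scale_equivariance(self, dataset63, spec28):
        fit1 = fit_response(dataset63, spec28, "ps_nm")
        scaled = StudyDataset(
            tuple(
                ResponseRecord(r.run_id, r.condition, ps_nm=r.ps_nm * 3.0)
                for r in dataset63
            )
        )
        fit3 = fit_response(scaled, spec28, "ps_nm")
        np.testing.assert_allclose(fit3.coeffs, 3.0 * fit1.coeffs, rtol=1e-10)
        assert fit3.r2 == pytest.approx(fit1.r2, rel=1e-12)
        assert fit3.f_stat == pytest.approx(fit1.f_stat, rel=1e-10)
        assert fit3.p_value == pytest.approx(fit1.p_value, rel=1e-8)

    def test_prediction_at_design_run_is_fitted_value(self, dataset63, fits63):
        fit = fits63["ps_nm"]
        for i in (0, 17, 62):
            rec = dataset63.records[i]
            assert predict(fit, rec.condition) == pytest.approx(
                rec.ps_nm - fit.residuals[i], abs=1e-9
            )

    def test_predictions_invariant_to_process_coding(self, dataset63, spec28):
        # oracle: refit with process factors coded to [0, 1] instead of [-1, 1]
        fit = fit_response(dataset63, spec28, "ps_nm")
        conds = [rec.condition for rec in dataset63]
        p80 = np.array([c.p80_pct for c in conds])
        us = np.array([c.us_time_min for c in conds])
        blend = np.array([c.blend for c in conds])
        X01 = matrix_from_arrays(
            p80 / 100.0, (us - 1.0) / 9.0, blend[:, 0], blend[:, 1], blend[:, 2], spec28
        )
        beta01 = np.linalg.solve(X01.T @ X01, X01.T @ dataset63.response_values("ps_nm"))
        rng = np.random.default_rng(3)
        probe_b = rng.dirichlet((1, 1, 1), size=100)
        probe_p = rng.uniform(0, 100, size=100)
        probe_u = rng.uniform(1, 10, size=100)
        ours = fit.evaluate_batch(probe_p, probe_u, probe_b)
        theirs = matrix_from_arrays(
            probe_p / 100.0, (probe_u - 1.0) / 9.0,
            probe_b[:, 0], probe_b[:, 1], probe_b[:, 2], spec28,
        ) @ beta01
        np.testing.assert_allclose(ours, theirs, rtol=1e-6, atol=1e-6)

    def test_perfect_fit_r2_one(self, spec7):
        from mixproc import cross_design, process_grid, simplex_centroid_points

        design = list(
            cross_design(simplex_centroid_points(), process_grid((0, 100), (1, 10)))
        )
        beta = np.arange(1.0, 8.0) * 10
        ds = simulate_responses(design, spec7, {"ps_nm": beta}, 0.0, seed=0)
        fit = fit_response(ds, spec7, "ps_nm")
        f, p, r2 = anova_regression(fit)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-100

    def test_constant_response_degenerate(self, spec7):
        from mixproc import cross_design, process_grid, simplex_centroid_points

        design = list(
            cross_design(simplex_centroid_points(), process_grid((0, 100), (1, 10)))
        )
        recs = tuple(
            ResponseRecord(str(i), c, ps_nm=100.0) for i, c in enumerate(design)
        )
        fit = fit_response(StudyDataset(recs), spec7, "ps_nm")
        with pytest.raises(DegenerateResponseError):
            anova_regression(fit)

    def test_rank_deficiency_names_terms(self, spec28):
        # a single process setting leaves every x1-, x2-crossed column constant
        blends = [
            (1, 0, 0), (0, 1, 0), (0, 0, 1), (0.5, 0.5, 0), (0.5, 0, 0.5),
            (0, 0.5, 0.5), (1 / 3, 1 / 3, 1 / 3), (0.2, 0.3, 0.5), (0.6, 0.2, 0.2),
        ] * 4
        recs = tuple(
            ResponseRecord(str(i), RunCondition(50, 5, b), ps_nm=float(100 + i))
            for i, b in enumerate(blends)
        )
        with pytest.raises(FittingError, match="collinear"):
            fit_response(StudyDataset(recs), spec28, "ps_nm")

    def test_too_few_rows(self, spec28):
        recs = tuple(
            ResponseRecord(str(i), RunCondition(0, 1, (1, 0, 0)), ps_nm=100.0)
            for i in range(5)
        )
        with pytest.raises(ArgumentError):
            fit_response(StudyDataset(recs), spec28, "ps_nm")

    def test_unknown_response(self, dataset, spec28):
        with pytest.raises(ArgumentError):
            fit_response(dataset, spec28, "turbidity")


class TestReplicateVariance:
    def test_fixture_ps(self, dataset):
        # hand-applied pooled-pairs formula on (113.9, 111.2), (98.83, 131.2),
        # (142.3, 128.3): ((2.7^2 + 32.37^2 + 14.0^2) / 2) / 3
        s2, df = replicate_variance(dataset, "ps_nm")
        expected = ((2.7**2 + 32.37**2 + 14.0**2) / 2) / 3
        assert s2 == pytest.approx(expected, rel=1e-9)
        assert s2 == pytest.approx(208.5, abs=0.1)
        assert df == 3

    def test_fixture_df_all_responses(self, dataset):
        for response in ("ps_nm", "pdi", "zp_abs_mv"):
            _, df = replicate_variance(dataset, response)
            assert df == 3

    def test_identical_replicates_zero(self):
        c = RunCondition(50, 5, (1, 0, 0))
        recs = (
            ResponseRecord("1", c, ps_nm=120.0),
            ResponseRecord("1r", c, ps_nm=120.0),
        )
        s2, df = replicate_variance(StudyDataset(recs), "ps_nm")
        assert s2 == 0.0 and df == 1

    def test_no_replicates_rejected(self, dataset63):
        with pytest.raises(DataError):
            replicate_variance(dataset63, "ps_nm")


class TestSerialization:
    def test_yaml_round_trip(self, fits63):
        fit = fits63["zp_abs_mv"]
        back = FitResult.from_yaml(fit.to_yaml())
        np.testing.assert_allclose(back.coeffs, fit.coeffs)
        assert back.r2 == pytest.approx(fit.r2)
        assert back.p_value == pytest.approx(fit.p_value)
        cond = RunCondition(40.8, 7.5, (0.59, 0.22, 0.19))
        assert predict(back, cond) == pytest.approx(predict(fit, cond))

    def test_round_trip_stable(self, fits63):
        text = fits63["pdi"].to_yaml()
        assert FitResult.from_yaml(text).to_yaml() == text


class TestParameterRecovery:
    def test_unbiased_at_experimental_noise(self, dataset63, spec28, fits63):
        # bias over seeded simulations at the replicate s.d. stays within
        # 3 Monte-Carlo standard errors of zero for every coefficient
        design = [rec.condition for rec in dataset63]
        beta = fits63["ps_nm"].coeffs.copy()
        beta[:3] += 500  # shift predictions clear of the positivity clip
        sd = 14.4  # ~sqrt of the pooled replicate variance
        n_sim = 200
        estimates = np.empty((n_sim, len(beta)))
        for k in range(n_sim):
            ds = simulate_responses(design, spec28, {"ps_nm": beta}, sd, seed=1000 + k)
            estimates[k] = fit_response(ds, spec28, "ps_nm").coeffs
        bias = estimates.mean(axis=0) - beta
        mc_se = estimates.std(axis=0, ddof=1) / np.sqrt(n_sim)
        assert np.all(np.abs(bias) <= 3.0 * mc_se)
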