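"""REML engine: design bookkeeping, likelihood correctness, fit behavior.

The restricted likelihood is validated against a dense multivariate-normal
oracle that materialises the full marginal covariance; fit-level agreement
with lme4 lives in test_reference.py.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trilevel as tl
from trilevel.lmm import VarianceComponents, _gls_pieces

from oracles import (
    dense_design,
    dense_marginal_covariance,
    dense_restricted_deviance,
)


@pytest.fixture(scope="module")
def tiny_pop():
    """4 classes x 3 students x 5 occasions = 60 rows, both classtypes."""
    structure = tl.PopulationStructure(classes_per_stratum=4, strata_sizes=(3,))
    pop = tl.generate_population(tl.PopulationParams(), structure, seed=12)
    assert pop.drop_duplicates("class_id")["classtype"].nunique() == 2
    return pop


class TestBuildDesign:
    def test_dimensional_bookkeeping(self):
        structure = tl.PopulationStructure(classes_per_stratum=1, strata_sizes=(2,))
        pop = tl.generate_population(structure=structure, seed=5)
        bundle = tl.build_design(pop, tl.FULL_MODEL)
        assert bundle.n_classes == 1 and bundle.n_students == 2
        blk = bundle.blocks[0]
        assert blk.X.shape == (10, 9)
        assert len(blk.signature) == 2  # two students ...
        assert all(len(s) == 5 for s in blk.signature)  # ... five occasions each

    def test_empty_model_design_is_intercept_only(self, tiny_pop):
        bundle = tl.build_design(tiny_pop, tl.EMPTY_MODEL)
        assert bundle.blocks[0].X.shape[1] == 1
        assert np.all(bundle.blocks[0].X == 1.0)

    def test_single_row_student_supported(self, tiny_pop):
        # post-missingness a student may retain one occasion
        key = tiny_pop["class_id"].astype(str) + "/" + tiny_pop["student_id"].astype(str)
        drop = (key == "0/0") & (tiny_pop["occasion_index"] > 0)
        reduced = tiny_pop.loc[~drop]
        bundle = tl.build_design(reduced, tl.FULL_MODEL)
        assert bundle.n_obs == len(tiny_pop) - 4
        assert min(len(s) for s in bundle.blocks[0].signature) == 1
        fit = tl.fit_lmm(reduced)
        assert fit.converged

    def test_missing_column_is_schema_error(self, tiny_pop):
        with pytest.raises(ValueError, match="missing required columns"):
            tl.build_design(tiny_pop.drop(columns=["influence"]), tl.FULL_MODEL)


CANDIDATES = [
    VarianceComponents(0.25, 0.20, 0.001, 0.004, 0.0002),
    VarianceComponents(0.40, 0.05, 0.01, 0.05, 0.002),
    VarianceComponents(1.30, 0.90, 0.08, 0.30, 0.01),
    VarianceComponents(0.25, 0.20, 0.0, 0.0, 0.0),
]


class TestRemlDeviance:
    @pytest.mark.parametrize("vc", CANDIDATES)
    @pytest.mark.parametrize("method", ["REML", "ML"])
    def test_agrees_with_dense_oracle(self, tiny_pop, vc, method):
        bundle = tl.build_design(tiny_pop, tl.FULL_MODEL)
        dev = tl.reml_deviance(vc, bundle, method=method)
        V = dense_marginal_covariance(
            tiny_pop, vc.resid, vc.l2_intercept, vc.l2_slope,
            vc.l3_intercept, vc.l3_slope,
        )
        dense = dense_restricted_deviance(
            tiny_pop, tl.FULL_MODEL.fixed_terms, V, method=method
        )
        assert dev == pytest.approx(dense, abs=1e-6)

    def test_zero_random_variances_reduce_to_ols_restricted_likelihood(self, tiny_pop):
        sigma2 = 0.3
        vc = VarianceComponents(sigma2, 0.0, 0.0, 0.0, 0.0)
        bundle = tl.build_design(tiny_pop, tl.FULL_MODEL)
        dev = tl.reml_deviance(vc, bundle)
        df = tiny_pop.sort_values(["class_id", "student_id", "time"])
        X = dense_design(df)
        y = df["motivation"].to_numpy()
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(np.sum((y - X @ beta) ** 2))
        closed = (
            (n - p) * np.log(2 * np.pi)
            + (n - p) * np.log(sigma2)
            + np.linalg.slogdet(X.T @ X)[1]
            + rss / sigma2
        )
        assert dev == pytest.approx(closed, abs=1e-8)

    def test_scaling_shifts_deviance_by_jacobian_term(self, tiny_pop):
        # scaling the response and every scale-bearing parameter by c
        # changes -2 log L_R by exactly (n - p) log c^2
        c = 3.0
        vc = CANDIDATES[0]
        scaled_vc = VarianceComponents(
            vc.resid * c**2, vc.l2_intercept * c**2, vc.l2_slope * c**2,
            vc.l3_intercept * c**2, vc.l3_slope * c**2,
        )
        scaled_pop = tiny_pop.assign(motivation=tiny_pop["motivation"] * c)
        bundle = tl.build_design(tiny_pop, tl.FULL_MODEL)
        scaled_bundle = tl.build_design(scaled_pop, tl.FULL_MODEL)
        n, p = bundle.n_obs, len(tl.FULL_MODEL.fixed_terms)
        shift = tl.reml_deviance(scaled_vc, scaled_bundle) - tl.reml_deviance(vc, bundle)
        assert shift == pytest.approx((n - p) * np.log(c**2), abs=1e-8)

    def test_nonpositive_resid_rejected(self, tiny_pop):
        bundle = tl.build_design(tiny_pop, tl.FULL_MODEL)
        with pytest.raises(ValueError):
            tl.reml_deviance(VarianceComponents(0.0, 0.1), bundle)


class TestFitLmm:
    def test_zero_variance_data_matches_ols(self):
        params = tl.PopulationParams(
            var_l2_intercept=0, var_l2_slope=0, var_l3_intercept=0, var_l3_slope=0
        )
        structure = tl.PopulationStructure(classes_per_stratum=10, strata_sizes=(6,))
        pop = tl.generate_population(params, structure, seed=21)
        fit = tl.fit_lmm(pop)
        df = pop.sort_values(["class_id", "student_id", "time"])
        X = dense_design(df)
        beta = np.linalg.lstsq(X, df["motivation"].to_numpy(), rcond=None)[0]
        est = np.array([fit.coefficients[t] for t in tl.FULL_MODEL.fixed_terms])
        np.testing.assert_allclose(est, beta, rtol=1e-5, atol=1e-7)
        assert fit.singular  # all random SDs at the zero boundary

    def test_permutation_invariance(self, small_population):
        cond = tl.Condition(n2=15, n3=10, pattern="COM")
        sample = tl.draw_sample(small_population, cond, np.random.default_rng(2))
        shuffled = sample.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = tl.fit_lmm(sample)
        b = tl.fit_lmm(shuffled)
        for t in tl.FULL_MODEL.fixed_terms:
            assert a.coefficients[t] == pytest.approx(b.coefficients[t], abs=1e-8)
        assert a.varcomps.resid == pytest.approx(b.varcomps.resid, abs=1e-8)

    def test_profiling_identity(self, tiny_pop):
        # GLS fixed effects recomputed from the returned variance components
        # reproduce the returned coefficients
        fit = tl.fit_lmm(tiny_pop)
        V = dense_marginal_covariance(
            tiny_pop,
            fit.varcomps.resid,
            fit.varcomps.l2_intercept,
            fit.varcomps.l2_slope,
            fit.varcomps.l3_intercept,
            fit.varcomps.l3_slope,
        )
        df = tiny_pop.sort_values(["class_id", "student_id", "time"]).reset_index(drop=True)
        X = dense_design(df)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["motivation"].to_numpy())
        est = np.array([fit.coefficients[t] for t in tl.FULL_MODEL.fixed_terms])
        np.testing.assert_allclose(est, beta, rtol=1e-6, atol=1e-8)

    def test_per_cluster_equals_dense_at_optimum(self, tiny_pop):
        fit = tl.fit_lmm(tiny_pop)
        bundle = tl.build_design(tiny_pop, tl.FULL_MODEL)
        dev = tl.reml_deviance(fit.varcomps, bundle)
        assert dev == pytest.approx(-2 * fit.log_restricted_likelihood, abs=1e-6)

    def test_too_few_rows_rejected(self, tiny_pop):
        with pytest.raises(ValueError, match="needs more"):
            tl.fit_lmm(tiny_pop.head(8))

    def test_fit_result_json_roundtrip(self, tiny_pop, tmp_path):
        fit = tl.fit_lmm(tiny_pop)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["n_obs"] == 60
        assert payload["varcomps"]["resid"] == pytest.approx(fit.varcomps.resid)

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            tl.ModelSpec(fixed_terms=("time",))
        with pytest.raises(ValueError):
            tl.ModelSpec(random_l2=("time",))
        with pytest.raises(ValueError):
            tl.ModelSpec(method="PQL")


class TestWaldCI:
    def test_quantile_arithmetic(self):
        fit = _fake_fit({"time": 1.0}, {"time": 0.5})
        ci = tl.wald_ci(fit, alpha=0.05)
        lo, hi = ci["time"]
        assert lo == pytest.approx(0.0200, abs=1e-4)
        assert hi == pytest.approx(1.9800, abs=1e-4)

    def test_zero_se_degenerates_to_point(self):
        fit = _fake_fit({"time": 0.7}, {"time": 0.0})
        ci = tl.wald_ci(fit)
        assert ci["time"] == (0.7, 0.7)

    def test_one_third_alpha_is_about_one_se(self):
        fit = _fake_fit({"time": 0.0}, {"time": 1.0})
        ci = tl.wald_ci(fit, alpha=0.32)
        half = ci["time"][1]
        assert half == pytest.approx(1.0, rel=0.01)
        assert half == pytest.approx(stats.norm.ppf(0.84), abs=1e-9)

    def test_alpha_out_of_range(self):
        fit = _fake_fit({"time": 0.0}, {"time": 1.0})
        for alpha in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                tl.wald_ci(fit, alpha=alpha)


def _fake_fit(coefficients, std_errors):
    return tl.FitResult(
        coefficients=coefficients,
        std_errors=std_errors,
        varcomps=VarianceComponents(resid=1.0, l2_intercept=0.0),
        log_restricted_likelihood=0.0,
        converged=True,
        singular=False,
        n_obs=10,
        n_students=2,
        n_classes=1,
    )
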