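import warnings

import numpy as np
import pytest

import oracles
from ocdim.datasets import DomainMap, ItemResponseMatrix
from ocdim.latent_models import (
    LatentParams,
    ModelSpec,
    compare_models,
    eap_scores_binary,
    fit_latent_model,
    leave_one_domain_out,
    marginal_loglik,
    standardized_loadings,
)
from ocdim.simulate import simulate_bifactor_responses


def _mat(values, prefix="p"):
    n, j = values.shape
    return ItemResponseMatrix(
        [f"{prefix}{i}" for i in range(n)], [f"i{k}" for k in range(j)], values
    )


def _two_domain_map(item_ids, split):
    return DomainMap(
        {
            i: ("doubt_checking" if k < split else "taboo")
            for k, i in enumerate(item_ids)
        },
        strict=False,
    )


class TestMarginalLoglikOracle:
    def test_single_symmetric_item_gives_log_half(self):
        data = _mat(np.array([[1.0]]))
        params = LatentParams(
            "unidimensional", "binary_2pl", ["i0"], np.array([1.0]), np.array([0.0])
        )
        ll = marginal_loglik(params, data, spec=ModelSpec(n_quad=61))
        assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_zero_slopes_factor_out_the_trait(self):
        rng = np.random.default_rng(0)
        Y = (rng.random((6, 4)) < 0.5).astype(float)
        params = LatentParams(
            "unidimensional",
            "binary_2pl",
            [f"i{k}" for k in range(4)],
            np.zeros(4),
            np.zeros(4),
        )
        ll = marginal_loglik(params, _mat(Y), spec=ModelSpec(n_quad=21))
        assert ll == pytest.approx(24 * np.log(0.5), abs=1e-10)

    def test_unidimensional_matches_dense_grid(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.5, 2.0, 3)
        c = rng.normal(0, 1, 3)
        Y = np.array([[1, 0, 1], [0, 0, 0], [1, 1, 1], [0, 1, np.nan]], dtype=float)
        params = LatentParams(
            "unidimensional", "binary_2pl", [f"i{k}" for k in range(3)], a, c
        )
        ll = marginal_loglik(params, _mat(Y), spec=ModelSpec(n_quad=101))
        oracle = oracles.uni_marginal_loglik(Y, a, c)
        assert abs(ll - oracle) / abs(oracle) < 1e-6

    def test_bifactor_matches_dense_2d_grid(self):
        rng = np.random.default_rng(2)
        a0 = rng.uniform(0.5, 1.8, 3)
        asp = rng.uniform(0.3, 1.2, 3)
        c = rng.normal(0, 0.8, 3)
        Y = np.array([[1, 1, 0], [0, 0, 1], [1, 0, 0], [1, 1, 1]], dtype=float)
        ids = [f"i{k}" for k in range(3)]
        dmap = DomainMap({i: "taboo" for i in ids}, strict=False)
        params = LatentParams(
            "bifactor",
            "binary_2pl",
            ids,
            a0,
            c,
            a_specific=asp,
            domains=["taboo"],
            item_domain_index=np.zeros(3, dtype=int),
        )
        spec = ModelSpec(structure="bifactor", n_quad=61, n_quad_specific=61)
        ll = marginal_loglik(params, _mat(Y), dmap, spec)
        oracle = oracles.bifactor_marginal_loglik(Y, a0, asp, c)
        assert abs(ll - oracle) / abs(oracle) < 1e-6

    def test_correlated_factors_match_dense_2d_grid(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.6, 1.6, 3)
        c = rng.normal(0, 0.7, 3)
        rho = 0.55
        Y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 1], [0, 0, 0]], dtype=float)
        ids = [f"i{k}" for k in range(3)]
        dmap = _two_domain_map(ids, 2)
        params = LatentParams(
            "correlated_factors",
            "binary_2pl",
            ids,
            a,
            c,
            corr=np.array([[1.0, rho], [rho, 1.0]]),
            domains=dmap.domains,
            item_domain_index=dmap.domain_index(ids),
        )
        spec = ModelSpec(structure="correlated_factors", n_quad_per_dim=41)
        ll = marginal_loglik(params, _mat(Y), dmap, spec)
        oracle = oracles.correlated2_marginal_loglik(Y, a, c, [0, 0, 1], rho)
        assert abs(ll - oracle) / abs(oracle) < 1e-6

    def test_nonfinite_parameter_rejected(self):
        params = LatentParams(
            "unidimensional", "binary_2pl", ["i0"], np.array([np.inf]), np.array([0.0])
        )
        with pytest.raises(ValueError, match="non-finite"):
            marginal_loglik(params, _mat(np.array([[1.0]])))


class TestFitting:
    def test_2pl_parameter_recovery_across_seeds(self):
        # n=2000, 20 items: correlation(truth, estimate) >= 0.95 (b), 0.85 (a)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, J = 2000, 20
            a = rng.uniform(0.8, 2.5, J)
            b = rng.uniform(-1.0, 2.0, J)
            theta = rng.normal(0, 1, n)
            p = 1 / (1 + np.exp(-a[None, :] * (theta[:, None] - b[None, :])))
            resp = _mat((rng.random((n, J)) < p).astype(float))
            fit = fit_latent_model(
                resp, None, ModelSpec(structure="unidimensional", tol=1e-5)
            )
            assert fit.converged
            b_hat = fit.params.difficulty()
            assert np.corrcoef(b, b_hat)[0, 1] >= 0.95
            assert np.corrcoef(a, fit.params.a_general)[0, 1] >= 0.85

    def test_em_never_decreases_loglik(self, small_cohort):
        params, resp, _, _ = small_cohort
        dmap = params.domain_map()
        for structure in ("unidimensional", "bifactor"):
            fit = fit_latent_model(
                resp,
                dmap,
                ModelSpec(
                    structure=structure,
                    n_quad=15,
                    n_quad_specific=9,
                    tol=1e-4,
                    max_iter=200,
                ),
            )
            assert fit.ascent_violations == 0
            diffs = np.diff(fit.loglik_path)
            assert np.all(diffs > -1e-6 * abs(fit.loglik))

    def test_bifactor_loglik_dominates_unidimensional(self, small_cohort):
        params, resp, _, _ = small_cohort
        dmap = params.domain_map()
        f_uni = fit_latent_model(
            resp, dmap, ModelSpec(structure="unidimensional", n_quad=41, tol=1e-3)
        )
        f_bif = fit_latent_model(
            resp,
            dmap,
            ModelSpec(
                structure="bifactor",
                n_quad=41,
                n_quad_specific=21,
                tol=1e-3,
                max_iter=150,
            ),
        )
        assert f_bif.loglik >= f_uni.loglik - 1e-4

    def test_quadrature_stability(self, small_cohort):
        params, resp, _, _ = small_cohort
        fit = fit_latent_model(
            resp, None, ModelSpec(structure="unidimensional", tol=1e-5)
        )
        ll_default = marginal_loglik(fit.params, resp, spec=ModelSpec())
        ll_doubled = marginal_loglik(fit.params, resp, spec=ModelSpec(n_quad=202))
        assert abs(ll_default - ll_doubled) < 0.01

    def test_bifactor_on_unidimensional_data_finds_no_specific_structure(self):
        # on truly unidimensional data the specific factors absorb only
        # sampling noise: the log-likelihood gain stays near its chi-square
        # expectation (J/2) and BIC prefers the unidimensional model
        rng = np.random.default_rng(12)
        n, J = 1500, 20
        a = rng.uniform(0.8, 2.0, J)
        b = rng.uniform(-1.0, 1.5, J)
        theta = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-a[None, :] * (theta[:, None] - b[None, :])))
        resp = _mat((rng.random((n, J)) < p).astype(float))
        dmap = _two_domain_map(resp.item_ids, 10)
        f_uni = fit_latent_model(
            resp, dmap, ModelSpec(structure="unidimensional", tol=1e-4)
        )
        f_bif = fit_latent_model(
            resp,
            dmap,
            ModelSpec(
                structure="bifactor",
                n_quad=21,
                n_quad_specific=15,
                tol=1e-3,
                max_iter=80,
            ),
        )
        gain = f_bif.loglik - f_uni.loglik
        assert gain < 30.0  # ~J/2 expected under the null
        assert f_bif.bic > f_uni.bic
        assert f_bif.bic > f_uni.bic

    def test_degenerate_item_bounded_and_flagged(self):
        rng = np.random.default_rng(4)
        Y = (rng.random((200, 4)) < 0.4).astype(float)
        Y[:, 3] = 0.0  # endorsed by nobody
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_latent_model(
                _mat(Y), None, ModelSpec(structure="unidimensional", tol=1e-4)
            )
        assert fit.degenerate_items == ["i3"]
        assert np.all(np.isfinite(fit.params.a_general))
        assert np.all(np.isfinite(np.asarray(fit.params.intercepts)))


class TestModelComparison:
    def _fake_fit(self, structure, loglik, n_par, n=100):
        params = LatentParams(
            structure, "binary_2pl", ["i0"], np.ones(1), np.zeros(1)
        )
        from ocdim.latent_models import FitResult

        return FitResult(
            params=params,
            loglik=loglik,
            n_parameters=n_par,
            n_persons=n,
            converged=True,
            n_iter=1,
            spec=ModelSpec(structure=structure),
            data_fingerprint=(n, 1, 0.0),
        )

    def test_information_criteria_identities(self):
        f = self._fake_fit("unidimensional", -55.0, 4, n=100)
        assert f.aic == pytest.approx(-2 * -55.0 + 8)
        assert f.bic == pytest.approx(110 + 4 * np.log(100))

    def test_delta_aic_prefers_smaller(self):
        f1 = self._fake_fit("unidimensional", -60.0, 0)
        f2 = self._fake_fit("bifactor", -55.0, 0)
        table = compare_models([f1, f2])
        row = table[table.structure == "unidimensional"].iloc[0]
        assert row["delta_aic"] == pytest.approx(10.0)

    def test_identical_fits_give_null_lrt(self):
        f1 = self._fake_fit("unidimensional", -50.0, 4)
        f2 = self._fake_fit("bifactor", -50.0, 4)
        table = compare_models([f1, f2])
        row = table[table.structure == "bifactor"].iloc[0]
        assert row["lrt_stat"] == 0.0
        assert row["lrt_p"] == 1.0

    def test_chi_square_quantile(self):
        f1 = self._fake_fit("unidimensional", -51.92, 4)
        f2 = self._fake_fit("bifactor", -50.0, 5)
        table = compare_models([f1, f2])
        row = table[table.structure == "bifactor"].iloc[0]
        assert row["lrt_df"] == 1
        assert row["lrt_p"] == pytest.approx(0.05, abs=0.001)

    def test_mismatched_n_rejected(self):
        f1 = self._fake_fit("unidimensional", -50.0, 4, n=100)
        f2 = self._fake_fit("bifactor", -50.0, 5, n=200)
        with pytest.raises(ValueError, match="identical data"):
            compare_models([f1, f2])


class TestLeaveOneDomainOut:
    def test_loaded_domain_has_largest_drop(self):
        rng = np.random.default_rng(31)
        n, J = 800, 12
        ids = [f"i{k}" for k in range(J)]
        dmap = DomainMap(
            {
                i: ("contamination" if k < 4 else "taboo" if k < 8 else "hoarding")
                for k, i in enumerate(ids)
            },
            strict=False,
        )
        a0 = rng.uniform(0.8, 2.0, J)
        asp = np.where(np.arange(J) < 4, 1.2, 0.0)  # only contamination loads
        c = rng.normal(0, 1, J)
        resp = simulate_bifactor_responses(
            a0, asp, c, dmap.domain_index(ids), rng, n_persons=n, item_ids=ids
        )
        spec = ModelSpec(
            structure="bifactor", n_quad=15, n_quad_specific=9, tol=1e-4
        )
        table = leave_one_domain_out(resp, dmap, spec)
        assert table.iloc[0]["domain"] == "contamination"
        assert table.iloc[0]["lrt_p"] < 0.001
        # the full model dominates every ablated one (up to convergence slack)
        assert np.all(table["loglik_drop"] > -0.05)

    def test_null_data_show_no_significant_domain(self):
        rng = np.random.default_rng(32)
        n, J = 1000, 12
        ids = [f"i{k}" for k in range(J)]
        dmap = DomainMap(
            {i: ("contamination" if k < 6 else "taboo") for k, i in enumerate(ids)},
            strict=False,
        )
        a = rng.uniform(0.8, 2.0, J)
        c = rng.normal(0, 1, J)
        resp = simulate_bifactor_responses(
            a, np.zeros(J), c, dmap.domain_index(ids), rng, n_persons=n, item_ids=ids
        )
        spec = ModelSpec(
            structure="bifactor", n_quad=15, n_quad_specific=9, tol=1e-4
        )
        table = leave_one_domain_out(resp, dmap, spec)
        assert np.all(table["lrt_p"] > 0.01)



class TestLoadings:
    def test_normal_metric_conversion(self):
        params = LatentParams(
            "unidimensional",
            "binary_2pl",
            ["i0", "i1"],
            np.array([1.702, 0.0]),
            np.zeros(2),
        )
        from ocdim.latent_models import FitResult

        fit = FitResult(params, -1.0, 4, 10, True, 1, ModelSpec())
        tab = standardized_loadings(fit)
        assert tab["loading_general"][0] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        assert tab["loading_general"][1] == 0.0

    def test_general_plus_specific_communality(self):
        params = LatentParams(
            "bifactor",
            "binary_2pl",
            ["i0"],
            np.array([1.702]),
            np.zeros(1),
            a_specific=np.array([1.702]),
        )
        from ocdim.latent_models import FitResult

        fit = FitResult(params, -1.0, 3, 10, True, 1, ModelSpec("bifactor"))
        tab = standardized_loadings(fit)
        assert tab["loading_general"][0] == pytest.approx(0.5774, abs=1e-3)
        assert tab["communality"][0] == pytest.approx(2.0 / 3.0, abs=1e-3)
        assert tab["communality"][0] < 1.0


class TestEAPScoring:
    def test_matches_dense_grid(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0.8, 2.0, 4)
        c = rng.normal(0, 1, 4)
        Y = np.array([[1, 0, 1, 1], [0, 0, 0, 1]], dtype=float)
        params = LatentParams(
            "unidimensional", "binary_2pl", [f"i{k}" for k in range(4)], a, c
        )
        scores = eap_scores_binary(params, _mat(Y), n_quad=101)
        oracle = oracles.binary_eap(Y, a, c)
        np.testing.assert_allclose(scores.mean, oracle, atol=1e-6)

    def test_equal_slope_scores_are_monotone_in_sum_score(self):
        rng = np.random.default_rng(7)
        n, J = 300, 12
        theta = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(theta[:, None] - rng.uniform(-1, 1, J)[None, :])))
        resp = _mat((rng.random((n, J)) < p).astype(float))
        fit = fit_latent_model(
            resp,
            None,
            ModelSpec(structure="unidimensional", equal_slopes=True, tol=1e-6),
        )
        assert np.ptp(fit.params.a_general) == 0.0
        scores = eap_scores_binary(fit.params, resp)
        sums = resp.symptom_counts()
        for s in range(int(sums.max())):
            lo = scores.mean[sums == s]
            hi = scores.mean[sums == s + 1]
            if len(lo) and len(hi):
                assert hi.min() > lo.max() - 1e-9
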