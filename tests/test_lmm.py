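"""REML fitting, GLS and BLUP against dense explicit-inverse oracles."""

import numpy as np
import pandas as pd
import pytest

from repgwas.design import build_design
from repgwas.io_formats import KinshipMatrix, PhenotypeTable
from repgwas.kinship import compute_kinship
from repgwas.lmm import (
    LmmError,
    VarianceComponents,
    estimate_bv,
    fit_null,
    gls_solve,
)
from helpers import (
    gls_oracle,
    make_geno,
    mme_oracle,
    random_instance,
    reml_oracle,
)


def _fit_instance(seed, **kw):
    pheno, geno, kin = random_instance(seed, **kw)
    factors = tuple(pheno.schema)
    design = build_design(pheno, geno, fixed_factors=factors)
    return design, kin, fit_null(design, kin)


class TestFitNull:
    @pytest.mark.parametrize("seed,k,nf", [(0, 2, 1), (1, 1, 0), (2, 3, 2)])
    def test_matches_dense_brute_force_oracle(self, seed, k, nf):
        design, kin, vc = _fit_instance(seed, n_lines=25, k=k, n_factors=nf)
        sg, se, ll = reml_oracle(design.y, design.X, design.Z, kin.values)
        assert vc.sigma_g2 == pytest.approx(sg, rel=1e-4)
        assert vc.sigma_e2 == pytest.approx(se, rel=1e-4)
        assert vc.reml_loglik == pytest.approx(ll, abs=1e-3)

    def test_identity_design_collapses_to_ols(self, rng):
        # Z=I, K=I: only the total variance is identifiable; the fitted V
        # must equal the OLS unbiased residual variance times I, and the
        # GLS coefficients must equal OLS
        n = 40
        geno = make_geno(rng, n, 30)
        x2 = rng.standard_normal(n)
        y = 1.0 + 0.5 * x2 + rng.standard_normal(n)
        pheno = PhenotypeTable(
            pd.DataFrame({"line": geno.line_ids, "trait": y, "x": x2}),
            {"x": "numerical"})
        design = build_design(pheno, geno, fixed_factors=("x",))
        kin = KinshipMatrix(list(geno.line_ids), np.eye(n))
        vc = fit_null(design, kin)
        X = design.X
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta_ols) ** 2).sum())
        total = vc.sigma_g2 + vc.sigma_e2
        assert total == pytest.approx(rss / (n - 2), rel=1e-6)
        np.testing.assert_allclose(vc.beta_hat, beta_ols, atol=1e-8)

    def test_pure_noise_gives_near_zero_heritability(self):
        # with no genetic signal the variance ratio should collapse
        for seed in range(3):
            rng = np.random.default_rng(seed)
            geno = make_geno(rng, 500, 100)
            kin = compute_kinship(geno)
            pheno = PhenotypeTable(
                pd.DataFrame({"line": geno.line_ids,
                              "trait": rng.standard_normal(500)}), {})
            design = build_design(pheno, geno)
            vc = fit_null(design, kin)
            assert vc.heritability < 0.1

    def test_reml_invariant_to_x_reparameterization(self, rng):
        # reference coding vs sum coding span the same column space
        pheno, geno, kin = random_instance(7, n_lines=20, k=2, n_factors=1)
        design = build_design(pheno, geno, fixed_factors=("env",))
        vc_ref = fit_null(design, kin)
        a = np.array([[1.0, 0.0], [-1.0, 2.0]])  # invertible reparameterization
        design.X = design.X @ a
        vc_sum = fit_null(design, kin)
        assert vc_sum.sigma_g2 == pytest.approx(vc_ref.sigma_g2, rel=1e-6)
        assert vc_sum.reml_loglik == pytest.approx(vc_ref.reml_loglik, abs=1e-8)

    def test_fit_invariant_to_observation_order(self, rng):
        pheno, geno, kin = random_instance(11, n_lines=15, k=2, n_factors=1)
        design = build_design(pheno, geno, fixed_factors=("env",))
        vc = fit_null(design, kin)
        perm = rng.permutation(len(pheno.data))
        pheno2 = PhenotypeTable(pheno.data.iloc[perm].reset_index(drop=True),
                                pheno.schema)
        design2 = build_design(pheno2, geno, fixed_factors=("env",))
        vc2 = fit_null(design2, kin)
        # round-off in the eigendecomposition shifts the (flat) profile
        # optimum by ~sqrt(eps), so exact bit-identity is not expected
        assert vc2.sigma_g2 == pytest.approx(vc.sigma_g2, rel=1e-6)
        assert vc2.sigma_e2 == pytest.approx(vc.sigma_e2, rel=1e-6)
        assert vc2.reml_loglik == pytest.approx(vc.reml_loglik, abs=1e-8)

    def test_parameter_recovery_sigma_g(self):
        # data simulated with sigma_g2 = sigma_e2 = 1 on replicated lines;
        # the mean REML estimate over seeds should be close to truth
        est = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = 400
            geno = make_geno(rng, n, 200)
            kin = compute_kinship(geno)
            chol = np.linalg.cholesky(kin.values + 1e-8 * np.eye(n))
            g = chol @ rng.standard_normal(n)
            rows = {"line": list(geno.line_ids) * 2}
            e = rng.standard_normal(2 * n)
            gv = np.concatenate([g, g])
            rows["trait"] = gv + e
            pheno = PhenotypeTable(pd.DataFrame(rows), {})
            design = build_design(pheno, geno)
            vc = fit_null(design, kin)
            est.append(vc.sigma_g2)
        assert 0.85 <= np.mean(est) <= 1.15

    def test_misaligned_kinship_rejected(self, rng):
        pheno, geno, kin = random_instance(3, n_lines=10, k=1, n_factors=0)
        design = build_design(pheno, geno)
        bad = KinshipMatrix(list(reversed(kin.line_ids)), kin.values)
        with pytest.raises(LmmError, match="align"):
            fit_null(design, bad)


class TestGlsSolve:
    def test_identity_v_equals_ols(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        beta, cov = gls_solve(y, X, np.eye(n), np.ones(n))
        ref, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(beta, ref, atol=1e-10)

    def test_scaling_v_doubles_covariance_only(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        b1, c1 = gls_solve(y, X, np.eye(n), np.ones(n))
        b2, c2 = gls_solve(y, X, np.eye(n), 2.0 * np.ones(n))
        np.testing.assert_allclose(b1, b2, atol=1e-12)
        np.testing.assert_allclose(c2, 2 * c1, atol=1e-12)

    def test_random_psd_v_matches_explicit_inverse(self, rng):
        n = 10
        a = rng.standard_normal((n, n))
        V = a @ a.T + n * np.eye(n)
        d, u = np.linalg.eigh(V)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        beta, cov = gls_solve(y, X, u, d)
        ref_beta, ref_cov = gls_oracle(y, X, V)
        np.testing.assert_allclose(beta, ref_beta, atol=1e-10)
        np.testing.assert_allclose(cov, ref_cov, atol=1e-10)

    def test_singular_xvx_rejected(self, rng):
        n = 8
        X = np.ones((n, 2))  # duplicated column
        y = rng.standard_normal(n)
        with pytest.raises(LmmError, match="singular"):
            gls_solve(y, X, np.eye(n), np.ones(n))


class TestEstimateBv:
    def test_zero_genetic_variance_gives_zero_bvs(self, rng):
        pheno, geno, kin = random_instance(5, n_lines=10, k=2, n_factors=0)
        design = build_design(pheno, geno)
        vc = VarianceComponents(
            sigma_g2=0.0, sigma_e2=1.0, delta=np.inf, reml_loglik=0.0,
            beta_hat=np.array([0.0]), beta_cov=np.eye(1),
            fixed_effect_names=["intercept"])
        bv = estimate_bv(design, kin, vc)
        assert np.all(bv.to_numpy() == 0.0)

    def test_identity_model_shrinks_centered_phenotypes(self, rng):
        # Z=I, K=I, intercept-only: g_i = h2 * (y_i - ybar)
        n = 4
        geno = make_geno(rng, n, 10)
        y = np.array([1.0, 3.0, -2.0, 6.0])
        pheno = PhenotypeTable(
            pd.DataFrame({"line": geno.line_ids, "trait": y}), {})
        design = build_design(pheno, geno)
        kin = KinshipMatrix(list(geno.line_ids), np.eye(n))
        sg2, se2 = 2.0, 3.0
        h2 = sg2 / (sg2 + se2)
        vc = VarianceComponents(
            sigma_g2=sg2, sigma_e2=se2, delta=se2 / sg2, reml_loglik=0.0,
            beta_hat=np.array([y.mean()]), beta_cov=np.eye(1),
            fixed_effect_names=["intercept"])
        bv = estimate_bv(design, kin, vc)
        np.testing.assert_allclose(bv.to_numpy(), h2 * (y - y.mean()),
                                   atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 4])
    def test_matches_mixed_model_equations_oracle(self, seed):
        # the MME route needs an invertible K; a marker-based K has row sums
        # zero (centering), so blend it with the identity
        pheno, geno, kin = random_instance(seed, n_lines=15, k=3, n_factors=1,
                                           n_markers=60)
        kin = KinshipMatrix(kin.line_ids,
                            0.9 * kin.values + 0.1 * np.eye(len(kin.line_ids)))
        design = build_design(pheno, geno, fixed_factors=("env",))
        vc = fit_null(design, kin)
        bv = estimate_bv(design, kin, vc)
        beta_mme, g_mme = mme_oracle(design.y, design.X, design.Z, kin.values,
                                     vc.sigma_g2, vc.sigma_e2)
        np.testing.assert_allclose(bv.to_numpy(), g_mme, atol=1e-8)
        np.testing.assert_allclose(vc.beta_hat, beta_mme, atol=1e-8)

    def test_unobserved_lines_predicted_through_kinship(self, rng):
        pheno, geno, kin = random_instance(9, n_lines=12, k=2, n_factors=0)
        # drop the last two lines from the phenotypes
        drop = set(geno.line_ids[-2:])
        kept = pheno.data[~pheno.data["line"].isin(drop)].reset_index(drop=True)
        design = build_design(PhenotypeTable(kept, {}), geno)
        from repgwas.kinship import align_kinship

        k_obs = align_kinship(kin, design.line_ids)
        vc = fit_null(design, k_obs)
        bv = estimate_bv(design, k_obs, vc, full_kinship=kin)
        assert set(bv.index) == set(geno.line_ids)
        # block-regression prediction for the unobserved lines
        obs_idx = [kin.line_ids.index(l) for l in design.line_ids]
        un_idx = [kin.line_ids.index(l) for l in geno.line_ids[-2:]]
        k_oo = kin.values[np.ix_(obs_idx, obs_idx)]
        k_uo = kin.values[np.ix_(un_idx, obs_idx)]
        expected = k_uo @ np.linalg.pinv(k_oo) @ bv[design.line_ids].to_numpy()
        np.testing.assert_allclose(bv[geno.line_ids[-2:]].to_numpy(), expected,
                                   atol=1e-8)
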