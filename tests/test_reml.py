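"""AI-REML engine: oracle equivalence, calibration, PCs, partitioning."""

import numpy as np
import pytest

from snph2 import (
    GREML,
    Grm,
    compute_grm,
    h2_partition,
    pcs_from_grm,
    reml_fit,
    simulate_genotypes,
)
from snph2.reml import _DenseKernel, _SpectralKernel, design_matrix, restricted_loglik

from conftest import simulate_observed_phenotype


class TestBackendEquivalence:
    """The spectral single-GRM path is an exact reparameterization of the dense path."""

    @pytest.mark.parametrize("n,m", [(60, 30), (40, 90)])  # kernel rank below and at n
    def test_loglik_score_ai_agree(self, n, m):
        G = simulate_genotypes(n, m, ld_rho=0.3, seed=n)
        A = compute_grm(G)
        rng = np.random.default_rng(1)
        y = simulate_observed_phenotype(A, 0.4, 0.6, rng)
        X = design_matrix(n, rng.standard_normal(n))
        for theta in ([0.3, 0.7], [0.9, 0.2], [0.05, 1.5]):
            sp = _SpectralKernel(y, X, A).stats(np.array(theta))
            de = _DenseKernel(y, X, [A.values]).stats(np.array(theta))
            assert sp[0] == pytest.approx(de[0], abs=1e-8)
            assert np.allclose(sp[3], de[3], atol=1e-7)  # scores
            assert np.allclose(sp[4], de[4], atol=1e-6)  # AI matrices
            assert sp[0] == pytest.approx(restricted_loglik(y, X, A, np.array(theta)), abs=1e-8)

    def test_fit_matches_two_grm_split_of_same_kernel(self):
        # duplicated half-weight kernels must reproduce the single-kernel fit
        G = simulate_genotypes(120, 80, seed=7)
        A = compute_grm(G)
        rng = np.random.default_rng(2)
        y = simulate_observed_phenotype(A, 0.5, 0.5, rng)
        single = reml_fit(y, None, A)
        half = Grm(values=A.values, n_snps=A.n_snps, sample_ids=A.sample_ids)
        double = reml_fit(y, None, [half, half])
        assert double.h2_observed == pytest.approx(single.h2_observed, abs=1e-4)
        assert double.loglik == pytest.approx(single.loglik, abs=1e-4)


class TestGridOracle:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_optimum_matches_dense_grid_search(self, seed):
        """On tiny instances the AI-REML optimum must sit on the grid maximum."""
        n, m = 12, 8
        G = simulate_genotypes(n, m, ld_rho=0.2, seed=seed)
        A = compute_grm(G)
        rng = np.random.default_rng(seed)
        y = simulate_observed_phenotype(A, 0.8, 0.8, rng)
        X = np.ones((n, 1))
        fit = reml_fit(y, X, A, tol=1e-10)
        grid = np.linspace(0.02, 4.0, 80)
        lls = np.array([[restricted_loglik(y, X, A, np.array([sg, se])) for se in grid] for sg in grid])
        spacing = grid[1] - grid[0]
        assert fit.loglik >= lls.max() - 1e-8  # the fit can only improve on the grid
        # cross-formula check: the reported loglik equals the independent dense evaluation
        direct = restricted_loglik(y, X, A, np.array([fit.sigma2_g[0], fit.sigma2_e]))
        assert fit.loglik == pytest.approx(direct, abs=1e-8)
        # the fitted point sits within one grid cell of the near-optimal grid region
        # (the likelihood ridge can be flat at n = 12, so proximity is measured
        # against every grid point within 0.01 log-units of the grid maximum)
        near = np.argwhere(lls >= lls.max() - 0.01)
        dist = np.min(
            np.maximum(
                np.abs(grid[near[:, 0]] - fit.sigma2_g[0]), np.abs(grid[near[:, 1]] - fit.sigma2_e)
            )
        )
        assert dist <= spacing

    def test_loglik_never_below_null(self, small_grm):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(small_grm.n_samples)
        fit = reml_fit(y, None, small_grm)
        assert fit.loglik >= fit.loglik_null - 1e-6


class TestCalibration:
    def test_observed_scale_recovery_and_se(self, small_grm):
        """Mean estimate within 2 MC SEs of truth; reported SE tracks empirical SD."""
        rng = np.random.default_rng(17)
        for h2_true in (0.0, 0.5):
            est, ses = [], []
            for _ in range(40):
                y = simulate_observed_phenotype(small_grm, h2_true, 1 - h2_true, rng)
                fit = reml_fit(y, None, small_grm)
                est.append(fit.h2_observed)
                ses.append(fit.se_h2)
            est = np.array(est)
            sem = est.std(ddof=1) / np.sqrt(len(est))
            if h2_true == 0.0:
                assert est.mean() == pytest.approx(0.0, abs=max(2 * sem, 0.02))
            else:
                assert abs(est.mean() - h2_true) < 2 * sem + 0.01
                assert 0.7 < np.mean(ses) / est.std(ddof=1) < 1.4

    def test_null_pvalue_not_significant_for_unrelated_phenotype(self, small_grm):
        rng = np.random.default_rng(23)
        ps = [
            reml_fit(rng.standard_normal(small_grm.n_samples), None, small_grm).p_lrt
            for _ in range(20)
        ]
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_orthogonal_covariate_barely_moves_estimate(self, small_grm):
        rng = np.random.default_rng(29)
        y = simulate_observed_phenotype(small_grm, 0.5, 0.5, rng)
        base = reml_fit(y, None, small_grm)
        junk = rng.standard_normal(small_grm.n_samples)
        with_cov = reml_fit(y, design_matrix(small_grm.n_samples, junk), small_grm)
        assert abs(with_cov.h2_observed - base.h2_observed) < base.se_h2


class TestDegenerateInputs:
    def test_identity_grm_flags_non_identifiability(self):
        n = 60
        A = Grm(values=np.eye(n), n_snps=10, sample_ids=[str(i) for i in range(n)])
        y = np.random.default_rng(31).standard_normal(n)
        fit = reml_fit(y, None, A)
        assert any("identifiable" in msg for msg in fit.messages)

    def test_rank_deficient_design_rejected(self, small_grm):
        n = small_grm.n_samples
        X = np.ones((n, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_fit(np.zeros(n), X, small_grm)

    def test_dimension_mismatch_rejected(self, small_grm):
        with pytest.raises(ValueError):
            reml_fit(np.zeros(10), None, small_grm)

    def test_nonconvergence_is_flagged_not_raised(self, small_grm):
        rng = np.random.default_rng(37)
        y = simulate_observed_phenotype(small_grm, 0.5, 0.5, rng)
        fit = reml_fit(y, None, small_grm, max_iter=2, em_steps=1)
        assert not fit.converged
        assert any("converge" in m for m in fit.messages)


class TestPcs:
    def test_zero_pcs_empty_block(self, small_grm):
        assert pcs_from_grm(small_grm, 0).shape == (small_grm.n_samples, 0)

    def test_orthonormal(self, small_grm):
        P = pcs_from_grm(small_grm, 5)
        assert np.allclose(P.T @ P, np.eye(5), atol=1e-8)

    def test_sign_convention_deterministic(self, small_grm):
        P = pcs_from_grm(small_grm, 3)
        for j in range(3):
            assert P[np.argmax(np.abs(P[:, j])), j] > 0

    def test_pc1_separates_divergent_subpopulations(self):
        # two populations with shifted allele frequencies
        a = simulate_genotypes(80, 200, maf_range=(0.05, 0.25), seed=41)
        b = simulate_genotypes(80, 200, maf_range=(0.3, 0.5), seed=43)

        from snph2 import GenotypeMatrix

        d = np.vstack([a.dosages, b.dosages])
        meta = a.snp_meta.copy()
        meta["allele_freq"] = d.mean(axis=0) / 2
        G = GenotypeMatrix(d, meta, [f"i{i}" for i in range(160)])
        pc1 = pcs_from_grm(compute_grm(G), 1)[:, 0]
        assert abs(np.mean(pc1[:80]) - np.mean(pc1[80:])) > 2 * (pc1[:80].std() + pc1[80:].std())


class TestPartitionAndReports:
    def test_single_component_share_is_one(self, small_grm):
        rng = np.random.default_rng(47)
        y = simulate_observed_phenotype(small_grm, 0.5, 0.5, rng)
        fit = reml_fit(y, None, small_grm)
        part = h2_partition(fit)
        assert part["share_of_genetic"][0] == pytest.approx(1.0)

    def test_duplicated_grms_split_evenly(self, small_grm):
        rng = np.random.default_rng(53)
        y = simulate_observed_phenotype(small_grm, 0.6, 0.4, rng)
        A2 = Grm(values=small_grm.values, n_snps=small_grm.n_snps, sample_ids=small_grm.sample_ids)
        fit = reml_fit(y, None, [small_grm, A2])
        part = h2_partition(fit)
        assert part["share_of_genetic"][0] == pytest.approx(0.5, abs=0.05)

    def test_hsq_report_contains_gcta_fields(self, small_grm):
        rng = np.random.default_rng(59)
        y = simulate_observed_phenotype(small_grm, 0.5, 0.5, rng)
        report = reml_fit(y, None, small_grm).to_hsq()
        for token in ("V(G1)", "V(e)", "V(G)/Vp", "logL", "LRT", "Pval", "n"):
            assert token in report


class TestSklearnEstimator:
    def test_fit_exposes_fitted_attributes(self, small_genotypes):
        rng = np.random.default_rng(61)
        A = compute_grm(small_genotypes)
        y = simulate_observed_phenotype(A, 0.5, 0.5, rng)
        est = GREML(n_pcs=2).fit(small_genotypes, y)
        assert 0.0 <= est.h2_observed_ <= 1.0
        assert est.converged_
        assert est.fit_.n == small_genotypes.n_samples

    def test_precomputed_kernel_matches_functional_api(self, small_genotypes):
        rng = np.random.default_rng(67)
        A = compute_grm(small_genotypes)
        y = simulate_observed_phenotype(A, 0.4, 0.6, rng)
        est = GREML(kernel="precomputed").fit(A, y)
        ref = reml_fit(y, None, A)
        assert est.h2_observed_ == pytest.approx(ref.h2_observed, abs=1e-10)

    def test_get_params_round_trip(self):
        est = GREML(n_pcs=4, tol=1e-8)
        assert GREML(**est.get_params()).get_params() == est.get_params()
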