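import numpy as np
import pytest
from scipy import linalg

import mtcv
from mtcv import accuracy as acc
from mtcv.mixedmodel import blup_with_fixed_components, univariate_blup_with_fixed
from mtcv.predict import predict_cv2, predict_single
from mtcv.relatedness import Partition, conditional_blocks
from mtcv.simulate import (GeneticArchitecture, build_covariances, draw_common,
                           make_partition, simulate_traits)


class TestTrueAccuracy:
    def test_perfect_and_antiperfect(self):
        u = np.array([0.3, -1.2, 0.5, 2.0])
        assert acc.true_accuracy(u, u) == pytest.approx(1.0)
        assert acc.true_accuracy(u, -u) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # correlation assembled from raw sums, independent of library routines
        a = np.array([1.0, 2.0, 3.0, 5.0])
        b = np.array([1.0, 1.0, 2.0, 4.0])
        n = 4
        num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
        den = np.sqrt(n * np.sum(a * a) - np.sum(a) ** 2) * \
            np.sqrt(n * np.sum(b * b) - np.sum(b) ** 2)
        assert acc.true_accuracy(a, b) == pytest.approx(num / den)

    def test_zero_variance_is_missing(self):
        assert np.isnan(acc.true_accuracy(np.ones(5), np.arange(5.0)))

    def test_length_validation(self):
        with pytest.raises(ValueError):
            acc.true_accuracy(np.arange(2.0), np.arange(2.0))


class TestNaiveAccuracy:
    def test_h2_one_equals_plain_correlation(self, rng):
        a, b = rng.standard_normal((2, 30))
        assert acc.naive_accuracy(a, b, 1.0) == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_correction_conventions(self, rng):
        a, b = rng.standard_normal((2, 30))
        r = np.corrcoef(a, b)[0, 1]
        assert acc.naive_accuracy(a, b, 0.25, "h") == pytest.approx(r / 0.5)
        assert acc.naive_accuracy(a, b, 0.25, "h2") == pytest.approx(r / 0.25)

    def test_permuted_phenotypes_near_zero(self, rng):
        a = rng.standard_normal(200)
        b = rng.permutation(a)
        assert abs(acc.naive_accuracy(a, b, 0.5)) < 0.3

    def test_consistent_for_single_trait_when_no_residual_correlation(self, mid_grm):
        """At rho_R=0 the 1/h-corrected naive estimate is unbiased for the
        single-trait predictor's true accuracy."""
        arch = GeneticArchitecture(0.4, 0.4, 0.0, 0.0)
        G, R = build_covariances(arch)
        part = make_partition(mid_grm, "random_split", 0.2, 9)
        blocks = conditional_blocks(mid_grm, part)
        o = mid_grm.index_of(part.train_ids)
        t = mid_grm.index_of(part.test_ids)
        Koo = mid_grm.values[np.ix_(o, o)]
        eig = linalg.eigh(Koo)
        chol_k = linalg.cholesky(mid_grm.values, lower=True)
        rng = np.random.default_rng(21)
        naive, true = [], []
        for r in range(200):
            rep = simulate_traits(mid_grm, arch, draw_common(mid_grm.n, rng, r), chol_k)
            uni = univariate_blup_with_fixed(rep.Y[o, 0], Koo, G[0, 0], R[0, 0], eig=eig)
            pred = predict_single(uni, blocks)
            naive.append(acc.naive_accuracy(pred, rep.Y[t, 0], arch.h1_sq))
            true.append(acc.true_accuracy(pred, rep.U[t, 0]))
        assert np.mean(naive) == pytest.approx(np.mean(true), abs=0.05)


class TestFullDataEBV:
    def test_near_truth_when_residual_tiny(self, mid_grm, rng):
        arch = GeneticArchitecture(0.999, 0.999, 0.0, 0.0)
        rep = simulate_traits(mid_grm, arch, draw_common(mid_grm.n, rng))
        u_tilde = acc.full_data_ebv_predictand(rep.Y, mid_grm)
        assert np.corrcoef(u_tilde, rep.U[:, 0])[0, 1] > 0.98

    def test_inflates_estimated_accuracy(self, tiny_grm):
        """Scoring against full-data EBVs overstates accuracy — the
        documented invalid-predictand failure mode."""
        arch = GeneticArchitecture(0.2, 0.6, 0.6, 0.0)
        G, R = build_covariances(arch)
        part = make_partition(tiny_grm, "random_split", 0.2, 2)
        blocks = conditional_blocks(tiny_grm, part)
        o = tiny_grm.index_of(part.train_ids)
        t = tiny_grm.index_of(part.test_ids)
        Koo = tiny_grm.values[np.ix_(o, o)]
        eig = linalg.eigh(Koo)
        chol_k = linalg.cholesky(tiny_grm.values, lower=True)
        rng = np.random.default_rng(6)
        est_vs_ebv, est_true, ebv_vs_y, true_vs_y = [], [], [], []
        for r in range(40):
            rep = simulate_traits(tiny_grm, arch, draw_common(tiny_grm.n, rng, r), chol_k)
            uni = univariate_blup_with_fixed(rep.Y[o, 0], Koo, G[0, 0], R[0, 0], eig=eig)
            pred = predict_single(uni, blocks)
            u_tilde = acc.full_data_ebv_predictand(rep.Y, tiny_grm, part)
            est_vs_ebv.append(acc.true_accuracy(pred, u_tilde))
            est_true.append(acc.true_accuracy(pred, rep.U[t, 0]))
            ebv_vs_y.append(np.corrcoef(u_tilde, rep.Y[t, 0])[0, 1])
            true_vs_y.append(np.corrcoef(rep.U[t, 0], rep.Y[t, 0])[0, 1])
        assert np.mean(est_vs_ebv) > np.mean(est_true)
        # at low h2 the EBV predictand tracks the phenotype more than truth does
        assert np.mean(ebv_vs_y) > np.mean(true_vs_y)


class TestParametricAccuracy:
    def test_perfect_index_near_one(self, mid_grm):
        arch = GeneticArchitecture(0.4, 0.4, 0.0, 0.0)
        chol_k = linalg.cholesky(mid_grm.values, lower=True)
        eig = linalg.eigh(mid_grm.values)
        rng = np.random.default_rng(4)
        vals = [acc.parametric_accuracy(rep.U[:, 0], rep.Y[:, 0], mid_grm.values, eig=eig)
                for rep in (simulate_traits(mid_grm, arch, draw_common(mid_grm.n, rng, r),
                                            chol_k) for r in range(15))]
        assert np.nanmean(vals) == pytest.approx(1.0, abs=0.1)

    def test_noise_index_near_zero(self, mid_grm):
        arch = GeneticArchitecture(0.4, 0.4, 0.0, 0.0)
        chol_k = linalg.cholesky(mid_grm.values, lower=True)
        eig = linalg.eigh(mid_grm.values)
        rng = np.random.default_rng(14)
        vals = []
        for r in range(15):
            rep = simulate_traits(mid_grm, arch, draw_common(mid_grm.n, rng, r), chol_k)
            vals.append(acc.parametric_accuracy(rng.standard_normal(mid_grm.n),
                                                rep.Y[:, 0], mid_grm.values, eig=eig))
        assert abs(np.nanmean(vals)) < 0.15

    def test_less_biased_than_naive_for_cv2(self, mid_grm):
        """Mirrors the 50:50 comparison: the selection-index estimate sits
        closer to the true CV2 accuracy than the naive estimate does."""
        from mtcv.experiment import GridConfig, run_grid

        cfg = GridConfig(h1_sq=[0.2], h2_sq=[0.6], rho_g=[0.6], rho_r=[-0.6],
                         reps=30, designs=["naive", "parametric"], seed=44)
        grid = run_grid(cfg, grm=mid_grm)
        naive_rows = grid[grid.design == "naive"]
        par_rows = grid[grid.design == "parametric"]
        bias_naive = abs(
            naive_rows[(naive_rows.method == "cv2") & (naive_rows.estimator == "naive")].value.mean()
            - naive_rows[(naive_rows.method == "cv2") & (naive_rows.estimator == "true")].value.mean())
        bias_par = abs(
            par_rows[(par_rows.method == "cv2") & (par_rows.estimator == "parametric")].value.mean()
            - par_rows[(par_rows.method == "cv2") & (par_rows.estimator == "true")].value.mean())
        assert bias_par < bias_naive


@pytest.fixture(scope="module")
def bias_setup(mid_grm):
    arch = GeneticArchitecture(0.2, 0.6, 0.6, -0.6)
    G, R = build_covariances(arch)
    part = make_partition(mid_grm, "random_split", 0.1, 7)
    blocks = conditional_blocks(mid_grm, part)
    o = mid_grm.index_of(part.train_ids)
    t = mid_grm.index_of(part.test_ids)
    Koo = mid_grm.values[np.ix_(o, o)]
    eig = linalg.eigh(Koo)
    return mid_grm, arch, G, R, part, blocks, o, t, Koo, eig


class TestSemiparametricBias:
    def _fixed_fit(self, setup, rho_g, rho_r):
        grm, _, _, _, part, blocks, o, t, Koo, eig = setup
        arch = GeneticArchitecture(0.2, 0.6, rho_g, rho_r)
        G, R = build_covariances(arch)
        return blup_with_fixed_components(np.zeros((len(o), 2)), Koo, G, R, eig=eig), blocks

    def test_zero_when_no_genetic_covariance(self, bias_setup, rng):
        fit, blocks = self._fixed_fit(bias_setup, 0.0, -0.6)
        bias = acc.semiparametric_bias(fit, blocks, rng.standard_normal(20),
                                       rng.standard_normal(20))
        assert bias.bias_cov == 0.0 and bias.bias_hat == 0.0

    def test_zero_when_no_residual_covariance(self, bias_setup, rng):
        fit, blocks = self._fixed_fit(bias_setup, 0.6, 0.0)
        bias = acc.semiparametric_bias(fit, blocks, rng.standard_normal(20),
                                       rng.standard_normal(20))
        assert bias.bias_cov == 0.0

    @pytest.mark.parametrize("rho_r, sign", [(-0.6, -1), (0.6, +1)])
    def test_sign_follows_covariance_product(self, bias_setup, rng, rho_r, sign):
        fit, blocks = self._fixed_fit(bias_setup, 0.6, rho_r)
        bias = acc.semiparametric_bias(fit, blocks, rng.standard_normal(20),
                                       rng.standard_normal(20))
        assert np.sign(bias.bias_cov) == sign

    def test_covariance_scale_monte_carlo_oracle(self, bias_setup):
        """With the true G and R, the analytic term equals the mean excess of
        cov(u_hat3, y_n1) over cov(u_hat3, u_n1) — the decisive check of the
        correction's derivation."""
        grm, arch, G, R, part, blocks, o, t, Koo, eig = bias_setup
        chol_k = linalg.cholesky(grm.values, lower=True)
        rng = np.random.default_rng(11)
        diffs = []
        fit0 = blup_with_fixed_components(np.zeros((len(o), 2)), Koo, G, R, eig=eig)
        analytic = acc.semiparametric_bias(fit0, blocks, np.arange(20.0),
                                           np.arange(20.0) ** 2).bias_cov
        for r in range(1200):
            rep = simulate_traits(grm, arch, draw_common(grm.n, rng, r), chol_k)
            biv = blup_with_fixed_components(rep.Y[o], Koo, G, R, eig=eig)
            u3 = predict_cv2(biv, blocks, rep.Y[t, 1])
            diffs.append(np.cov(u3, rep.Y[t, 0])[0, 1] - np.cov(u3, rep.U[t, 0])[0, 1])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(analytic, abs=3 * se)

    def test_correlation_scale_monte_carlo(self, bias_setup):
        """Correlation-scale version of the oracle; approximate because the
        correlation is a ratio (small-n curvature allowance added)."""
        grm, arch, G, R, part, blocks, o, t, Koo, eig = bias_setup
        chol_k = linalg.cholesky(grm.values, lower=True)
        rng = np.random.default_rng(13)
        cdiff, bhat = [], []
        for r in range(1200):
            rep = simulate_traits(grm, arch, draw_common(grm.n, rng, r), chol_k)
            biv = blup_with_fixed_components(rep.Y[o], Koo, G, R, eig=eig)
            u3 = predict_cv2(biv, blocks, rep.Y[t, 1])
            y1, u1 = rep.Y[t, 0], rep.U[t, 0]
            cdiff.append(np.corrcoef(u3, y1)[0, 1]
                         - np.corrcoef(u3, u1)[0, 1] * np.sqrt(arch.h1_sq))
            bhat.append(acc.semiparametric_bias(biv, blocks, u3, y1).bias_hat)
        cdiff, bhat = np.asarray(cdiff), np.asarray(bhat)
        se = cdiff.std(ddof=1) / np.sqrt(len(cdiff))
        assert np.mean(cdiff) == pytest.approx(np.mean(bhat), abs=3 * se + 0.02)


class TestSemiparametricAccuracy:
    def _bias(self, value):
        return acc.BiasCorrection(bias_hat=value, bias_cov=value, g12=0.1, r12=0.1,
                                  trace_term=1.0, var_u_hat=1.0, var_y=1.0, n=20)

    def test_zero_bias_equals_naive(self):
        assert acc.semiparametric_accuracy(0.3, self._bias(0.0), 0.2) == \
            pytest.approx(0.3 / np.sqrt(0.2))

    def test_opposing_correlations_raise_estimate(self):
        # g12*r12 < 0 -> negative bias -> corrected estimate above naive
        corrected = acc.semiparametric_accuracy(0.1, self._bias(-0.15), 0.2)
        assert corrected > 0.1 / np.sqrt(0.2)

    def test_aligned_correlations_lower_estimate(self):
        corrected = acc.semiparametric_accuracy(0.4, self._bias(0.15), 0.2)
        assert corrected < 0.4 / np.sqrt(0.2)


class TestCV2Star:
    def test_unrelated_surrogates_estimate_nothing(self, mid_grm):
        """Surrogates with no genomic overlap give ~0 estimated accuracy no
        matter how good the predictions are — the documented failure mode."""
        arch = GeneticArchitecture(0.2, 0.6, 0.6, 0.0)
        chol_k = linalg.cholesky(mid_grm.values, lower=True)
        rng = np.random.default_rng(3)
        # predictions for lines 0..19; "surrogates" from distant families 180..199
        part = Partition(test_ids=mid_grm.ids[:20], train_ids=mid_grm.ids[20:180])
        blocks = conditional_blocks(mid_grm, part)
        G, R = build_covariances(arch)
        Koo = mid_grm.values[20:180, 20:180]
        eig = linalg.eigh(Koo)
        vals = []
        for r in range(80):
            rep = simulate_traits(mid_grm, arch, draw_common(mid_grm.n, rng, r), chol_k)
            biv = blup_with_fixed_components(rep.Y[20:180], Koo, G, R, eig=eig)
            u3 = predict_cv2(biv, blocks, rep.Y[:20, 1])
            vals.append(acc.cv2star_accuracy(u3, rep.Y[180:, 0], arch.h1_sq, "relative"))
        assert abs(np.mean(vals)) < 0.12

    def test_clone_design_slightly_downward_biased(self, mid_grm):
        from mtcv.experiment import GridConfig, run_grid

        cfg = GridConfig(h1_sq=[0.2], h2_sq=[0.6], rho_g=[0.6], rho_r=[-0.6, 0.6],
                         reps=80, designs=["cv2star_clone"], seed=33)
        grid = run_grid(cfg, grm=mid_grm)
        cv2 = grid[grid.method == "cv2"]
        est = cv2[cv2.estimator == "cv2star"].pivot_table(
            index="replicate", columns="rho_r", values="value")
        true = cv2[cv2.estimator == "true"].pivot_table(
            index="replicate", columns="rho_r", values="value")
        paired = (est - true).to_numpy().ravel()
        assert paired.mean() < 0.0  # downward, from the doubled residual variance
        # and the estimate does not depend systematically on rho_R:
        # the shared-residual bias channel is severed
        d = (est[0.6] - est[-0.6]).to_numpy()
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 3 * se + 0.02

    def test_clone_correction_factor(self, rng):
        a, b = rng.standard_normal((2, 50))
        r = np.corrcoef(a, b)[0, 1]
        h1 = 0.2
        expect_clone = r / np.sqrt(h1 / (h1 + 2 * 0.8))
        expect_rel = r / np.sqrt(h1)
        assert acc.cv2star_accuracy(a, b, h1, "clone") == pytest.approx(expect_clone)
        assert acc.cv2star_accuracy(a, b, h1, "relative") == pytest.approx(expect_rel)

    def test_location_shift_invariance(self, rng):
        a, b = rng.standard_normal((2, 50))
        assert acc.cv2star_accuracy(a + 3.0, b - 1.0, 0.3, "clone") == \
            pytest.approx(acc.cv2star_accuracy(a, b, 0.3, "clone"))
        assert acc.naive_accuracy(a + 3.0, b - 1.0, 0.3) == \
            pytest.approx(acc.naive_accuracy(a, b, 0.3))

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            acc.cv2star_accuracy(rng.standard_normal(5), rng.standard_normal(6),
                                 0.3, "clone")
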