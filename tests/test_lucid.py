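"""Latent-cluster EM engine: degenerate cases, closed-form posteriors,
ascent/normalization invariants, parameter recovery, BIC selection,
parallel factorization, and cluster alignment."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

import lucidomics as lo
from lucidomics.lucid import LucidLayer, _as_design, _weighted_multinomial_newton


def two_cluster_data(seed, n=500, p=5, sep=1.5, slope=1.0):
    """Exposure-driven two-cluster Gaussian layer with mu = -/+ sep."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    logit = slope * x
    lab = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    mu = np.vstack([np.full(p, -sep), np.full(p, sep)])
    Z = mu[lab] + rng.standard_normal((n, p))
    return Z, x, lab, mu


class TestSingleCluster:
    def test_k1_degenerates_to_gaussian(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(2.0, 1.5, size=(40, 3))
        x = rng.normal(size=40)
        m = LucidLayer(n_clusters=1).fit(Z, x)
        np.testing.assert_array_equal(m.responsibilities_, np.ones((40, 1)))
        np.testing.assert_allclose(m.mu_[0], Z.mean(axis=0), atol=1e-12)
        assert m.beta_.shape == (0, 2)
        # loglik equals the diagonal-Gaussian log-density sum at the MLE
        s2 = Z.var(axis=0)
        expected = scipy.stats.norm.logpdf(
            Z, Z.mean(axis=0), np.sqrt(s2)
        ).sum()
        assert m.loglik_ == pytest.approx(expected, abs=1e-8)


class TestClosedFormPosterior:
    def test_frozen_parameter_responsibilities(self):
        """With beta=0, mu=(-1,+1), sigma^2=1 frozen, responsibilities are
        the Bayes posterior N(z; mu_k, 1) / sum_j N(z; mu_j, 1)."""
        m = LucidLayer(n_clusters=2)
        m.beta_ = np.zeros((1, 2))
        m.mu_ = np.array([[-1.0], [1.0]])
        m.sigma2_ = np.array([1.0])
        m.feature_names_ = None
        z = np.array([[0.3], [-0.7]])
        x = np.array([0.0, 0.0])
        R = m.predict_proba(z, x)
        for i in range(2):
            like = scipy.stats.norm.pdf(z[i, 0], [-1.0, 1.0], 1.0)
            np.testing.assert_allclose(R[i], like / like.sum(), atol=1e-12)


class TestEMInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ascent_and_row_normalization(self, seed):
        Z, x, _, _ = two_cluster_data(seed, n=150, p=3, sep=0.8)
        m = LucidLayer(n_clusters=2, random_state=seed).fit(Z, x)
        trace = np.asarray(m.loglik_trace_)
        assert np.all(np.diff(trace) >= -1e-8)
        np.testing.assert_allclose(m.responsibilities_.sum(axis=1), 1.0, atol=1e-8)
        assert (m.responsibilities_ >= 0).all()
        assert np.isfinite(m.bic_)

    def test_permutation_invariance(self):
        """Reordering subjects permutes the IP rows and leaves the
        parameters unchanged (deterministic PC1 init, n_restarts=1)."""
        Z, x, _, _ = two_cluster_data(3, n=200, p=4)
        m1 = LucidLayer(n_clusters=2, n_restarts=1).fit(Z, x)
        perm = np.random.default_rng(0).permutation(200)
        m2 = LucidLayer(n_clusters=2, n_restarts=1).fit(Z[perm], x[perm])
        np.testing.assert_allclose(m1.beta_, m2.beta_, atol=1e-10)
        np.testing.assert_allclose(m1.mu_, m2.mu_, atol=1e-10)
        assert m1.bic_ == pytest.approx(m2.bic_, abs=1e-8)
        np.testing.assert_allclose(
            m1.responsibilities_[perm], m2.responsibilities_, atol=1e-10
        )

    def test_input_validation(self):
        Z, x, _, _ = two_cluster_data(4, n=20, p=2)
        with pytest.raises(ValueError, match="n_clusters"):
            LucidLayer(n_clusters=0).fit(Z, x)
        with pytest.raises(ValueError, match="n > K"):
            LucidLayer(n_clusters=25).fit(Z, x)
        Zbad = Z.copy()
        Zbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            LucidLayer(n_clusters=2).fit(Zbad, x)
        with pytest.raises(ValueError, match="covariance"):
            LucidLayer(n_clusters=2, covariance="full").fit(Z, x)


class TestRecovery:
    def test_single_seed_recovery(self):
        """Well-separated clusters with slope 1: labels, means, and the
        exposure slope sign are all recovered."""
        Z, x, lab, mu = two_cluster_data(7)
        m = LucidLayer(n_clusters=2, random_state=0).fit(Z, x)
        m = lo.align_clusters(m, "anchor", anchor=0)
        ari = adjusted_rand_score(lab, m.predict(Z, x))
        assert ari >= 0.9
        assert np.max(np.abs(m.mu_ - mu)) <= 0.15
        assert m.beta_[0, 1] > 0

    def test_newton_solver_against_sklearn(self):
        """The weighted multinomial M-step matches an unpenalized sklearn
        logistic regression when the weights are hard labels."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        lab = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1])))).astype(int)
        R = np.eye(2)[lab]
        beta = _weighted_multinomial_newton(X, R, np.zeros((1, 2)))
        ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=1000).fit(
            X[:, 1:], lab
        )
        assert beta[0, 0] == pytest.approx(ref.intercept_[0], abs=1e-6)
        assert beta[0, 1] == pytest.approx(ref.coef_[0, 0], abs=1e-6)


class TestSelectK:
    def test_grid_of_one(self):
        Z, x, _, _ = two_cluster_data(8, n=100, p=3)
        chosen, table = lo.select_k_bic(Z, x, k_grid=[1])
        assert chosen == 1
        assert table.shape[0] == 1

    def test_two_cluster_data_prefers_k2(self):
        Z, x, _, _ = two_cluster_data(9, n=400, p=5)
        chosen, table = lo.select_k_bic(Z, x, k_grid=[1, 2, 3], random_state=0)
        assert chosen == 2
        assert table["bic"].idxmin() == 1

    def test_single_gaussian_prefers_k1(self):
        rng = np.random.default_rng(10)
        Z = rng.normal(size=(400, 5))
        x = rng.normal(size=400)
        chosen, _ = lo.select_k_bic(Z, x, k_grid=[1, 2, 3], random_state=0)
        assert chosen == 1


class TestParallel:
    def test_identical_layers_identical_fits(self):
        Z, x, _, _ = two_cluster_data(11, n=200, p=3)
        m = lo.LucidParallel(n_clusters=2, random_state=1).fit(
            {"a": Z, "b": Z.copy()}, x
        )
        np.testing.assert_array_equal(
            m.layer_models_["a"].mu_, m.layer_models_["b"].mu_
        )
        assert m.layer_models_["a"].loglik_ == m.layer_models_["b"].loglik_

    def test_factorization_equals_per_layer_fits(self):
        Za, x, _, _ = two_cluster_data(12, n=200, p=3)
        Zb, _, _, _ = two_cluster_data(13, n=200, p=2)
        joint = lo.LucidParallel(n_clusters=2, random_state=2).fit(
            {"a": Za, "b": Zb}, x
        )
        sep_a = LucidLayer(n_clusters=2, random_state=2).fit(Za, x)
        sep_b = LucidLayer(n_clusters=2, random_state=2).fit(Zb, x)
        assert joint.loglik_ == pytest.approx(sep_a.loglik_ + sep_b.loglik_, abs=1e-10)
        assert joint.layer_models_["a"].loglik_ == pytest.approx(sep_a.loglik_, abs=1e-12)

    def test_mixed_k_fit(self):
        Za, x, _, _ = two_cluster_data(14, n=100, p=2)
        Zb = np.random.default_rng(15).normal(size=(100, 3))
        m = lo.LucidParallel(n_clusters={"a": 2, "b": 1}, random_state=0).fit(
            {"a": Za, "b": Zb}, x
        )
        assert m.layer_models_["a"].mu_.shape[0] == 2
        assert m.layer_models_["b"].mu_.shape[0] == 1

    def test_subject_mismatch_raises(self):
        Za, x, _, _ = two_cluster_data(16, n=100, p=2)
        dfa = pd.DataFrame(Za, index=[f"S{i}" for i in range(100)])
        dfb = pd.DataFrame(Za, index=[f"T{i}" for i in range(100)])
        with pytest.raises(ValueError, match="mismatch"):
            lo.LucidParallel(n_clusters=2).fit({"a": dfa, "b": dfb}, x)


class TestAlignClusters:
    def _fit(self):
        Z, x, _, _ = two_cluster_data(17, n=200, p=3)
        return LucidLayer(n_clusters=2, random_state=0).fit(Z, x), x

    def test_idempotent(self):
        m, x = self._fit()
        a1 = lo.align_clusters(m, "exposure", E=x)
        a2 = lo.align_clusters(a1, "exposure", E=x)
        np.testing.assert_array_equal(a1.mu_, a2.mu_)
        np.testing.assert_array_equal(a1.beta_, a2.beta_)

    def test_swap_then_align_restores(self):
        from lucidomics.lucid import _permute

        m, x = self._fit()
        aligned = lo.align_clusters(m, "exposure", E=x)
        swapped = _permute(aligned, np.array([1, 0]))
        restored = lo.align_clusters(swapped, "exposure", E=x)
        np.testing.assert_allclose(restored.mu_, aligned.mu_, atol=1e-12)
        np.testing.assert_allclose(restored.beta_, aligned.beta_, atol=1e-12)
        np.testing.assert_allclose(
            restored.responsibilities_, aligned.responsibilities_, atol=1e-12
        )

    def test_anchor_rule_orders_by_feature_mean(self):
        m, x = self._fit()
        a = lo.align_clusters(m, "anchor", anchor=0)
        assert a.mu_[0, 0] < a.mu_[1, 0]

    def test_outcome_rule_puts_high_rate_first(self):
        m, x = self._fit()
        lab = m.responsibilities_.argmax(axis=1)
        y = (lab == 1).astype(float)  # cluster 1 has outcome rate 1
        a = lo.align_clusters(m, "outcome", outcome=y)
        lab_a = a.responsibilities_.argmax(axis=1)
        assert y[lab_a == 0].mean() > y[lab_a == 1].mean()

    def test_unknown_rule(self):
        m, x = self._fit()
        with pytest.raises(ValueError, match="unknown"):
            lo.align_clusters(m, "alphabetical")

    def test_swap_preserves_loglik(self):
        from lucidomics.lucid import _permute

        m, x = self._fit()
        swapped = _permute(m, np.array([1, 0]))
        Z, x2, _, _ = two_cluster_data(17, n=200, p=3)
        assert swapped.score(Z, x2) == pytest.approx(m.score(Z, x2), abs=1e-8)


class TestDesignHandling:
    def test_intercept_prepended_once(self):
        x = np.arange(5.0)
        E = _as_design(x)
        assert E.shape == (5, 2)
        np.testing.assert_array_equal(_as_design(E), E)
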