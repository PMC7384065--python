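"""Loss terms: closed forms checked against quadrature and Monte Carlo."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from dmriharm.model import LatentCode
from dmriharm.objectives import (
    LossWeights,
    adversarial_loss,
    kl_to_prior,
    marginal_kl_bound,
    pairwise_gaussian_kl,
    proj_loss,
    recon_loss,
    total_loss,
)
from dmriharm.pipeline import voxel_features
from dmriharm.synthetic import generate_site_volume, make_crossing_phantom


def quadrature_kl(mu_a, sig_a, mu_b, sig_b):
    """Numerical KL between two 1-D Gaussians."""

    def integrand(x):
        p = norm.pdf(x, mu_a, sig_a)
        return p * (norm.logpdf(x, mu_a, sig_a) - norm.logpdf(x, mu_b, sig_b)) \
            if p > 1e-300 else 0.0

    lo, hi = mu_a - 12 * sig_a, mu_a + 12 * sig_a
    val, _ = quad(integrand, lo, hi, limit=200)
    return val


class TestReconLoss:
    def test_identity_zero(self, rng):
        x = rng.standard_normal(637)
        assert recon_loss(x, x) == 0.0

    def test_unit_offset(self, rng):
        x = rng.standard_normal(637)
        assert recon_loss(x + 1.0, x) == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        assert recon_loss(a, b) == pytest.approx(np.mean((a - b) ** 2))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            recon_loss(np.zeros(3), np.zeros(4))


class TestKLToPrior:
    def test_standard_normal_zero(self):
        assert kl_to_prior(LatentCode(np.zeros(32), np.ones(32))) == pytest.approx(0.0)

    def test_unit_mean_half(self):
        assert kl_to_prior(LatentCode([1.0], [1.0])) == pytest.approx(0.5)

    def test_quadrature_oracle(self, rng):
        for _ in range(20):
            d = rng.integers(1, 5)
            mu = rng.normal(0, 2, d)
            sig = rng.uniform(0.2, 3.0, d)
            expected = sum(quadrature_kl(m, s, 0.0, 1.0) for m, s in zip(mu, sig))
            assert kl_to_prior(LatentCode(mu, sig)) == pytest.approx(expected,
                                                                     abs=1e-4)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            LatentCode([0.0], [0.0])


class TestMarginalKLBound:
    def test_identical_codes_zero(self):
        codes = [LatentCode(np.ones(4), np.full(4, 0.5)) for _ in range(5)]
        assert marginal_kl_bound(codes) == pytest.approx(0.0)

    def test_symmetric_pair_hand_value(self):
        """mu = +-a, sigma = 1, 1-dim: bound = mean{0, 2a^2, 2a^2, 0} = a^2."""
        a = 0.8
        codes = [LatentCode([a], [1.0]), LatentCode([-a], [1.0])]
        assert marginal_kl_bound(codes) == pytest.approx(a**2)

    def test_pairwise_kl_quadrature(self, rng):
        for _ in range(20):
            mu = rng.normal(0, 1.5, 2)
            sig = rng.uniform(0.3, 2.0, 2)
            got = pairwise_gaussian_kl(LatentCode([mu[0]], [sig[0]]),
                                       LatentCode([mu[1]], [sig[1]]))
            assert got == pytest.approx(
                quadrature_kl(mu[0], sig[0], mu[1], sig[1]), abs=1e-4)

    def test_bound_dominates_monte_carlo_mixture_kl(self, rng):
        """(1/N^2) sum KL_ij >= E_i KL[q_i || mixture] (MC, 1e4 draws)."""
        for _ in range(10):
            n, d = int(rng.integers(2, 6)), int(rng.integers(1, 4))
            mu = rng.normal(0, 1.5, (n, d))
            sig = rng.uniform(0.3, 1.5, (n, d))
            codes = [LatentCode(mu[i], sig[i]) for i in range(n)]
            bound = marginal_kl_bound(codes)
            mc = _mc_mixture_kl(mu, sig, rng, 10_000)
            assert bound >= mc - 3e-2  # small MC slack

    def test_single_code_rejected(self):
        with pytest.raises(ValueError):
            marginal_kl_bound([LatentCode([0.0], [1.0])])


def _mc_mixture_kl(mu, sig, rng, n_draws):
    """Monte-Carlo average over i of KL[q_i || (1/N) sum_j q_j]."""
    n, d = mu.shape
    total = 0.0
    for i in range(n):
        z = mu[i] + sig[i] * rng.standard_normal((n_draws, d))
        log_qi = norm.logpdf(z, mu[i], sig[i]).sum(axis=1)
        comps = np.stack([norm.logpdf(z, mu[j], sig[j]).sum(axis=1)
                          for j in range(n)])
        log_mix = np.logaddexp.reduce(comps, axis=0) - np.log(n)
        total += np.mean(log_qi - log_mix)
    return total / n


class TestProjLoss:
    @pytest.fixture(scope="class")
    def voxel_setup(self, two_site_profiles, spec, table):
        phantom = make_crossing_phantom((5, 5, 5), seed=2)
        vol = generate_site_volume(phantom, two_site_profiles[0], seed=0,
                                   noise_free=True)
        voxel = tuple(np.argwhere(vol.mask)[3])
        feat = voxel_features(vol, voxel, spec, table)
        return feat, vol.data[voxel], vol.scheme

    def test_fitted_features_zero_loss(self, voxel_setup, spec, table):
        feat, raw, scheme = voxel_setup
        # 30 directions/shell < 45 coeffs: interpolation is exact
        assert proj_loss(feat, raw, scheme, spec, table) < 1e-14

    def test_zero_against_zero(self, voxel_setup, spec, table):
        _, raw, scheme = voxel_setup
        assert proj_loss(np.zeros(91), np.zeros_like(raw), scheme, spec,
                         table) == 0.0

    def test_quadratic_in_perturbation(self, voxel_setup, spec, table):
        feat, raw, scheme = voxel_setup
        losses = []
        for delta in (0.01, 0.02, 0.04):
            f = feat.copy()
            f[3] += delta
            losses.append(proj_loss(f, raw, scheme, spec, table))
        assert losses[1] / losses[0] == pytest.approx(4.0, rel=1e-6)
        assert losses[2] / losses[1] == pytest.approx(4.0, rel=1e-6)

    def test_scheme_mismatch_rejected(self, voxel_setup, spec, table):
        feat, raw, scheme = voxel_setup
        with pytest.raises(ValueError):
            proj_loss(feat, raw[:-1], scheme, spec, table)


class TestAdversarialLoss:
    def test_uniform_logits_ln_k(self):
        assert adversarial_loss(np.zeros(4), np.eye(4)[1]) == pytest.approx(
            np.log(4.0))

    def test_confident_true_class_near_zero(self):
        logits = np.array([50.0, 0.0, 0.0])
        assert adversarial_loss(logits, np.eye(3)[0]) == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_matches_direct_formula(self, rng):
        logits = rng.standard_normal(5)
        s = np.eye(5)[2]
        expected = -np.log(np.exp(logits)[2] / np.exp(logits).sum())
        assert adversarial_loss(logits, s) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            adversarial_loss(np.array([np.inf, 0.0]), np.eye(2)[0])


class TestTotalLoss:
    def test_zero_weights_reduce_to_recon(self):
        w = LossWeights(alpha=0, beta=0, gamma=0, lambda_=0)
        assert total_loss(0.3, 1.0, 2.0, 3.0, 4.0, w).total == pytest.approx(0.3)

    def test_unit_parts_default_weights(self):
        out = total_loss(1.0, 1.0, 1.0, 1.0, 1.0, LossWeights())
        assert out.total == pytest.approx(1 + 1 + 0.01 + 1 - 10)  # -6.99

    def test_affine_in_each_part(self, rng):
        w = LossWeights()
        base = dict(recon=0.5, prior_kl=1.0, marginal=0.2, proj=0.4, adv=0.7)
        coefs = dict(recon=1.0, prior_kl=w.alpha, marginal=w.lambda_,
                     proj=w.beta, adv=-w.gamma)
        t0 = total_loss(**base, w=w).total
        for part, coef in coefs.items():
            bumped = dict(base)
            bumped[part] += 0.25
            assert total_loss(**bumped, w=w).total - t0 == pytest.approx(
                coef * 0.25)

    def test_one_plus_lambda_flag(self):
        w = LossWeights(recon_one_plus_lambda=True, alpha=0, beta=0, gamma=0)
        assert total_loss(2.0, 0.0, 0.0, 0.0, 0.0, w).total == pytest.approx(
            2.0 * 1.01)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.nan, 0, 0, 0, 0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)


class TestEvidenceBound:
    def test_elbo_below_log_evidence_linear_gaussian(self, rng):
        """For x = W z + eps the ELBO never exceeds the exact log evidence."""
        d_z, d_x = 2, 3
        W = rng.standard_normal((d_x, d_z))
        cov_x = W @ W.T + np.eye(d_x)
        from scipy.stats import multivariate_normal

        for _ in range(10):
            x = multivariate_normal.rvs(np.zeros(d_x), cov_x,
                                        random_state=rng.integers(1 << 31))
            log_ev = multivariate_normal.logpdf(x, np.zeros(d_x), cov_x)
            mu_q = rng.normal(0, 1, d_z)
            sig_q = rng.uniform(0.3, 1.5, d_z)
            # E_q[log N(x; Wz, I)] in closed form for diagonal-Gaussian q
            mean_term = -0.5 * np.sum((x - W @ mu_q) ** 2)
            trace_term = -0.5 * np.sum((W**2) @ sig_q**2)
            const = -0.5 * d_x * np.log(2 * np.pi)
            elbo = (mean_term + trace_term + const
                    - kl_to_prior(LatentCode(mu_q, sig_q)))
            assert elbo <= log_ev + 1e-9
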