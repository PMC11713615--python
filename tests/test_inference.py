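"""Priors, latent posteriors, the hyperparameter M-step, and the MLE / MAP /
GML estimators."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import isingnet as ng
from isingnet import (EffectiveNetwork, Hyperparameters, LatentPosteriors,
                      NetworkGeometry, OptimizerConfig, SpikeRaster)
from isingnet.inference import (classify_arrays, coupling_log_density,
                                evidence_objective, gml_fit,
                                hyperparameters_from_mle, link_prior,
                                log_prior_H, map_fit, mle_fit, posterior_phi,
                                posterior_z, posteriors_all,
                                update_hyperparameters, _micro_em)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

class TestPriors:
    def test_field_prior_at_its_peak(self):
        rho = Hyperparameters(mu_H=0.3, v_H=0.7)
        n = 4
        expected = n * (-0.5 * math.log(2 * math.pi * 0.7))
        assert log_prior_H(np.full(n, 0.3), rho) == pytest.approx(expected)

    def test_field_prior_standard_normal_value(self):
        rho = Hyperparameters(mu_H=0.0, v_H=1.0)
        expected = math.log(math.exp(-0.5) / math.sqrt(2 * math.pi))
        assert log_prior_H(np.array([1.0]), rho) == pytest.approx(expected)

    def test_field_prior_translation_invariance(self):
        H = np.array([0.1, -0.4, 2.0])
        a = log_prior_H(H, Hyperparameters(mu_H=0.2))
        b = log_prior_H(H + 5.0, Hyperparameters(mu_H=5.2))
        assert a == pytest.approx(b)

    def test_spike_density_at_zero(self):
        rho = Hyperparameters(epsilon=1e-4)
        expected = -0.5 * math.log(2 * math.pi * 1e-4)
        assert coupling_log_density(0.0, 0, 1, rho) == pytest.approx(expected)

    def test_sign_indicator_kills_wrong_sign(self):
        rho = Hyperparameters()
        assert coupling_log_density(-0.3, 1, +1, rho) == -np.inf
        assert coupling_log_density(0.3, 1, -1, rho) == -np.inf

    def test_lognormal_at_its_log_location(self):
        rho = Hyperparameters(mu_Jp=-1.0, v_Jp=0.4)
        expected = 1.0 - 0.5 * math.log(2 * math.pi * 0.4)
        assert coupling_log_density(math.exp(-1.0), 1, +1, rho) == pytest.approx(expected)

    def test_link_prior_no_decay(self):
        geom = NetworkGeometry(l=np.array([[0.0, 3.0], [3.0, 0.0]]),
                               theta=np.array([[1.0, 0.4], [0.4, 1.0]]))
        rho = Hyperparameters(a=0.0)
        assert link_prior(1, 0, 1, geom, rho) == pytest.approx(0.4)
        assert link_prior(0, 0, 1, geom, rho) == pytest.approx(0.6)

    def test_link_prior_exponential_decay(self):
        geom = NetworkGeometry(l=np.array([[0.0, 10.0], [10.0, 0.0]]),
                               theta=np.ones((2, 2)))
        rho = Hyperparameters(a=0.1)
        assert link_prior(1, 0, 1, geom, rho) == pytest.approx(math.exp(-1.0))

    def test_link_prior_vanishes_at_infinity(self):
        geom = NetworkGeometry(l=np.array([[0.0, 1e9], [1e9, 0.0]]),
                               theta=np.ones((2, 2)))
        assert link_prior(1, 0, 1, geom, Hyperparameters(a=0.1)) == pytest.approx(0.0)

    def test_link_prior_normalises(self):
        geom = NetworkGeometry(l=np.full((2, 2), 7.0) - 7.0 * np.eye(2),
                               theta=np.full((2, 2), 0.3))
        rho = Hyperparameters(a=0.05)
        total = link_prior(0, 0, 1, geom, rho) + link_prior(1, 0, 1, geom, rho)
        assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# latent posteriors vs brute-force enumeration
# ---------------------------------------------------------------------------

def enumeration_posteriors(net, rho, geometry):
    """Brute force over the 2-state z and 2-state φ joint, scalar path."""
    n = net.n_units
    pz = np.zeros(n)
    pphi = np.zeros((n, n))
    for j in range(n):
        mass = {}
        for z in (+1, -1):
            prior = rho.gamma if z > 0 else 1.0 - rho.gamma
            total = math.log(prior) if prior > 0 else -math.inf
            for l in range(n):
                if l == j:
                    continue
                per_phi = []
                for phi in (0, 1):
                    lp = math.log(link_prior(phi, l, j, geometry, rho)) \
                        if link_prior(phi, l, j, geometry, rho) > 0 else -math.inf
                    per_phi.append(lp + coupling_log_density(net.J[l, j], phi, z, rho))
                total += np.logaddexp(per_phi[0], per_phi[1])
            mass[z] = total
        norm = np.logaddexp(mass[+1], mass[-1])
        pz[j] = math.exp(mass[+1] - norm)
        for i in range(n):
            if i == j:
                continue
            mix = 0.0
            for z, w in ((+1, pz[j]), (-1, 1.0 - pz[j])):
                lp = [math.log(link_prior(phi, i, j, geometry, rho))
                      if link_prior(phi, i, j, geometry, rho) > 0 else -math.inf
                      for phi in (0, 1)]
                l0 = lp[0] + coupling_log_density(net.J[i, j], 0, z, rho)
                l1 = lp[1] + coupling_log_density(net.J[i, j], 1, z, rho)
                mix += w * math.exp(l1 - np.logaddexp(l0, l1))
            pphi[i, j] = mix
    return pz, pphi


class TestLatentPosteriors:
    def _setup(self, seed=0, n=4):
        rng = np.random.default_rng(seed)
        J = rng.normal(0, 0.4, (n, n))
        H = rng.normal(0, 0.3, n)
        net = EffectiveNetwork(J=J, H=H)
        l = np.abs(rng.normal(0, 20, (n, n))) * (1 - np.eye(n))
        geom = NetworkGeometry(l=(l + l.T) / 2, theta=np.full((n, n), 0.6))
        rho = Hyperparameters(gamma=0.7, a=0.02, mu_Jp=-1.2, v_Jp=0.5,
                              mu_Jm=-1.0, v_Jm=0.6, epsilon=1e-3)
        return net, geom, rho

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_enumeration_oracle(self, seed):
        net, geom, rho = self._setup(seed)
        lat = posteriors_all(net, rho, geom)
        pz_ref, pphi_ref = enumeration_posteriors(net, rho, geom)
        np.testing.assert_allclose(lat.pz, pz_ref, atol=1e-10)
        od = ~np.eye(net.n_units, dtype=bool)
        np.testing.assert_allclose(lat.pphi[od], pphi_ref[od], atol=1e-10)

    def test_all_excitatory_prior_forces_type(self):
        net, geom, _ = self._setup()
        rho = Hyperparameters(gamma=1.0)
        lat = posteriors_all(net, rho, geom)
        np.testing.assert_allclose(lat.pz, 1.0)

    def test_consistent_positive_column_is_excitatory(self):
        n = 4
        J = np.full((n, n), 0.5)
        np.fill_diagonal(J, -0.2)
        net = EffectiveNetwork(J=J, H=np.zeros(n))
        geom = NetworkGeometry.uniform(n, theta=0.5)
        rho = Hyperparameters(gamma=0.5, mu_Jp=-0.7, v_Jp=0.5,
                              mu_Jm=-0.7, v_Jm=0.5)
        assert posterior_z(net, rho, geom, 1) > 0.99

    def test_zero_couplings_fall_back_to_prior_symmetry(self):
        n = 3
        net = EffectiveNetwork(J=np.zeros((n, n)), H=np.zeros(n))
        geom = NetworkGeometry.uniform(n, theta=0.5)
        rho = Hyperparameters(gamma=0.5, mu_Jp=-1.0, v_Jp=0.5,
                              mu_Jm=-1.0, v_Jm=0.5)
        assert posterior_z(net, rho, geom, 0) == pytest.approx(0.5)

    def test_theta_zero_forbids_links(self):
        net, geom, rho = self._setup()
        geom.theta = np.zeros_like(geom.theta)
        lat = posteriors_all(net, rho, geom)
        od = ~np.eye(net.n_units, dtype=bool)
        np.testing.assert_allclose(lat.pphi[od], 0.0)

    def test_slab_scale_coupling_is_a_link(self):
        n = 2
        rho = Hyperparameters(gamma=0.5, a=0.0, mu_Jp=-1.0, v_Jp=0.3,
                              mu_Jm=-1.0, v_Jm=0.3, epsilon=1e-4)
        J = np.array([[0.0, math.exp(-1.0)], [0.0, 0.0]])
        net = EffectiveNetwork(J=J, H=np.zeros(n))
        geom = NetworkGeometry.uniform(n, theta=0.5)
        lat = posteriors_all(net, rho, geom)
        assert posterior_phi(net, lat, rho, geom, 0, 1) > 0.99


# ---------------------------------------------------------------------------
# hyperparameter M-step / micro EM
# ---------------------------------------------------------------------------

class TestHyperparameterUpdates:
    def _hard_latents(self, J, pz):
        n = J.shape[0]
        pz = np.asarray(pz, dtype=float)
        cond_pos = ((J > 0).astype(float))
        cond_neg = ((J < 0).astype(float))
        pphi = pz[None, :] * cond_pos + (1 - pz)[None, :] * cond_neg
        return LatentPosteriors(pz=pz, pphi=pphi,
                                pphi_pos=cond_pos, pphi_neg=cond_neg)

    def test_hard_type_posteriors_give_fraction(self):
        rng = np.random.default_rng(0)
        J = rng.normal(0, 0.5, (5, 5))
        net = EffectiveNetwork(J=J, H=rng.normal(0, 1, 5))
        geom = NetworkGeometry.uniform(5)
        lat = self._hard_latents(J, [1, 0, 1, 1, 0])
        rho = update_hyperparameters(net, lat, geom, Hyperparameters())
        assert rho.gamma == pytest.approx(3 / 5)

    def test_location_update_matches_numeric_maximiser(self):
        rng = np.random.default_rng(1)
        n = 6
        z = np.array([1, 1, 1, 1, 0, 0])
        J = np.abs(rng.lognormal(-1.0, 0.5, (n, n)))
        J[:, z == 0] *= -1.0
        np.fill_diagonal(J, 0.1)
        net = EffectiveNetwork(J=J, H=np.zeros(n))
        geom = NetworkGeometry.uniform(n)
        lat = self._hard_latents(J, z)
        rho = update_hyperparameters(net, lat, geom, Hyperparameters())
        od = ~np.eye(n, dtype=bool)
        vals = np.log(J[:, z == 1][od[:, z == 1]])
        assert rho.mu_Jp == pytest.approx(vals.mean(), abs=1e-12)
        # numeric maximiser of the weighted log-normal likelihood in mu
        neg = lambda mu: np.sum((vals - mu) ** 2)
        res = minimize_scalar(neg, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-8})
        assert rho.mu_Jp == pytest.approx(res.x, abs=1e-6)

    def test_dense_link_beliefs_drive_decay_to_zero(self):
        rng = np.random.default_rng(2)
        n = 4
        J = np.abs(rng.normal(0.5, 0.1, (n, n)))
        net = EffectiveNetwork(J=J, H=np.zeros(n))
        l = np.abs(rng.normal(0, 30, (n, n)))
        l = (l + l.T) / 2
        np.fill_diagonal(l, 0)
        geom = NetworkGeometry(l=l, theta=np.ones((n, n)))
        lat = self._hard_latents(J, np.ones(n))
        rho = update_hyperparameters(net, lat, geom,
                                     Hyperparameters(a=0.3))
        assert rho.a == pytest.approx(0.0, abs=1e-6)

    def test_zero_responsibility_keeps_previous_value(self):
        n = 3
        J = np.abs(np.random.default_rng(3).lognormal(-1, 0.3, (n, n)))
        net = EffectiveNetwork(J=J, H=np.zeros(n))  # no negative couplings
        geom = NetworkGeometry.uniform(n)
        lat = self._hard_latents(J, np.ones(n))
        old = Hyperparameters(mu_Jm=-2.5, v_Jm=0.123)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = update_hyperparameters(net, lat, geom, old)
        assert rho.mu_Jm == old.mu_Jm
        assert rho.v_Jm == old.v_Jm

    @pytest.mark.parametrize("seed", range(3))
    def test_micro_em_objective_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        z = np.where(rng.random(n) < 0.7, 1, -1)
        J = rng.lognormal(-1.2, 0.6, (n, n)) * z[None, :]
        J[rng.random((n, n)) < 0.5] = 0.0
        net = EffectiveNetwork(J=J, H=rng.normal(-0.5, 0.5, n))
        geom = NetworkGeometry.uniform(n, theta=0.5)
        rho0 = Hyperparameters(gamma=0.6, a=0.1)
        _, _, trace = _micro_em(net, rho0, geom, OptimizerConfig())
        diffs = np.diff(trace)
        assert (diffs >= -1e-8).all()


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class TestEstimators:
    @pytest.fixture(scope="class")
    def generated(self):
        rng = np.random.default_rng(42)
        N = 5
        net = EffectiveNetwork(J=rng.normal(0, 0.35, (N, N)),
                               H=rng.normal(0, 0.3, N))
        raster = ng.simulate(net, 60_000, seed=7)
        return net, raster

    def test_mle_recovers_couplings(self, generated):
        net, raster = generated
        fit = mle_fit(raster, OptimizerConfig(max_iter=800))
        assert np.corrcoef(fit.J.ravel(), net.J.ravel())[0, 1] >= 0.95
        dJ, dH = ng.likelihood_gradients(raster, fit)
        scale = raster.n_bins - 1
        assert max(np.abs(dJ).max(), np.abs(dH).max()) / scale < 1e-3

    def test_mle_couplings_shrink_for_uncoupled_data(self):
        N = 4
        truth = EffectiveNetwork(J=np.zeros((N, N)), H=np.zeros(N))
        fits = []
        for T in (5000, 80_000):
            raster = ng.simulate(truth, T, seed=3)
            fit = mle_fit(raster, OptimizerConfig(max_iter=500))
            fits.append(np.abs(fit.J).mean())
        assert fits[1] < fits[0]
        assert fits[1] < 3.0 / np.sqrt(80_000) * 4

    def test_always_active_unit_hits_field_cap(self):
        states = np.ones((1, 50), dtype=int)
        raster = SpikeRaster(states=states, tau=0.1)
        with pytest.warns(UserWarning, match="cap"):
            fit = mle_fit(raster, OptimizerConfig(max_iter=200))
        assert fit.H[0] == pytest.approx(20.0)

    def test_map_reduces_to_mle_under_flat_priors(self, generated):
        _, raster = generated
        cfg = OptimizerConfig(max_iter=800)
        mle = mle_fit(raster, cfg)
        flat = Hyperparameters(gamma=0.5, a=0.0, mu_H=0.0, v_H=1e4,
                               mu_Jp=0.0, v_Jp=1e4, mu_Jm=0.0, v_Jm=1e4,
                               epsilon=1e4)
        geom = NetworkGeometry.uniform(raster.n_units, theta=0.5)
        res = map_fit(raster, flat, geom, cfg, init=mle)
        np.testing.assert_allclose(res.net.J, mle.J, atol=0.02)
        np.testing.assert_allclose(res.net.H, mle.H, atol=0.02)

    def test_tight_spike_and_no_links_drive_couplings_to_zero(self, generated):
        _, raster = generated
        cfg = OptimizerConfig(max_iter=500)
        rho = Hyperparameters(gamma=0.5, epsilon=1e-6)
        geom = NetworkGeometry.uniform(raster.n_units, theta=0.0)
        res = map_fit(raster, rho, geom, cfg, init="mle")
        od = ~np.eye(raster.n_units, dtype=bool)
        assert np.abs(res.net.J[od]).max() < 0.05  # vs couplings ~0.35 in the data

    def test_single_macro_iteration_equals_map(self, generated):
        _, raster = generated
        cfg = OptimizerConfig(max_iter=300, max_macro_iters=1)
        geom = NetworkGeometry.uniform(raster.n_units, theta=0.5)
        mle = mle_fit(raster, cfg)
        rho = hyperparameters_from_mle(mle, Hyperparameters(gamma=0.8, a=0.1))
        res_map = map_fit(raster, rho, geom, cfg, init=mle)
        res_gml = gml_fit(raster, geom, rho_init=rho, config=cfg, init=mle)
        np.testing.assert_array_equal(res_map.net.J, res_gml.net.J)
        np.testing.assert_array_equal(res_map.net.H, res_gml.net.H)

    def test_evidence_with_flat_priors_tracks_likelihood(self, generated):
        net, raster = generated
        flat = Hyperparameters(gamma=0.5, a=0.0, v_H=1e6, v_Jp=1e6,
                               v_Jm=1e6, epsilon=1e6)
        # theta=0 keeps only the (essentially flat) wide spike component
        geom = NetworkGeometry.uniform(raster.n_units, theta=0.0)
        ev = evidence_objective(raster, net, flat, geom)
        ll = ng.log_likelihood(raster, net)
        shifted = EffectiveNetwork(J=net.J * 1.1, H=net.H * 0.9)
        ev2 = evidence_objective(raster, shifted, flat, geom)
        ll2 = ng.log_likelihood(raster, shifted)
        # with flat priors, evidence differences are likelihood differences
        assert (ev - ev2) == pytest.approx(ll - ll2, rel=1e-3, abs=0.5)


class TestClassify:
    def test_type_sign_rule(self):
        lat = LatentPosteriors(pz=np.array([0.9, 0.1]),
                               pphi=np.zeros((2, 2)))
        z_hat, phi_hat, Je = classify_arrays(np.ones((2, 2)), lat)
        np.testing.assert_array_equal(z_hat, [1, -1])
        assert phi_hat.sum() == 0
        assert np.all(Je == 0)

    def test_tie_goes_to_majority_class(self):
        lat = LatentPosteriors(pz=np.array([0.5]), pphi=np.zeros((1, 1)))
        z_hat, _, _ = classify_arrays(np.zeros((1, 1)), lat)
        assert z_hat[0] == 1

    def test_threshold_masks_couplings(self):
        J = np.array([[0.0, 0.7], [0.3, 0.0]])
        lat = LatentPosteriors(pz=np.array([0.9, 0.9]),
                               pphi=np.array([[0.0, 0.8], [0.4, 0.0]]))
        _, phi_hat, Je = classify_arrays(J, lat, phi_threshold=0.5)
        assert phi_hat[0, 1] == 1 and phi_hat[1, 0] == 0
        assert Je[0, 1] == pytest.approx(0.7) and Je[1, 0] == 0.0


class TestGmlRecovery:
    def test_sign_structured_columns_recovered(self):
        # generative-model data: 80/20 type split, spike-and-slab couplings
        rng = np.random.default_rng(5)
        N = 12
        z = np.array([1] * 9 + [-1] * 3)
        phi = rng.random((N, N)) < 0.4
        J = np.where(phi, rng.lognormal(-1.2, np.sqrt(0.3), (N, N)), 0.0)
        J *= z[None, :]
        np.fill_diagonal(J, -0.3)
        net = EffectiveNetwork(J=J, H=rng.normal(-0.5, 0.3, N))
        raster = ng.simulate(net, 50_000, seed=6)
        geom = NetworkGeometry.uniform(N, theta=0.5)
        res = gml_fit(raster, geom, config=OptimizerConfig(
            max_iter=600, max_macro_iters=4))
        assert np.mean(res.z_hat == z) >= 0.9
        assert abs(res.rho.gamma - 0.75) <= 0.15
        rep = ng.link_metrics(J, res.phi_hat)
        assert rep.TPR > rep.FPR
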