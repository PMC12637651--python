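"""Parameterization stack: marginal inversion, contrasting, reweighting."""

import math

import numpy as np
import pytest
from scipy.special import expit

from bfbdna.constants import KB
from bfbdna.fit import (ESSRegularizerSettings, EnsembleBatch,
                        ObservableTarget, ParameterVector, ReferenceEnsemble,
                        ReweightingState, boltzmann_invert_marginal,
                        contrastive_loss, effective_sample_size,
                        ess_regularizer, finetune, observable_matching_loss,
                        optimize_contrast, reweight_observable, softplus,
                        inv_softplus)

KT = KB * 300.0


def _sample_pdf(grid, pdf, n, rng):
    """Inverse-CDF sampling on a dense grid (independent of the fitting path)."""
    cdf = np.cumsum(pdf)
    cdf = cdf / cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


class TestBoltzmannInversion:
    def test_bond_recovery(self):
        """r^2-weighted Gaussian bond marginal: k2 within 5%, x0 within 0.5%."""
        k2, x0 = 100.0, 0.5
        rng = np.random.default_rng(12)
        grid = np.linspace(0.2, 0.8, 6000)
        pdf = grid**2 * np.exp(-k2 * (grid - x0) ** 2 / KT)
        samples = _sample_pdf(grid, pdf, 100_000, rng)
        coeffs, info = boltzmann_invert_marginal(samples, "bond", 300.0)
        assert coeffs.k2 == pytest.approx(k2, rel=0.05)
        assert coeffs.x0 == pytest.approx(x0, rel=0.005)

    def test_symmetric_samples_give_small_k3(self):
        k2, x0 = 80.0, 2.0
        rng = np.random.default_rng(5)
        grid = np.linspace(1.5, 2.5, 4000)
        pdf = np.sin(grid) * np.exp(-k2 * (grid - x0) ** 2 / KT)
        samples = _sample_pdf(grid, pdf, 80_000, rng)
        coeffs, _ = boltzmann_invert_marginal(samples, "angle", 300.0)
        assert coeffs.k2 == pytest.approx(k2, rel=0.1)
        assert abs(coeffs.k3) < 0.25 * coeffs.k2

    def test_dihedral_cosine_recovery(self):
        k, phase = 6.0, 0.8
        rng = np.random.default_rng(8)
        grid = np.linspace(-np.pi, np.pi, 8000)
        pdf = np.exp(-k * (1 + np.cos(grid + phase)) / KT)
        samples = _sample_pdf(grid, pdf, 80_000, rng)
        (k_fit, phase_fit), _ = boltzmann_invert_marginal(samples, "dihedral", 300.0)
        assert k_fit == pytest.approx(k, rel=0.1)
        assert phase_fit == pytest.approx(phase, abs=0.05)

    def test_narrow_uniform_flags_ill_conditioned(self):
        rng = np.random.default_rng(2)
        samples = rng.uniform(1.0, 1.05, 5000)
        coeffs, info = boltzmann_invert_marginal(samples, "angle", 300.0,
                                                 n_bins=30, min_count=5)
        assert any("ill-conditioned" in w for w in info["warnings"])

    def test_multimodal_warns(self):
        rng = np.random.default_rng(4)
        samples = np.concatenate([rng.normal(0.4, 0.03, 30000),
                                  rng.normal(0.8, 0.03, 30000)])
        _, info = boltzmann_invert_marginal(samples, "bond", 300.0)
        assert "multimodal" in info["warnings"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="500"):
            boltzmann_invert_marginal(np.ones(100), "bond", 300.0)


class _ScalarBondBatch:
    """Duck-typed ensemble of scalar bond lengths for contrasting tests."""

    def __init__(self, r):
        self.r = np.asarray(r, float)

    @property
    def n(self):
        return len(self.r)


class _ScalarBondModel:
    """U = k2 (r - x0)^2 with k2 softplus-reparameterized; x0 fixed."""

    def __init__(self, k2, x0):
        self.theta = np.array([inv_softplus(k2)])
        self.x0 = x0

    def vector(self):
        return self.theta.copy()

    def set_vector(self, theta):
        self.theta = np.asarray(theta, float).copy()

    @property
    def k2(self):
        return float(softplus(self.theta[0]))

    def energies(self, batch):
        return self.k2 * (batch.r - self.x0) ** 2

    def param_grad(self, batch, coeff, theta):
        d2 = (batch.r - self.x0) ** 2
        return np.array([np.sum(coeff * d2) * expit(theta[0])])


class TestContrastiveLoss:
    def _batches(self, k_data=80.0, k_noise=40.0, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        x0, beta = 0.5, 1.0 / KT
        sd = lambda k: math.sqrt(1.0 / (2 * beta * k))
        data = _ScalarBondBatch(x0 + sd(k_data) * rng.standard_normal(n))
        noise = _ScalarBondBatch(x0 + sd(k_noise) * rng.standard_normal(n))
        noise_model = _ScalarBondModel(k_noise, x0)
        ne = (noise_model.energies(data), noise_model.energies(noise))
        return data, noise, ne, beta, x0

    def test_equal_model_and_noise_gives_2ln2(self):
        data, noise, ne, beta, x0 = self._batches(k_data=40.0, k_noise=40.0)
        model = _ScalarBondModel(40.0, x0)
        loss, _ = contrastive_loss(model.vector(), model, data, noise, ne, beta,
                                   want_grad=False)
        # U_theta == U_noise everywhere -> h == 0 -> loss = 2 ln 2
        assert loss == pytest.approx(2 * math.log(2), rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        data, noise, ne, beta, x0 = self._batches()
        model = _ScalarBondModel(55.0, x0)
        theta = model.vector()
        loss, grad, d_logz = contrastive_loss(theta, model, data, noise, ne, beta)
        h = 1e-6
        lp, _ = contrastive_loss(theta + h, model, data, noise, ne, beta,
                                 want_grad=False)
        lm, _ = contrastive_loss(theta - h, model, data, noise, ne, beta,
                                 want_grad=False)
        fd = (lp - lm) / (2 * h)
        assert grad[0] == pytest.approx(fd, rel=1e-5)
        lzp, _ = contrastive_loss(theta, model, data, noise, ne, beta,
                                  log_z=h, want_grad=False)
        lzm, _ = contrastive_loss(theta, model, data, noise, ne, beta,
                                  log_z=-h, want_grad=False)
        assert d_logz == pytest.approx((lzp - lzm) / (2 * h), rel=1e-5)

    def test_perfect_separation_saturates_to_zero(self):
        data, noise, ne, beta, x0 = self._batches()
        model = _ScalarBondModel(80.0, x0)
        # shift model energies hugely in favour of data
        ne_shifted = (ne[0] + 1e4, ne[1] - 1e4)
        loss, _ = contrastive_loss(model.vector(), model, data, noise,
                                   ne_shifted, beta, want_grad=False)
        assert loss < 1e-6

    def test_recovery_of_known_stiffness(self):
        """Data k2=80, noise k2=40, optimization from 40 recovers ~80."""
        data, noise, ne, beta, x0 = self._batches(seed=3)
        model = _ScalarBondModel(40.0, x0)
        theta, trace = optimize_contrast(model, data, noise, ne, beta,
                                         n_steps=3000, lr=0.05)
        assert model.k2 == pytest.approx(80.0, rel=0.10)
        smooth = np.convolve(trace, np.ones(25) / 25, mode="valid")
        assert smooth[-1] <= smooth[0]
        assert np.all(np.diff(np.minimum.accumulate(smooth)) <= 1e-12)

    def test_data_equals_noise_no_drift(self):
        data, noise, ne, beta, x0 = self._batches(k_data=40.0, k_noise=40.0,
                                                  seed=9)
        model = _ScalarBondModel(40.0, x0)
        optimize_contrast(model, data, noise, ne, beta, n_steps=200, lr=0.02)
        assert model.k2 == pytest.approx(40.0, rel=0.15)


class TestReweighting:
    def test_reference_equals_plain_mean(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=50)
        obs = rng.normal(size=50)
        st = ReweightingState(u0=u, u1=u.copy(), beta=2.0)
        assert reweight_observable(obs, st) == pytest.approx(obs.mean())

    def test_additive_constant_cancels(self):
        rng = np.random.default_rng(1)
        u0 = rng.normal(size=40)
        u1 = u0 + rng.normal(scale=0.3, size=40)
        obs = rng.normal(size=40)
        a = reweight_observable(obs, ReweightingState(u0=u0, u1=u1, beta=1.0))
        b = reweight_observable(obs, ReweightingState(u0=u0, u1=u1 + 7.3, beta=1.0))
        assert a == pytest.approx(b)

    def test_two_sample_hand_value(self):
        st = ReweightingState(u0=np.zeros(2), u1=np.array([0.0, math.log(2)]),
                              beta=1.0)
        assert reweight_observable(np.array([1.0, 2.0]), st) == pytest.approx(4 / 3)

    def test_ess_identities(self):
        assert effective_sample_size(np.ones(11)) == pytest.approx(11.0)
        assert effective_sample_size(np.array([0.0, 0.0, 3.0])) == pytest.approx(1.0)
        assert effective_sample_size(np.array([2.0, 1.0, 1.0])) == pytest.approx(16 / 6)
        rng = np.random.default_rng(2)
        w = rng.random(100)
        assert 1.0 <= effective_sample_size(w) <= 100.0

    def test_ess_shift_stability(self):
        u0 = np.zeros(3)
        st = ReweightingState(u0=u0, u1=np.array([1e4, 1e4 + 1, 1e4 + 2]), beta=1.0)
        assert np.isfinite(st.ess)


class TestESSRegularizer:
    def test_value_at_ess0(self):
        s = ESSRegularizerSettings(alpha=100.0, ess0=750.0)
        assert ess_regularizer(750.0, s) == pytest.approx(math.log(2) / 100.0)

    def test_large_ess_vanishes(self):
        s = ESSRegularizerSettings()
        assert ess_regularizer(5000.0, s) == pytest.approx(0.0, abs=1e-12)

    def test_small_ess_linear_asymptote(self):
        s = ESSRegularizerSettings()
        assert ess_regularizer(100.0, s) == pytest.approx((750.0 - 100.0) / 2, rel=1e-6)

    def test_monotone_decreasing(self):
        s = ESSRegularizerSettings()
        vals = [ess_regularizer(e, s) for e in (10, 300, 750, 1500)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _toy_ensemble(k_ref, n, seed, target_value, ess0_settings):
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=math.sqrt(1.0 / (2 * k_ref)), size=n)

    def energy_fn(theta):
        k = softplus(theta[0])
        return k * x**2, (x**2 * expit(theta[0]))[:, None]

    return ReferenceEnsemble(target=ObservableTarget("toy", target_value),
                             obs=x**2, u0=k_ref * x**2, energy_fn=energy_fn,
                             beta=1.0)


class TestFineTuning:
    SETTINGS = ESSRegularizerSettings(alpha=100.0, ess0=750.0)

    def test_om_gradient_matches_finite_differences(self):
        ens = _toy_ensemble(1.0, 2000, 3, 0.25, self.SETTINGS)
        theta = np.array([inv_softplus(1.3)])
        loss, grad, _ = observable_matching_loss(theta, [ens], self.SETTINGS)
        h = 1e-6
        lp, _, _ = observable_matching_loss(theta + h, [ens], self.SETTINGS,
                                            want_grad=False)
        lm, _, _ = observable_matching_loss(theta - h, [ens], self.SETTINGS,
                                            want_grad=False)
        assert grad[0] == pytest.approx((lp - lm) / (2 * h), rel=1e-5)

    def test_target_at_current_estimate_leaves_only_regularizer(self):
        ens = _toy_ensemble(1.0, 2000, 5, 0.0, self.SETTINGS)
        theta = np.array([inv_softplus(1.0)])
        # set the target to the model's own estimate: zero mismatch gradient
        _, _, diag = observable_matching_loss(theta, [ens], self.SETTINGS)
        ens.target.value = diag["estimates"][0]
        loss, grad, diag = observable_matching_loss(theta, [ens], self.SETTINGS)
        assert abs(grad[0]) < 1e-10
        assert loss == pytest.approx(ess_regularizer(diag["min_ess"], self.SETTINGS))

    def test_harmonic_stiffness_recovery(self):
        """Fine-tune k from 1 toward the k*=2 target <x^2> = 1/(2k*)."""
        settings = self.SETTINGS

        def make_ensembles(theta):
            k = float(softplus(theta[0]))
            return [_toy_ensemble(k, 2000, 17, 0.25, settings)]

        theta0 = np.array([inv_softplus(1.0)])
        theta, trace, refreshes = finetune(theta0, make_ensembles, settings,
                                           n_steps=300, lr=0.02)
        k_final = float(softplus(theta[0]))
        assert k_final == pytest.approx(2.0, rel=0.05)
        assert trace[-1] < trace[0]  # loss decreased over the first cycle
        # ESS stayed above the refresh floor throughout
        ens = make_ensembles(theta)
        _, _, diag = observable_matching_loss(theta, ens, settings)
        assert diag["min_ess"] > settings.ess0 / settings.refresh_ratio

    def test_ess_decreases_along_parameter_displacement(self):
        ens = _toy_ensemble(1.0, 4000, 21, 0.25, self.SETTINGS)
        esses = []
        for k in (1.0, 1.3, 1.7, 2.2):
            u1, _ = ens.energy_fn(np.array([inv_softplus(k)]))
            esses.append(ReweightingState(u0=ens.u0, u1=u1, beta=1.0).ess)
        assert all(a > b for a, b in zip(esses, esses[1:]))


class TestParameterVector:
    def test_round_trip_lossless(self, ff):
        pv = ParameterVector(ff)
        theta = pv.vector()
        pv.set_vector(theta)
        ff2 = pv.to_forcefield()
        for key in ff.trimers:
            assert ff.trimers[key] == ff2.trimers[key]
        for l in ff.fan:
            # class2 comparison coefficients are not trainable and persist
            assert ff.fan[l] == ff2.fan[l]

    def test_positive_entries_stay_positive(self, ff):
        pv = ParameterVector(ff, trainable=[("fan", "depth", None)])
        theta = pv.vector() - 50.0  # drive raw coordinates very negative
        pv.set_vector(theta)
        ff2 = pv.to_forcefield()
        assert all(rec.depth > 0 for rec in ff2.fan.values())

    def test_duplex_param_gradient_matches_fd(self, ff, duplex8):
        topo, _, perturbed = duplex8
        rng = np.random.default_rng(0)
        configs = perturbed[None] + rng.normal(scale=0.02, size=(20, 16, 3))
        batch = EnsembleBatch.from_configs(configs, topo, es=ff.electrostatics)
        pv = ParameterVector(ff)
        theta = pv.vector()
        coeff = rng.normal(size=20)

        def total(th):
            pv.set_vector(th)
            return float(np.sum(coeff * pv.energies(batch)))

        pv.set_vector(theta)
        grad = pv.param_grad(batch, coeff, theta)
        idx = rng.choice(len(theta), 15, replace=False)
        for k in idx:
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            fd = (total(tp) - total(tm)) / (2 * h)
            assert grad[k] == pytest.approx(fd, rel=2e-5, abs=1e-9)


class TestMarginalForceField:
    def test_equilibria_recovered_from_oracle_ensemble(self, ff):
        """Marginal fitting of a sampled duplex recovers every equilibrium
        close to truth; stiffnesses come out high because neighbouring terms
        narrow each marginal (the bias the contrasting stage removes)."""
        from bfbdna.fit import fit_marginal_forcefield
        from bfbdna.synthetic import make_toy_ensembles
        from bfbdna.topology import build_duplex_topology

        seq = "AAAAAA"
        topo = build_duplex_topology(seq)
        data, _, _ = make_toy_ensembles(ff, ff, seq, n_data=400, n_noise=1,
                                        n_steps=3000, sample_every=100, seed=2)
        mf = fit_marginal_forcefield(data.configs, topo, ff, temperature=300.0)
        rec = mf.trimers["AAA"]
        truth = ff.trimers["AAA"]
        assert rec.bond_i.x0 == pytest.approx(truth.bond_i.x0, rel=0.03)
        assert rec.bond_j.x0 == pytest.approx(truth.bond_j.x0, rel=0.03)
        assert rec.bond_cross.x0 == pytest.approx(truth.bond_cross.x0, rel=0.03)
        assert rec.theta_m == pytest.approx(truth.theta_m, abs=0.05)
        assert rec.k_phi > 0
        for l, fan_rec in mf.fan.items():
            assert fan_rec.r0 == pytest.approx(ff.fan[l].r0, abs=0.06)
        assert rec.bond_i.k2 > truth.bond_i.k2  # marginal narrowing bias
        mf.validate()
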