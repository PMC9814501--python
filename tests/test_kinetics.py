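import math

import numpy as np
import pytest
from scipy.integrate import quad

from chargemig.kinetics import (
    KineticModel,
    KineticModelParams,
    fit_ion_trace,
    model_rise_decay,
    model_step_decay,
    photon_order,
)
from chargemig.synthetic_data import DatasetConfig, simulate_pumpprobe_dataset
from chargemig.tof_extraction import IonTrace


def convolution_oracle(ideal, t, sigma):
    """Brute-force Gaussian convolution by adaptive quadrature."""
    def f(s):
        return ideal(t - s) * math.exp(-0.5 * (s / sigma) ** 2) / (
            sigma * math.sqrt(2 * math.pi))
    lo, hi = -10 * sigma, 10 * sigma
    # break at +-sigma and at the step kink s = t
    pts = sorted({lo, -sigma, sigma, hi} | ({t} if lo < t < hi else set()))
    val = 0.0
    for a, b in zip(pts, pts[1:]):
        val += quad(f, a, b, limit=800, epsabs=1e-14, epsrel=1e-13)[0]
    return val


class TestModelStepDecay:
    def test_unconvolved_limits(self):
        p = KineticModelParams("A", t0=1.0, amplitude=2.0, tau1=5.0, baseline=0.3)
        assert model_step_decay(0.0, p) == pytest.approx(0.3)
        assert model_step_decay(1.0 + 5.0, p) == pytest.approx(0.3 + 2.0 / math.e)

    @pytest.mark.parametrize("sigma,tau,t", [
        (1.7, 24.0, 3.0),
        (1.7, 2.32, 0.5),
        (4.0, 0.5, -2.0),     # sigma >> tau regime
        (0.3, 60.0, 30.0),
    ])
    def test_emg_matches_quadrature(self, sigma, tau, t):
        p = KineticModelParams("A", t0=0.0, amplitude=1.0, tau1=tau,
                               baseline=0.0, sigma_irf=sigma)
        ideal = lambda x: math.exp(-x / tau) if x >= 0 else 0.0
        oracle = convolution_oracle(ideal, t, sigma)
        assert model_step_decay(t, p) == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_numerically_safe_far_from_step(self):
        p = KineticModelParams("A", t0=0.0, amplitude=1.0, tau1=2.0,
                               baseline=0.0, sigma_irf=1.7)
        y = model_step_decay(np.array([-60.0, 200.0]), p)
        assert np.all(np.isfinite(y))
        assert y[0] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            KineticModelParams("A", t0=0, amplitude=1, tau1=-1.0)


class TestModelRiseDecay:
    def test_starts_at_baseline(self):
        p = KineticModelParams("B", t0=2.0, amplitude=1.0, tau1=2.32,
                               tau2=24.0, baseline=0.7)
        assert model_rise_decay(2.0, p) == pytest.approx(0.7)

    def test_unconvolved_peak_location(self):
        # maximum of the double exponential at t0 + tau1 tau2 ln(tau2/tau1)/(tau2-tau1)
        tau1, tau2 = 2.32, 24.0
        p = KineticModelParams("B", t0=0.0, amplitude=1.0, tau1=tau1, tau2=tau2)
        t_peak = tau1 * tau2 * math.log(tau2 / tau1) / (tau2 - tau1)
        assert t_peak == pytest.approx(6.00, abs=5e-3)
        t = np.linspace(0, 30, 30001)
        y = model_rise_decay(t, p)
        assert t[np.argmax(y)] == pytest.approx(t_peak, abs=2e-3)

    @pytest.mark.parametrize("sigma,tau1,tau2", [
        (1.7, 2.32, 24.0), (0.5, 1.0, 3.0), (3.0, 0.8, 40.0),
    ])
    def test_matches_quadrature_on_grid(self, sigma, tau1, tau2):
        p = KineticModelParams("B", t0=0.0, amplitude=1.3, tau1=tau1,
                               tau2=tau2, baseline=0.1, sigma_irf=sigma)
        pref = tau2 / (tau2 - tau1)
        ideal = lambda x: pref * (math.exp(-x / tau2) - math.exp(-x / tau1)) if x >= 0 else 0.0
        for t in np.linspace(-3, 15, 100):
            oracle = 0.1 + 1.3 * convolution_oracle(ideal, t, sigma)
            assert model_rise_decay(t, p) == pytest.approx(oracle, rel=1e-9, abs=1e-10)

    def test_converges_to_step_decay_as_tau1_vanishes(self):
        # pointwise convergence is O(tau1/sigma): the vanished rise
        # branch still carries ~0.23 tau1/sigma of weight near the step
        t = np.linspace(-5, 40, 200)
        pa = KineticModelParams("A", t0=0.0, amplitude=1.0, tau1=24.0, sigma_irf=1.7)
        for tau1, tol in ((1e-4, 3e-5), (1e-6, 1e-6)):
            pb = KineticModelParams("B", t0=0.0, amplitude=1.0, tau1=tau1,
                                    tau2=24.0, sigma_irf=1.7)
            diff = np.max(np.abs(model_rise_decay(t, pb) - model_step_decay(t, pa)))
            assert diff < tol

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            KineticModelParams("B", t0=0, amplitude=1, tau1=5.0, tau2=2.0)


class TestConvolvedModelProperties:
    def test_shift_invariance_and_amplitude_linearity(self):
        t = np.linspace(-10, 40, 301)
        p = KineticModelParams("B", t0=0.0, amplitude=1.0, tau1=2.32,
                               tau2=24.0, sigma_irf=1.7)
        p_shift = KineticModelParams("B", t0=3.5, amplitude=1.0, tau1=2.32,
                                     tau2=24.0, sigma_irf=1.7)
        np.testing.assert_allclose(model_rise_decay(t + 3.5, p_shift),
                                   model_rise_decay(t, p), rtol=1e-12)
        p2 = KineticModelParams("B", t0=0.0, amplitude=2.0, tau1=2.32,
                                tau2=24.0, sigma_irf=1.7)
        np.testing.assert_allclose(model_rise_decay(t, p2),
                                   2 * model_rise_decay(t, p), rtol=1e-12)


class TestFitting:
    def test_noiseless_exact_recovery(self, default_irf):
        ds = simulate_pumpprobe_dataset(DatasetConfig(seed=0, noise_sigma=0.0),
                                        default_irf)
        fit = fit_ion_trace(ds.averaged("67.5"), model="B", irf=default_irf, n_boot=0)
        assert fit["t0"] == pytest.approx(0.0, abs=1e-6)
        assert fit["tau1"] == pytest.approx(2.32, abs=1e-6)
        assert fit["tau2"] == pytest.approx(24.0, abs=1e-5)
        assert fit["amplitude"] == pytest.approx(1.0, abs=1e-6)
        assert fit["baseline"] == pytest.approx(0.0, abs=1e-8)

    def test_bootstrap_intervals_bracket_estimates(self, default_irf):
        ds = simulate_pumpprobe_dataset(DatasetConfig(seed=3), default_irf)
        fit = fit_ion_trace(ds.averaged("67.5"), model="B", irf=default_irf,
                            n_boot=120, seed=7)
        for name in fit.free_names:
            lo, hi = fit.ci68[name]
            assert lo <= getattr(fit.params, name) <= hi
        assert "tau1" in fit.summary()

    def test_bootstrap_deterministic_under_seed(self, default_irf):
        ds = simulate_pumpprobe_dataset(DatasetConfig(seed=3), default_irf)
        tr = ds.averaged("67.5")
        f1 = fit_ion_trace(tr, model="B", irf=default_irf, n_boot=60, seed=11)
        f2 = fit_ion_trace(tr, model="B", irf=default_irf, n_boot=60, seed=11)
        assert f1.ci68 == f2.ci68

    def test_free_irf_width_mode(self, default_irf):
        ds = simulate_pumpprobe_dataset(DatasetConfig(seed=0, noise_sigma=0.0),
                                        default_irf)
        fit = fit_ion_trace(ds.averaged("67.5"), model="B", irf=None, n_boot=0)
        assert fit["sigma_irf"] == pytest.approx(default_irf.sigma, abs=1e-4)

    def test_too_few_points_rejected(self):
        tr = IonTrace("x", 1.0, np.arange(5.0), np.ones(5), np.zeros(5))
        with pytest.raises(ValueError):
            KineticModel.from_trace(tr, model="B")


class TestPhotonOrder:
    def test_exact_power_laws(self):
        I = np.linspace(7e12, 1.4e13, 8)
        for n in (1, 2, 3):
            slope, err, n_hat = photon_order(I, (I / 1e13) ** n)
            assert slope == pytest.approx(n, abs=1e-12)
            assert n_hat == n

    def test_recovers_two_photons_under_noise(self):
        I = np.linspace(7e12, 1.4e13, 8)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = (I / 1e13) ** 2 * (1 + rng.normal(0, 0.05, I.size))
            hits += photon_order(I, y)[2] == 2
        assert hits >= 95

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            photon_order([1e13, 2e13], [1.0, 2.0])
        with pytest.raises(ValueError):
            photon_order([1e13, -2e13, 3e13], [1.0, 2.0, 3.0])
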