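import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")

from chargemig.experiment_model import LaserPulse, irf_from_pulses
from chargemig.molecule import ModelMolecule
from chargemig.synthetic_data import make_adenine_like_molecule

# 8-fold symmetry orbit of real-orbital integrals <pq|rs>
SYM_PERMS = [(0, 1, 2, 3), (2, 1, 0, 3), (0, 3, 2, 1), (2, 3, 0, 1),
             (1, 0, 3, 2), (1, 2, 3, 0), (3, 0, 1, 2), (3, 2, 1, 0)]


def add_sym(tensor, p, q, r, s, g):
    """Add g on the full symmetry orbit of one integral."""
    seen = set()
    for perm in SYM_PERMS:
        t = tuple((p, q, r, s)[k] for k in perm)
        if t not in seen:
            tensor[t] += g
            seen.add(t)


def symmetrize8(w):
    return sum(w.transpose(p) for p in SYM_PERMS) / 8.0


def make_shakeup_toy(n_shallow=4, g=0.05, seed=None, jitter=0.0,
                     hole_ev=-12.0, special_ev=-3.0):
    """Minimal shake-up system: one hole channel, a shallow manifold and
    one special virtual coupled through designed pair channels."""
    rng = np.random.default_rng(seed)
    shallow = -7.5 + 0.3 * np.linspace(-1, 1, n_shallow)
    if jitter:
        shallow = np.sort(shallow + rng.uniform(-jitter, jitter, n_shallow))
    n = n_shallow + 2
    energies = np.concatenate([[hole_ev], shallow, [special_ev]])
    w = np.zeros((n, n, n, n))
    for i in range(1, 1 + n_shallow):
        for j in range(i + 1, 1 + n_shallow):
            add_sym(w, n - 1, 0, i, j, g)
    weights = np.zeros(1 + n_shallow)
    weights[0] = 1.0
    return ModelMolecule(energies, 1 + n_shallow, w, np.zeros((n, n, 3)),
                         0, n - 1, weights)


def make_hubbard_dimer(U=0.5, J=2.0):
    """Hubbard dimer in its molecular-orbital basis (levels at -3 -+ J)."""
    n = 2
    w = np.zeros((n, n, n, n))
    idx = np.indices((n, n, n, n)).sum(axis=0)
    w[idx % 2 == 0] = U / 2
    return ModelMolecule(np.array([-3.0 - J, -3.0 + J]), 1, w,
                         np.zeros((n, n, 3)), 0, 1, np.array([1.0]))


@pytest.fixture(scope="session")
def default_molecule():
    """The packaged calibrated adenine-like molecule (seed 0)."""
    return make_adenine_like_molecule(seed=0)


@pytest.fixture(scope="session")
def default_irf():
    """IRF of the reported pulse durations (0.3 fs pump, 4 fs probe)."""
    return irf_from_pulses(0.3, 4.0)


@pytest.fixture(scope="session")
def nir_pulse():
    return LaserPulse(central_photon_energy=1.77, fwhm_duration=4.0,
                      peak_intensity=1e13)


@pytest.fixture(scope="session")
def xuv_pulse():
    return LaserPulse(central_photon_energy=25.0, fwhm_duration=0.3,
                      peak_intensity=1e12)


@pytest.fixture(scope="session")
def depletion_curve(default_molecule, xuv_pulse, nir_pulse):
    """The packaged GKBA depletion scan: delays -3..8 fs, 0.5 fs step.

    Session-scoped because it is the most expensive computation in the
    suite; several tests and the acceptance check read from it.
    """
    import warnings

    from chargemig.dynamics import depletion_vs_delay

    delays = np.arange(-3.0, 8.0 + 0.25, 0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return depletion_vs_delay(default_molecule, xuv_pulse, nir_pulse,
                                  delays, method="gkba")


@pytest.fixture(scope="session")
def dication_fit_ensemble(default_irf):
    """50-seed synthetic dication fits with shared fragment-step t0."""
    from chargemig.kinetics import fit_ion_trace
    from chargemig.synthetic_data import DatasetConfig, simulate_pumpprobe_dataset

    tau1, tau2 = [], []
    for seed in range(50):
        ds = simulate_pumpprobe_dataset(DatasetConfig(seed=seed), default_irf)
        frag = fit_ion_trace(ds.averaged("27"), model="A", irf=default_irf, n_boot=0)
        fit = fit_ion_trace(ds.averaged("67.5"), model="B", irf=default_irf,
                            fix_t0=frag["t0"], n_boot=0)
        tau1.append(fit["tau1"])
        tau2.append(fit["tau2"])
    return np.asarray(tau1), np.asarray(tau2)
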