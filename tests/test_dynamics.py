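import warnings

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import curve_fit

from chargemig._units import fs_to_au
from chargemig.experiment_model import LaserPulse, field_at
from chargemig.molecule import ModelMolecule
from chargemig.shakeup_fgr import characteristic_times
from chargemig.dynamics import (
    DressedSystem,
    PropagationGrid,
    StabilityError,
    depletion_vs_delay,
    dress_with_continuum,
    initial_state_sudden_hole,
    propagate_exact_ci,
    propagate_gkba_2b,
    propagate_meanfield,
    sudden_hole_determinant,
)
from conftest import make_hubbard_dimer, make_shakeup_toy


@pytest.fixture(scope="module")
def toy():
    return make_shakeup_toy(n_shallow=4, g=0.05)


class TestInitialState:
    def test_sudden_hole_properties(self, toy):
        sysd = DressedSystem.from_molecule(toy)
        rho = initial_state_sudden_hole(sysd, toy.hole_index)
        assert np.trace(rho).real == pytest.approx(toy.n_electrons - 1)
        assert np.max(np.abs(rho @ rho - rho)) < 1e-12
        occ = sudden_hole_determinant(toy, toy.hole_index)
        assert len(occ) == toy.n_electrons - 1
        assert toy.hole_index not in occ

    def test_hole_must_be_occupied(self, toy):
        with pytest.raises(ValueError):
            initial_state_sudden_hole(toy, toy.n_so - 1)


class TestMeanField:
    def test_ground_state_is_stationary(self, toy):
        sysd = DressedSystem.from_molecule(toy)
        grid = PropagationGrid(0, 10.0, dt=0.05)
        traj = propagate_meanfield(sysd, [], grid, sysd.rho_neutral.copy(),
                                   store_stride=20)
        assert np.max(np.abs(traj.rho - traj.rho[0])) < 1e-9
        assert np.max(np.abs(np.diff(traj.particle_number))) < 1e-9

    def test_matches_one_body_matrix_exponential_oracle(self):
        """With the interaction off, mean field is exactly one-body; a
        time-ordered matrix-exponential product is the oracle."""
        mol = make_shakeup_toy().with_coupling_scale(0.0)
        rng = np.random.default_rng(3)
        d = rng.normal(0, 0.3, (mol.n_spatial, mol.n_spatial, 3))
        mol = ModelMolecule(mol.energies_spatial, mol.n_occ_spatial,
                            mol.two_electron_spatial, 0.5 * (d + d.transpose(1, 0, 2)),
                            mol.hole_spatial, mol.special_spatial,
                            mol.hole_weights_spatial, coupling_scale=0.0)
        pulse = LaserPulse(1.77, 2.0, 5e12, center_time=1.0)
        sysd = DressedSystem.from_molecule(mol)
        grid = PropagationGrid(0, 3.0, dt=0.0006)
        rho0 = initial_state_sudden_hole(sysd, mol.hole_index)
        traj = propagate_meanfield(sysd, [pulse], grid, rho0, store_stride=10**6)

        # oracle on a 4x finer grid
        dt = grid.dt / 4
        U = np.eye(sysd.n_so, dtype=complex)
        t = 0.0
        pol = np.asarray(pulse.polarization)
        dip = np.einsum("pqx,x->pq", sysd.dip_au, pol)
        while t < 3.0 - 1e-9:
            h = sysd.h0_au + float(field_at(pulse, t + dt / 2)) * dip
            U = expm(-1j * h * fs_to_au(dt)) @ U
            t += dt
        rho_oracle = U @ rho0 @ U.conj().T
        assert np.max(np.abs(traj.rho[-1] - rho_oracle)) < 1e-8

    def test_rabi_period(self):
        """Two-level molecule, resonant weak drive: population cycles
        with period 2 pi / (d E0)."""
        n = 2
        w = np.zeros((n, n, n, n))
        d = np.zeros((n, n, 3))
        d[0, 1, 2] = d[1, 0, 2] = 1.0
        gap = 1.77
        mol = ModelMolecule(np.array([-3.0 - gap / 2, -3.0 + gap / 2]), 1, w, d,
                            0, 1, np.array([1.0]))
        sysd = DressedSystem.from_molecule(mol)
        E0 = 0.005  # a.u.; weak enough that the rotating-wave period holds
        from chargemig._units import AU_INTENSITY_W_CM2

        pulse = LaserPulse(gap, 400.0, E0**2 * AU_INTENSITY_W_CM2,
                           envelope="gaussian", center_time=0.0)
        period = 2 * np.pi / (E0) * 0.02418884  # fs
        grid = PropagationGrid(0, 1.2 * period, dt=period / 2000)
        traj = propagate_meanfield(sysd, [pulse], grid, sysd.rho_neutral.copy(),
                                   store_stride=10)
        n_exc = traj.occupation_of_spatial(1)
        # first return to (near) zero excited population
        k = np.argmin(n_exc[len(n_exc) // 4:]) + len(n_exc) // 4
        assert traj.times[k] == pytest.approx(period, rel=0.01)

class TestGkba:
    def test_reduces_to_meanfield_without_interaction(self, toy):
        mol = toy.with_coupling_scale(0.0)
        sysd = DressedSystem.from_molecule(mol)
        grid = PropagationGrid(0, 2.0, dt=0.02)
        rho0 = initial_state_sudden_hole(sysd, mol.hole_index)
        g = propagate_gkba_2b(sysd, [], grid, rho0)
        m = propagate_meanfield(sysd, [], grid, rho0)
        assert np.max(np.abs(g.rho - m.rho)) < 1e-10

    def test_hubbard_dimer_quench_matches_exact_ci(self):
        """Interaction quench from the noninteracting ground state at
        half filling; the excited-orbital occupation is the
        double-occupancy-sensitive observable."""
        mol = make_hubbard_dimer(U=0.5, J=2.0)
        sysd = DressedSystem.from_molecule(mol)
        grid = PropagationGrid(0, 5.0, dt=0.01)
        gk = propagate_gkba_2b(sysd, [], grid, sysd.rho_neutral.copy(),
                               store_stride=10)
        ex = propagate_exact_ci(mol, [], grid, occupied=[0, 1], store_stride=10)
        ng = gk.occupation_of_spatial(1)
        ne = ex.occupation_of_spatial(1)
        m = min(ng.size, ne.size)
        assert ng[:m].max() == pytest.approx(ne[:m].max(), rel=0.05)
        assert np.max(np.abs(ng[:m] - ne[:m])) < 0.10 * ne[:m].max()

    def test_shakeup_toy_matches_exact_ci_through_rise(self, toy):
        sysd = DressedSystem.from_molecule(toy)
        grid = PropagationGrid(0, 4.0, dt=0.02)
        rho0 = initial_state_sudden_hole(sysd, toy.hole_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gk = propagate_gkba_2b(sysd, [], grid, rho0, store_stride=20)
        ex = propagate_exact_ci(toy, [], grid,
                                occupied=sudden_hole_determinant(toy, toy.hole_index),
                                store_stride=20)
        sp = toy.special_spatial
        ng, ne = gk.occupation_of_spatial(sp), ex.occupation_of_spatial(sp)
        assert np.max(np.abs(ng - ne)) < 0.10

    def test_conservation_and_hermiticity(self, toy):
        sysd = DressedSystem.from_molecule(toy)
        grid = PropagationGrid(0, 5.0, dt=0.02)
        rho0 = initial_state_sudden_hole(sysd, toy.hole_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = propagate_gkba_2b(sysd, [], grid, rho0, store_stride=10)
        assert abs(traj.particle_number[-1] - traj.particle_number[0]) < 1e-6
        assert traj.hermiticity_defect() < 1e-9

    def test_dt_convergence_is_second_order(self, toy):
        """Halving the step shrinks the discretisation error about
        fourfold (second-order stepping) and changes the occupations at
        the packaged default step by well under 1e-4."""
        sysd = DressedSystem.from_molecule(toy)
        rho0 = initial_state_sudden_hole(sysd, toy.hole_index)
        dt0 = 0.8 * 0.02418884
        t_end = 100 * dt0  # commensurate with every step size used
        vals = []
        for dt in (dt0, dt0 / 2, dt0 / 4):
            grid = PropagationGrid(0, t_end, dt=dt)
            traj = propagate_gkba_2b(sysd, [], grid, rho0, store_stride=10**6)
            vals.append(traj.occupation_of_spatial(toy.special_spatial)[-1])
        d1, d2 = abs(vals[1] - vals[0]), abs(vals[2] - vals[1])
        assert d1 < 1e-4
        assert 2.5 < d1 / d2 < 6.0

    def test_calibrated_molecule_rise_follows_golden_rule(self, default_molecule):
        """Sudden hole in the designated inner-valence orbital: the
        special state's occupation rises monotonically through the first
        2.5 fs and its exponential-rise timescale agrees with the
        tabulated golden-rule time within a factor of two."""
        sysd = DressedSystem.from_molecule(default_molecule)
        grid = PropagationGrid(0, 8.0)
        rho0 = initial_state_sudden_hole(sysd, default_molecule.hole_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = propagate_gkba_2b(sysd, [], grid, rho0, store_stride=10)
        nsp = traj.occupation_of_spatial(default_molecule.special_spatial)
        early = nsp[traj.times <= 2.5]
        assert np.all(np.diff(early) > -1e-6)

        f = lambda t, A, tau: A * (1 - np.exp(-t / tau))
        (A, tau_fit), _ = curve_fit(f, traj.times, nsp, p0=[1.0, 2.0],
                                    bounds=([0.3, 0.1], [1.4, 20.0]), maxfev=10000)
        tau_table = characteristic_times(default_molecule).special_tau
        assert tau_table / 2 <= tau_fit <= tau_table * 2


class TestExactCI:
    def test_norm_and_energy_conservation(self, toy):
        grid = PropagationGrid(0, 3.0, dt=0.02)
        traj = propagate_exact_ci(toy, [], grid,
                                  occupied=sudden_hole_determinant(toy, toy.hole_index),
                                  store_stride=30)
        n = traj.particle_number
        assert np.max(np.abs(n - n[0])) < 1e-9

    def test_stationary_without_interaction(self):
        mol = make_shakeup_toy().with_coupling_scale(0.0)
        grid = PropagationGrid(0, 2.0, dt=0.05)
        traj = propagate_exact_ci(mol, [], grid,
                                  occupied=sudden_hole_determinant(mol, mol.hole_index))
        occ = traj.occupations
        assert np.max(np.abs(occ - occ[0])) < 1e-10

    def test_capacity_limit(self):
        from chargemig.ci import CapacityError, DeterminantSpace

        with pytest.raises(CapacityError):
            DeterminantSpace(20, 10)


class TestDressing:
    def test_continuum_absorbs_monotonically(self, default_molecule, nir_pulse):
        sysd = dress_with_continuum(default_molecule)
        pulse = LaserPulse(1.77, 4.0, 1e13, center_time=2.0)
        grid = PropagationGrid(0, 6.0)
        rho0 = initial_state_sudden_hole(sysd, default_molecule.hole_index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = propagate_gkba_2b(sysd, [pulse], grid, rho0, store_stride=20)
        n = traj.particle_number
        assert np.all(np.diff(n) < 1e-9)          # nonincreasing
        assert n[-1] < n[0] - 1e-4                # something actually left

    def test_unbound_bridge_rejected(self, default_molecule):
        with pytest.raises(ValueError):
            dress_with_continuum(default_molecule, photon_energy_ev=4.0)


class TestDepletion:
    def test_zero_intensity_gives_zero(self, default_molecule, xuv_pulse):
        nir_off = LaserPulse(1.77, 4.0, 0.0)
        curve = depletion_vs_delay(default_molecule, xuv_pulse, nir_off,
                                   [0.0, 2.0], method="meanfield")
        assert np.all(curve.depletion == 0.0)

    def test_far_negative_delay_vanishes(self, depletion_curve):
        early = depletion_curve.depletion[depletion_curve.delays <= -2.5]
        assert np.all(np.abs(early) < 1e-3)

    def test_nondecreasing_through_window(self, depletion_curve):
        """The depletion grows with pump-probe delay across 0-8 fs (a
        small numerical tolerance absorbs late-time model noise)."""
        mask = depletion_curve.delays >= 0.0
        d = depletion_curve.depletion[mask]
        assert np.all(np.diff(d) > -0.02 * d.max())

    def test_onset_lies_in_reported_window(self, depletion_curve):
        half = depletion_curve.half_onset_delay(8.0)
        assert 2.0 <= half <= 4.0
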