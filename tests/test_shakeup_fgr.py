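import numpy as np
import pytest

from chargemig.molecule import ModelMolecule
from chargemig.shakeup_fgr import (
    FgrOptions,
    characteristic_times,
    photon_group,
    shakeup_rate,
    slater_condon_element,
)
from chargemig.synthetic_data import (
    CalibrationError,
    calibrate_molecule,
    make_adenine_like_molecule,
)
from conftest import make_shakeup_toy, symmetrize8

# ---------------------------------------------------------------------------
# independent second-quantised oracle (bitstring operator algebra)
# ---------------------------------------------------------------------------


def _annihilate(state, p):
    mask, amp = state
    if not mask >> p & 1:
        return None
    sgn = -1 if bin(mask & ((1 << p) - 1)).count("1") % 2 else 1
    return (mask ^ (1 << p), amp * sgn)


def _create(state, p):
    mask, amp = state
    if mask >> p & 1:
        return None
    sgn = -1 if bin(mask & ((1 << p) - 1)).count("1") % 2 else 1
    return (mask | (1 << p), amp * sgn)


def second_quantized_element(v, bra_occ, ket_occ):
    """<bra| 1/2 sum v_pqrs c_p+ c_q+ c_s c_r |ket> by brute force."""
    n = v.shape[0]
    bra = 0
    for p in bra_occ:
        bra |= 1 << p
    ket = 0
    for p in ket_occ:
        ket |= 1 << p
    total = 0.0
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    if v[p, q, r, s] == 0.0:
                        continue
                    st = (ket, 1.0)
                    for op, idx in (( _annihilate, r), (_annihilate, s),
                                    (_create, q), (_create, p)):
                        st = op(st, idx)
                        if st is None:
                            break
                    if st is not None and st[0] == bra:
                        total += 0.5 * v[p, q, r, s] * st[1]
    return total


def _random_molecule(seed):
    rng = np.random.default_rng(seed)
    n = 4
    w = symmetrize8(rng.normal(0, 0.4, (n, n, n, n)))
    return ModelMolecule(np.array([-12.0, -9.0, -7.0, -3.0]), 3, w,
                         np.zeros((n, n, 3)), 0, 3, np.array([1.0, 0, 0]))


class TestSlaterCondon:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_second_quantized_oracle(self, seed):
        mol = _random_molecule(seed)
        v = mol.two_electron_so * mol.coupling_scale
        occ = list(mol.occupied_so)
        # hole h (alpha of spatial 0); final holes i, j and particle a
        h, a = 0, mol.n_so - 2
        for (i, j) in ((2, 3), (2, 5), (3, 4)):
            ket = [p for p in occ if p != h]
            bra = sorted([p for p in occ if p not in (h, i, j)] + [a])
            oracle = second_quantized_element(v, bra, ket)
            ours = slater_condon_element(mol, h, i, j, a)
            # overall phases of the two determinant orderings may differ
            assert abs(ours) == pytest.approx(abs(oracle), abs=1e-12)

    def test_zero_interaction_and_antisymmetry(self):
        mol = _random_molecule(0).with_coupling_scale(0.0)
        assert slater_condon_element(mol, 0, 2, 3, 6) == 0.0
        mol = _random_molecule(0)
        assert slater_condon_element(mol, 0, 2, 2, 6) == 0.0

    def test_block_validation(self):
        mol = _random_molecule(0)
        with pytest.raises(ValueError):
            slater_condon_element(mol, 7, 2, 3, 6)   # h not occupied
        with pytest.raises(ValueError):
            slater_condon_element(mol, 0, 2, 3, 1)   # a not virtual


class TestShakeupRate:
    def test_zero_coupling_gives_zero_rate_and_infinite_time(self):
        mol = make_shakeup_toy().with_coupling_scale(0.0)
        assert shakeup_rate(mol, 0, 2 * (mol.n_spatial - 1)) == 0.0
        table = characteristic_times(mol)
        assert np.isinf(table.special_tau)

    def test_rate_scales_with_coupling_squared(self):
        mol = make_shakeup_toy()
        a = 2 * (mol.n_spatial - 1)
        g1 = shakeup_rate(mol, 0, a)
        g2 = shakeup_rate(mol.with_coupling_scale(2.0), a=a, h=0)
        assert g2 == pytest.approx(4.0 * g1, rel=1e-12)
        t1 = characteristic_times(mol).special_tau
        t2 = characteristic_times(mol.with_coupling_scale(2.0)).special_tau
        assert t2 == pytest.approx(t1 / 4.0, rel=1e-9)

    def test_pair_restriction_conventions_agree(self):
        mol = _random_molecule(1)
        a = mol.n_so - 2
        g_pairs = shakeup_rate(mol, 0, a, FgrOptions(pair_restriction="distinct_pairs"))
        g_ordered = shakeup_rate(mol, 0, a, FgrOptions(pair_restriction="all_ordered"))
        assert g_pairs == pytest.approx(g_ordered, rel=1e-12)

    def test_invalid_broadening(self):
        with pytest.raises(ValueError):
            FgrOptions(broadening_eta=0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_rate_matches_exact_propagation_slope(self, seed):
        """Golden-rule rate vs the population-growth slope of exact CI,
        in the quasi-exponential window after coherence build-up."""
        from chargemig.dynamics import (PropagationGrid, propagate_exact_ci,
                                        sudden_hole_determinant)

        mol = make_shakeup_toy(n_shallow=5, g=0.04, seed=seed, jitter=0.08)
        a0 = 2 * (mol.n_spatial - 1)
        gamma = shakeup_rate(mol, 0, a0) + shakeup_rate(mol, 0, a0 + 1)
        grid = PropagationGrid(0, 3.0, dt=0.02)
        traj = propagate_exact_ci(mol, [], grid,
                                  occupied=sudden_hole_determinant(mol, 0),
                                  store_stride=5)
        na = traj.occupation_of_spatial(mol.n_spatial - 1)
        t = traj.times
        m = (t >= 1.0) & (t <= 3.0)
        slope = np.polyfit(t[m], -np.log(1 - na[m]), 1)[0]
        assert slope == pytest.approx(gamma, rel=0.20)


class TestCharacteristicTimes:
    def test_single_hole_channel_identity(self):
        mol = make_shakeup_toy()
        a0 = 2 * (mol.n_spatial - 1)
        table = characteristic_times(mol)
        gamma_direct = sum(
            0.5 * (shakeup_rate(mol, h, a) )
            for h in (0, 1) for a in (a0, a0 + 1)
        )
        assert table.gamma_per_fs[table.special_row] == pytest.approx(
            gamma_direct, rel=1e-12)
        assert table.special_tau == pytest.approx(1.0 / gamma_direct, rel=1e-12)

    def test_rate_invariant_under_degenerate_relabeling(self):
        """Swapping two exactly degenerate shallow orbitals leaves the
        statistically summed rate unchanged."""
        mol = make_shakeup_toy(n_shallow=4, jitter=0.0)
        e = mol.energies_spatial.copy()
        e[2] = e[3] = 0.5 * (e[2] + e[3])        # force exact degeneracy
        mol = ModelMolecule(e, mol.n_occ_spatial, mol.two_electron_spatial,
                            mol.dipoles_spatial, 0, mol.special_spatial,
                            mol.hole_weights_spatial)
        perm = list(range(mol.n_spatial))
        perm[2], perm[3] = perm[3], perm[2]
        w2 = mol.two_electron_spatial[np.ix_(perm, perm, perm, perm)]
        mol2 = ModelMolecule(e, mol.n_occ_spatial, w2, mol.dipoles_spatial,
                             0, mol.special_spatial, mol.hole_weights_spatial)
        t1 = characteristic_times(mol).special_tau
        t2 = characteristic_times(mol2).special_tau
        assert t2 == pytest.approx(t1, rel=1e-9)

    def test_weights_must_normalise(self):
        mol = make_shakeup_toy()
        with pytest.raises(ValueError):
            ModelMolecule(mol.energies_spatial, mol.n_occ_spatial,
                          mol.two_electron_spatial, mol.dipoles_spatial,
                          0, mol.special_spatial,
                          np.full(mol.n_occ_spatial, 0.3))


class TestCalibratedMolecule:
    def test_special_time_hits_target(self, default_molecule):
        table = characteristic_times(default_molecule)
        assert table.special_tau == pytest.approx(2.5, abs=1e-3)

    def test_special_state_in_two_photon_group(self, default_molecule):
        table = characteristic_times(default_molecule)
        assert table.photon_group[table.special_row] == 2

    def test_non_special_virtuals_are_sub_femtosecond(self, default_molecule):
        table = characteristic_times(default_molecule)
        other = table.tau_fs[table.virtual_spatial != table.special_spatial]
        assert np.all(other < 1.0)

    def test_calibration_idempotent(self, default_molecule):
        recal = calibrate_molecule(default_molecule, 2.5)
        assert recal.coupling_scale == pytest.approx(
            default_molecule.coupling_scale, rel=1e-6)

    def test_calibration_fails_for_dead_channel(self):
        mol = make_shakeup_toy().with_coupling_scale(0.0)
        with pytest.raises(CalibrationError):
            calibrate_molecule(mol, 2.5)

    @pytest.mark.parametrize("eta", [0.1, 0.2, 0.3, 0.4])
    def test_calibration_robust_across_broadening(self, eta):
        """Recalibrating under a different Lorentzian width still lands
        on the target time, with a modest coupling-scale adjustment."""
        opts = FgrOptions(broadening_eta=eta)
        mol = make_adenine_like_molecule(seed=0, fgr_options=opts)
        tau = characteristic_times(mol, opts).special_tau
        assert tau == pytest.approx(2.5, abs=1e-3)
        ref = make_adenine_like_molecule(seed=0)
        assert mol.coupling_scale == pytest.approx(ref.coupling_scale, rel=0.35)


class TestPhotonGroup:
    @pytest.mark.parametrize("be,expected", [
        (1.0, 1), (3.0, 2), (1.77, 1), (3.54, 2), (3.55, 3), (5.0, 3),
    ])
    def test_grouping(self, be, expected):
        assert photon_group(be) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            photon_group(-1.0)
        with pytest.raises(ValueError):
            photon_group(1.0, 0.0)
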