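"""Time-dependent many-body electron dynamics on model molecules.

Three propagators share one model Hamiltonian:

* **mean field** (time-dependent Hartree-Fock) — the correlation-free
  baseline;
* **GKBA second Born** — the density matrix acquires a non-Markovian
  collision integral built from the two second-order Coulomb diagrams,
  with lesser/greater Green's functions reconstructed from the
  time-diagonal density matrix via the Generalised Kadanoff-Baym Ansatz
  with mean-field propagators (the HF-GKBA). This is the level of theory
  that captures shake-up: a sudden inner-valence hole decays by promoting
  a second electron into the bound virtuals, populating the special state
  on its few-femtosecond characteristic time;
* **exact CI** — full configuration interaction in the determinant basis
  (capacity-limited), the validation oracle.

The model Hamiltonian is fixed by a molecule's orbital energies
``eps``, its (coupling-scaled) two-electron integrals and its dipoles:
``H = sum h0 c+c + 1/4 sum <pq||rs> c+p c+q c_s c_r + E(t).d`` with
``h0 = diag(eps) - V_HF[rho_neutral]`` so that the neutral closed-shell
ground state is a mean-field stationary state with orbital energies
``eps`` (Koopmans consistency with the golden-rule module).

Probe ionisation is modelled by a small absorbing quasi-continuum: a
bridge level one NIR photon above the special state and a ladder of
equally spaced levels at the ionisation threshold, each carrying a
negative imaginary diagonal width so the photo-electron leaves
irreversibly. All member arrays are in atomic units; public interfaces
take fs/eV.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from ._units import EV_PER_HARTREE, FS_PER_AUT, ev_to_au, fs_to_au, au_to_fs
from .ci import DeterminantSpace, CapacityError
from .experiment_model import LaserPulse, field_at
from .molecule import ModelMolecule

__all__ = [
    "PropagationGrid",
    "DensityMatrixTrajectory",
    "DepletionCurve",
    "DressedSystem",
    "dress_with_continuum",
    "initial_state_sudden_hole",
    "propagate_meanfield",
    "propagate_gkba_2b",
    "propagate_exact_ci",
    "depletion_vs_delay",
    "StabilityError",
    "PropagationError",
]


class StabilityError(RuntimeError):
    pass


class PropagationError(RuntimeError):
    pass


@dataclass
class PropagationGrid:
    """Uniform time grid (fs) with a collision-integral history cutoff."""

    t_start: float
    t_end: float
    dt: float = 0.8 * FS_PER_AUT
    memory_cutoff: float = 2.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.memory_cutoff < self.dt:
            raise ValueError("memory_cutoff must be >= dt")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.dt))
        return self.t_start + self.dt * np.arange(n + 1)


@dataclass
class DensityMatrixTrajectory:
    """Stored one-body density matrix along a propagation."""

    times: np.ndarray          # fs
    rho: np.ndarray            # (nt, N, N) complex
    n_occ_labels: dict = field(default_factory=dict)

    @property
    def occupations(self) -> np.ndarray:
        """Real orbital occupations n_k(t), shape (nt, N)."""
        return np.real(np.einsum("tkk->tk", self.rho))

    @property
    def particle_number(self) -> np.ndarray:
        return self.occupations.sum(axis=1)

    def occupation_of_spatial(self, sp: int) -> np.ndarray:
        """Occupation of a spatial orbital (both spins summed)."""
        occ = self.occupations
        return occ[:, 2 * sp] + occ[:, 2 * sp + 1]

    def hermiticity_defect(self) -> float:
        return float(np.max(np.abs(self.rho - np.conj(np.swapaxes(self.rho, 1, 2)))))

    def to_hdf5(self, path):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("rho", data=self.rho)
            f.create_dataset("occupations", data=self.occupations)

    @classmethod
    def from_hdf5(cls, path) -> "DensityMatrixTrajectory":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(times=f["times"][...], rho=f["rho"][...])


@dataclass
class DepletionCurve:
    """NIR-induced depletion of the special state vs pump-probe delay."""

    delays: np.ndarray
    depletion: np.ndarray
    window: float
    raw: np.ndarray | None = None   # before birth-time averaging

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")

    def half_onset_delay(self, reference_delay: float | None = None) -> float:
        """Earliest delay at which the depletion first exceeds half of
        its value at ``reference_delay`` (default: the last delay)."""
        ref = self.depletion[-1] if reference_delay is None else float(
            np.interp(reference_delay, self.delays, self.depletion)
        )
        above = np.nonzero(self.depletion >= 0.5 * ref)[0]
        if above.size == 0:
            return float("nan")
        return float(self.delays[above[0]])

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"delay_fs": self.delays, "depletion": self.depletion}).to_csv(
            path, index=False
        )


# ======================================================================
# dressed system: molecule + absorbing quasi-continuum
# ======================================================================

class DressedSystem:
    """A model molecule embedded with optional bridge/continuum levels.

    Holds every array the propagators need, in atomic units: one-body
    ``h0``, antisymmetrized two-electron integrals on the *correlated*
    (molecular) block, dipole matrices, and the absorbing widths of the
    continuum levels.
    """

    def __init__(self, mol: ModelMolecule, extra_energies_ev=(), extra_gamma_ev=(),
                 extra_dipoles=None):
        self.mol = mol
        self.extra_energies_ev = np.asarray(extra_energies_ev, dtype=float)
        self.extra_gamma_ev = np.asarray(extra_gamma_ev, dtype=float)
        n_extra_sp = self.extra_energies_ev.size
        if self.extra_gamma_ev.size != n_extra_sp:
            raise ValueError("extra level widths must match extra energies")
        self.n_mol_sp = mol.n_spatial
        self.n_sp = self.n_mol_sp + n_extra_sp
        self.n_so = 2 * self.n_sp

        eps_sp = np.concatenate([mol.energies_spatial, self.extra_energies_ev])
        self.eps_au = np.repeat(ev_to_au(eps_sp), 2)
        gam_sp = np.concatenate([np.zeros(self.n_mol_sp), self.extra_gamma_ev])
        self.gamma_au = np.repeat(ev_to_au(gam_sp), 2)

        # dipoles: molecular block plus user-supplied couplings to extras
        d_sp = np.zeros((self.n_sp, self.n_sp, 3))
        d_sp[: self.n_mol_sp, : self.n_mol_sp] = mol.dipoles_spatial
        if extra_dipoles:
            for (p, q, vec) in extra_dipoles:
                d_sp[p, q] = vec
                d_sp[q, p] = vec
        sz = np.arange(self.n_so) % 2
        spi = np.arange(self.n_so) // 2
        dsz = (sz[:, None] == sz[None, :]).astype(float)
        self.dip_au = d_sp[np.ix_(spi, spi)] * dsz[..., None]

        # correlated block: the molecule's active spatial orbitals (all
        # molecular orbitals unless an active space is declared), in the
        # full spin-interleaved ordering
        active = mol.active_spatial if mol.active_spatial is not None \
            else list(range(self.n_mol_sp))
        act_so = [2 * sp + s for sp in active for s in (0, 1)]
        self.corr = np.array(act_so, dtype=int)
        u_full = mol.coupling_scale * mol.antisymmetrized_so
        self.u_corr_au = ev_to_au(u_full[np.ix_(act_so, act_so, act_so, act_so)])

        # neutral closed-shell reference and Koopmans-consistent h0
        occ_so = [2 * sp + s for sp in range(mol.n_occ_spatial) for s in (0, 1)]
        self.occupied_so = np.array(occ_so, dtype=int)
        rho0 = np.zeros((self.n_so, self.n_so), dtype=complex)
        rho0[occ_so, occ_so] = 1.0
        self.rho_neutral = rho0
        self.h0_au = np.diag(self.eps_au.astype(complex)) - self.mean_field(rho0)

    @classmethod
    def from_molecule(cls, mol: ModelMolecule) -> "DressedSystem":
        return cls(mol)

    # ------------------------------------------------------------------

    def mean_field(self, rho: np.ndarray) -> np.ndarray:
        """Hartree + exchange potential of a full-space density matrix."""
        c = self.corr
        rho_c = rho[np.ix_(c, c)]
        v = np.einsum("prqs,sr->pq", self.u_corr_au, rho_c, optimize=True)
        out = np.zeros((self.n_so, self.n_so), dtype=complex)
        out[np.ix_(c, c)] = v
        return out

    def h_hf(self, rho: np.ndarray, t_fs: float, pulses) -> np.ndarray:
        """Time-dependent mean-field Hamiltonian (a.u., incl. absorption)."""
        h = self.h0_au + self.mean_field(rho)
        for p in pulses:
            e = float(field_at(p, t_fs))
            if e != 0.0:
                h = h + e * np.einsum("pqx,x->pq", self.dip_au, np.asarray(p.polarization))
        if np.any(self.gamma_au):
            h = h - 0.5j * np.diag(self.gamma_au)
        return h

    @property
    def special_spatial(self) -> int:
        return self.mol.special_spatial

    def special_occupation(self, rho: np.ndarray) -> float:
        sp = self.special_spatial
        return float(np.real(rho[2 * sp, 2 * sp] + rho[2 * sp + 1, 2 * sp + 1]))


def dress_with_continuum(
    mol: ModelMolecule,
    n_continuum: int = 6,
    spacing_ev: float = 0.25,
    gamma_ev: float = 0.5,
    bridge: bool = True,
    bridge_dipole_au: float = 1.0,
    continuum_dipole_au: float = 1.0,
    photon_energy_ev: float = 1.77,
) -> DressedSystem:
    """Attach the NIR-ionisation surrogate to a molecule.

    A bridge level sits one probe photon above the special state (so the
    special electron needs two NIR photons to reach the continuum, as
    observed); ``n_continuum`` equally spaced absorbing levels start at
    the ionisation threshold (energy 0). The bridge couples to the
    special state and to every continuum level by z-polarised dipoles.
    The extra levels carry no Coulomb integrals: they are a one-body
    escape channel, not part of the correlated space.
    """
    extras, gammas, dips = [], [], []
    sp_off = mol.n_spatial
    e_special = mol.energies_spatial[mol.special_spatial]
    if bridge:
        e_bridge = e_special + photon_energy_ev
        if e_bridge >= 0:
            raise ValueError("bridge level would be unbound; lower the photon energy")
        extras.append(e_bridge)
        gammas.append(0.0)
        bridge_idx = sp_off + len(extras) - 1
        dips.append((mol.special_spatial, bridge_idx, (0.0, 0.0, bridge_dipole_au)))
    for k in range(n_continuum):
        extras.append(k * spacing_ev)
        gammas.append(gamma_ev)
        c_idx = sp_off + len(extras) - 1
        src = bridge_idx if bridge else mol.special_spatial
        dips.append((src, c_idx, (0.0, 0.0, continuum_dipole_au)))
    # continuum levels are "bound" bookkeeping-wise at epsilon >= 0; the
    # DressedSystem does not re-validate molecule invariants for extras.
    return DressedSystem(mol, extras, gammas, dips)


# ======================================================================
# initial states
# ======================================================================

def initial_state_sudden_hole(system, h: int) -> np.ndarray:
    """Density matrix right after sudden removal of the electron in spin
    orbital ``h`` from the neutral closed-shell ground state: idempotent,
    diagonal, trace ``N_electrons - 1``."""
    if isinstance(system, ModelMolecule):
        system = DressedSystem.from_molecule(system)
    if h not in system.occupied_so:
        raise ValueError(f"spin orbital {h} is not occupied in the reference")
    rho = system.rho_neutral.copy()
    rho[h, h] = 0.0
    return rho


def sudden_hole_determinant(mol: ModelMolecule, h: int) -> list:
    """Occupied spin-orbital list of the sudden-hole determinant (for
    the exact-CI oracle)."""
    occ = [p for p in mol.occupied_so if p != h]
    if len(occ) == len(mol.occupied_so):
        raise ValueError(f"spin orbital {h} is not occupied")
    return occ


# ======================================================================
# the propagator
# ======================================================================

class _Propagator:
    """Exponential predictor-corrector stepping of the one-body density
    matrix, optionally coupled to the two-particle correlation tensor.

    The correlated mode is HF-GKBA at the second-Born level in its
    time-local form: instead of accumulating the collision memory
    integral, the pair-correlation tensor
    ``G2_{ijkl} = <c_k+ c_l+ c_j c_i> - (rho_ik rho_jl - rho_il rho_jk)``
    is propagated alongside ``rho``; it is transported by the mean-field
    propagator (the GKBA reconstruction) and sourced by the Pauli-blocked
    second-order term, and feeds back on ``rho`` through the trace over
    the interaction. The two formulations are equivalent; the time-local
    one needs no history truncation. G2 lives on the correlated
    (molecular) block only — the absorbing quasi-continuum is a one-body
    escape channel by construction.
    """

    def __init__(self, system: DressedSystem, pulses, grid: PropagationGrid,
                 rho0: np.ndarray, correlated: bool = True):
        self.sys = system
        self.pulses = list(pulses)
        self.grid = grid
        self.dt_au = fs_to_au(grid.dt)
        self.correlated = correlated
        self.t_fs = grid.t_start
        self.rho = np.array(rho0, dtype=complex)
        n = self.sys.n_so
        if self.rho.shape != (n, n):
            raise ValueError("rho0 has wrong dimension")
        nc = self.sys.corr.size
        self.G2 = np.zeros((nc, nc, nc, nc), dtype=complex) if correlated else None
        self.warned_ansatz = False

    # -- correlation machinery ----------------------------------------------

    def _collision(self, G2) -> np.ndarray:
        """Hermitian collision contribution to drho/dt (full space)."""
        sysd = self.sys
        u = sysd.u_corr_au
        X = np.einsum("iklm,lmjk->ij", u, G2, optimize=True)
        C = -0.5j * (X - np.conj(X.T))
        out = np.zeros((sysd.n_so, sysd.n_so), dtype=complex)
        out[np.ix_(sysd.corr, sysd.corr)] = C
        return out

    def _pair_source(self, rho_full) -> np.ndarray:
        """Pauli-blocked second-order source of the pair correlations."""
        sysd = self.sys
        c = sysd.corr
        rho = rho_full[np.ix_(c, c)]
        rbar = np.eye(c.size) - rho
        u = sysd.u_corr_au
        t = np.einsum("ip,pqrs->iqrs", rbar, u, optimize=True)
        t = np.einsum("jq,iqrs->ijrs", rbar, t, optimize=True)
        t = np.einsum("ijrs,rk->ijks", t, rho, optimize=True)
        T1 = np.einsum("ijks,sl->ijkl", t, rho, optimize=True)
        # second term is the pair-adjoint of the first
        return T1 - np.conj(T1.transpose(2, 3, 0, 1))

    @staticmethod
    def _transport(U_cc, G2):
        g = np.einsum("ip,pjkl->ijkl", U_cc, G2, optimize=True)
        g = np.einsum("jq,iqkl->ijkl", U_cc, g, optimize=True)
        Uc = np.conj(U_cc)
        g = np.einsum("kr,ijrl->ijkl", Uc, g, optimize=True)
        return np.einsum("ls,ijks->ijkl", Uc, g, optimize=True)

    # -- stepping ----------------------------------------------------------

    def step(self):
        dt = self.dt_au
        sysd = self.sys
        c = sysd.corr
        t0, t1 = self.t_fs, self.t_fs + self.grid.dt

        C_n = self._collision(self.G2) if self.correlated else None

        h1 = sysd.h_hf(self.rho, t0, self.pulses)
        U1 = sla.expm(-1j * h1 * dt)
        rho_p = U1 @ self.rho @ np.conj(U1.T)
        if C_n is not None:
            rho_p = rho_p + dt * C_n
        # corrector: mean field of the averaged density, field at midpoint
        hm = sysd.h_hf(0.5 * (self.rho + rho_p), 0.5 * (t0 + t1), self.pulses)
        U = sla.expm(-1j * hm * dt)
        new = U @ self.rho @ np.conj(U.T)

        if self.correlated:
            Uh = sla.expm(-1j * hm * (0.5 * dt))
            U_cc = U[np.ix_(c, c)]
            Uh_cc = Uh[np.ix_(c, c)]
            psi_mid = self._pair_source(0.5 * (self.rho + rho_p))
            self.G2 = self._transport(U_cc, self.G2) \
                - 1j * dt * self._transport(Uh_cc, psi_mid)
            C_next = self._collision(self.G2)
            C_mid = 0.5 * (C_n + C_next)
            new = new + dt * (Uh @ C_mid @ np.conj(Uh.T))

        new = 0.5 * (new + np.conj(new.T))
        if not np.all(np.isfinite(new)):
            raise PropagationError(f"NaN/Inf in density matrix at t = {t1:.3f} fs")
        occ = np.real(np.diag(new))
        if self.correlated and not self.warned_ansatz and (
            occ.min() < -0.05 or occ.max() > 1.05
        ):
            warnings.warn(
                f"occupations left [-0.05, 1.05] at t = {t1:.3f} fs: "
                "ansatz breakdown (coupling too strong or dt too large)"
            )
            self.warned_ansatz = True
        self.rho = new
        self.t_fs = t1

    def snapshot(self) -> dict:
        return {
            "t_fs": self.t_fs,
            "rho": self.rho.copy(),
            "G2": None if self.G2 is None else self.G2.copy(),
        }

    def restore(self, snap: dict, pulses=None):
        self.t_fs = snap["t_fs"]
        self.rho = snap["rho"].copy()
        self.G2 = None if snap["G2"] is None else snap["G2"].copy()
        if pulses is not None:
            self.pulses = list(pulses)


def _run(system, pulses, grid, rho0, correlated, store_stride=1):
    if isinstance(system, ModelMolecule):
        system = DressedSystem.from_molecule(system)
    prop = _Propagator(system, pulses, grid, rho0, correlated=correlated)
    times = grid.times
    stored_t = [times[0]]
    stored_r = [prop.rho.copy()]
    for k in range(1, times.size):
        prop.step()
        if k % store_stride == 0 or k == times.size - 1:
            stored_t.append(prop.t_fs)
            stored_r.append(prop.rho.copy())
    traj = DensityMatrixTrajectory(np.array(stored_t), np.stack(stored_r))
    if not np.any(system.gamma_au):
        drift = abs(traj.particle_number[-1] - traj.particle_number[0])
        tol = 1e-4 if correlated else 1e-6
        if drift > tol:
            raise StabilityError(
                f"particle number drifted by {drift:.2e}; try dt = {grid.dt / 2:g} fs"
            )
    return traj


def propagate_meanfield(system, pulses, grid: PropagationGrid, rho0,
                        store_stride: int = 1) -> DensityMatrixTrajectory:
    """Time-dependent Hartree-Fock propagation (collisionless baseline)."""
    return _run(system, pulses, grid, rho0, correlated=False, store_stride=store_stride)


def propagate_gkba_2b(system, pulses, grid: PropagationGrid, rho0,
                      store_stride: int = 1) -> DensityMatrixTrajectory:
    """HF-GKBA propagation with the second-Born collision integral."""
    return _run(system, pulses, grid, rho0, correlated=True, store_stride=store_stride)


def propagate_exact_ci(mol: ModelMolecule, pulses, grid: PropagationGrid,
                       occupied=None, store_stride: int = 1) -> DensityMatrixTrajectory:
    """Exact CI propagation of a (small) molecule.

    ``occupied`` lists the occupied spin orbitals of the initial
    determinant (default: the sudden hole in the designated inner-valence
    orbital). Raises :class:`~chargemig.ci.CapacityError` when the
    determinant space exceeds its capacity.
    """
    sysd = DressedSystem.from_molecule(mol)
    if occupied is None:
        occupied = sudden_hole_determinant(mol, mol.hole_index)
    space = DeterminantSpace(mol.n_so, len(occupied))
    psi0 = space.determinant_vector(occupied)
    h0 = sysd.h0_au
    u = np.zeros((mol.n_so,) * 4)
    c = sysd.corr
    u[np.ix_(c, c, c, c)] = sysd.u_corr_au
    times_fs = grid.times
    times_au = fs_to_au(times_fs)
    if pulses:
        dip = sysd.dip_au

        def h1_of_t(t_au):
            t_fs = au_to_fs(t_au)
            h = h0.copy()
            for p in pulses:
                e = float(field_at(p, t_fs))
                if e != 0.0:
                    h = h + e * np.einsum("pqx,x->pq", dip, np.asarray(p.polarization))
            return h

        psis = space.propagate(psi0, h1_of_t, u, times_au)
    else:
        psis = space.propagate(psi0, h0, u, times_au)
    keep = list(range(0, times_fs.size, store_stride))
    if keep[-1] != times_fs.size - 1:
        keep.append(times_fs.size - 1)
    rhos = np.stack([space.one_body_rdm(psis[k]) for k in keep])
    return DensityMatrixTrajectory(times_fs[keep], rhos)


# ======================================================================
# depletion vs pump-probe delay
# ======================================================================

def _birth_times(pump: LaserPulse, n_birth: int):
    """Quantile birth times and weights from the pump intensity envelope."""
    if n_birth <= 1:
        return np.array([pump.center_time]), np.array([1.0])
    lo, hi = pump.support
    tt = np.linspace(lo, hi, 801)
    w = pump.envelope_at(tt) ** 2
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    qs = (np.arange(n_birth) + 0.5) / n_birth
    tb = np.interp(qs, cdf, tt)
    return tb, np.full(n_birth, 1.0 / n_birth)


def depletion_vs_delay(
    mol,
    pump: LaserPulse | None,
    nir: LaserPulse,
    delays,
    window: float = 1.0,
    method: str = "gkba",
    grid: PropagationGrid | None = None,
    continuum: dict | None = None,
    n_birth: int = 3,
) -> DepletionCurve:
    """NIR-induced depletion of the special state vs pump-probe delay.

    For each delay the dynamics is run with and without the NIR pulse
    centred there; the depletion is the occupation difference of the
    special state averaged over ``window`` fs after the pulse ends. The
    finite pump duration is handled by birth-time averaging: the sudden
    hole is created at t = 0 and the resulting delay curve is averaged
    over hole-creation times drawn from the pump intensity envelope.
    Delays are processed on a shared no-NIR reference propagation with
    checkpointing, so the cost scales with the NIR window, not the full
    trajectory, per delay.
    """
    delays = np.asarray(delays, dtype=float)
    order = np.argsort(delays)
    if isinstance(mol, DressedSystem):
        system = mol
    else:
        system = dress_with_continuum(mol, **(continuum or {}))
    if method not in ("gkba", "exact", "meanfield"):
        raise ValueError("method must be 'gkba', 'exact' or 'meanfield'")
    t_end_max = float(delays.max() + nir.fwhm_duration + window)
    if grid is None:
        grid = PropagationGrid(0.0, t_end_max + 2 * (0.8 * FS_PER_AUT), dt=0.8 * FS_PER_AUT,
                               memory_cutoff=1.5)
    elif grid.t_end < t_end_max:
        raise ValueError("grid too short: averaging window extends past t_end")
    if grid.t_start != 0.0:
        raise ValueError("depletion runs start at the ionisation instant t = 0")
    rho0 = initial_state_sudden_hole(system, system.mol.hole_index)

    if method == "exact":
        return _depletion_exact(system, nir, delays, window, grid, pump, n_birth)

    correlated = method == "gkba"
    times = grid.times
    dt = grid.dt
    base = _Propagator(system, [], grid, rho0, correlated=correlated)
    n_sp_base = np.empty(times.size)
    n_sp_base[0] = system.special_occupation(base.rho)

    # checkpoints: one per delay, at the last grid point before the NIR turns on
    start_idx = {}
    for d in delays:
        k = int(math.floor(max(d - nir.fwhm_duration, 0.0) / dt))
        start_idx[float(d)] = min(k, times.size - 1)
    snaps = {}
    need = sorted(set(start_idx.values()))
    ptr = 0
    if need and need[0] == 0:
        snaps[0] = base.snapshot()
        ptr = 1
    for k in range(1, times.size):
        base.step()
        n_sp_base[k] = system.special_occupation(base.rho)
        while ptr < len(need) and need[ptr] == k:
            snaps[k] = base.snapshot()
            ptr += 1

    raw = np.empty(delays.size)
    branch = _Propagator(system, [], grid, rho0, correlated=correlated)
    for i in order:
        d = float(delays[i])
        if nir.peak_intensity == 0.0:
            raw[i] = 0.0
            continue
        pulse = LaserPulse(
            central_photon_energy=nir.central_photon_energy,
            fwhm_duration=nir.fwhm_duration,
            peak_intensity=nir.peak_intensity,
            carrier_envelope_phase=nir.carrier_envelope_phase,
            envelope=nir.envelope,
            polarization=nir.polarization,
            center_time=d,
        )
        if d + nir.fwhm_duration < 0.0:
            raw[i] = 0.0  # whole pulse precedes the ionisation event
            continue
        k0 = start_idx[d]
        branch.restore(snaps[k0], pulses=[pulse])
        k_end = min(int(math.ceil((d + nir.fwhm_duration + window) / dt)), times.size - 1)
        w_lo = d + nir.fwhm_duration
        vals_nir, vals_base = [], []
        for k in range(k0 + 1, k_end + 1):
            branch.step()
            if times[k] >= w_lo:
                vals_nir.append(system.special_occupation(branch.rho))
                vals_base.append(n_sp_base[k])
        raw[i] = float(np.mean(vals_base) - np.mean(vals_nir)) if vals_nir else 0.0

    if pump is not None and n_birth > 1:
        tb, wb = _birth_times(pump, n_birth)
        srt = delays[order]
        avg = np.zeros_like(raw)
        for t_b, w_b in zip(tb, wb):
            avg += w_b * np.interp(delays - t_b, srt, raw[order])
        dep = avg
    else:
        dep = raw
    return DepletionCurve(delays=delays, depletion=dep, window=window, raw=raw)


def _depletion_exact(system, nir, delays, window, grid, pump, n_birth):
    """Exact-CI variant (small systems only); no checkpoint reuse."""
    mol = system.mol
    occupied = sudden_hole_determinant(mol, mol.hole_index)
    space = DeterminantSpace(system.n_so, len(occupied))
    psi0 = space.determinant_vector(
        occupied  # molecular orbitals map to the same leading spin orbitals
    )
    h0 = system.h0_au
    # embed the correlated u into the full space
    nso = system.n_so
    u_full = np.zeros((nso,) * 4, dtype=float)
    c = system.corr
    u_full[np.ix_(c, c, c, c)] = system.u_corr_au
    times_fs = grid.times
    times_au = fs_to_au(times_fs)
    dip = system.dip_au

    def run(pulses):
        if pulses:
            def h1(t_au):
                t_fs = au_to_fs(t_au)
                h = h0.copy()
                for p in pulses:
                    e = float(field_at(p, t_fs))
                    if e != 0.0:
                        h = h + e * np.einsum("pqx,x->pq", dip, np.asarray(p.polarization))
                if np.any(system.gamma_au):
                    h = h - 0.5j * np.diag(system.gamma_au)
                return h
            psis = space.propagate(psi0, h1, u_full, times_au)
        else:
            hh = h0 - 0.5j * np.diag(system.gamma_au) if np.any(system.gamma_au) else h0
            psis = space.propagate(psi0, hh, u_full, times_au)
        sp = system.special_spatial
        n_sp = np.empty(times_fs.size)
        for k in range(times_fs.size):
            rho = space.one_body_rdm(psis[k])
            n_sp[k] = np.real(rho[2 * sp, 2 * sp] + rho[2 * sp + 1, 2 * sp + 1])
        return n_sp

    base = run([])
    raw = np.empty(delays.size)
    for i, d in enumerate(delays):
        if nir.peak_intensity == 0.0 or d + nir.fwhm_duration < 0:
            raw[i] = 0.0
            continue
        pulse = LaserPulse(
            central_photon_energy=nir.central_photon_energy,
            fwhm_duration=nir.fwhm_duration,
            peak_intensity=nir.peak_intensity,
            envelope=nir.envelope,
            polarization=nir.polarization,
            center_time=float(d),
        )
        n_nir = run([pulse])
        mask = (times_fs >= d + nir.fwhm_duration) & (
            times_fs <= d + nir.fwhm_duration + window
        )
        raw[i] = float(np.mean(base[mask] - n_nir[mask])) if mask.any() else 0.0
    if pump is not None and n_birth > 1:
        tb, wb = _birth_times(pump, n_birth)
        srt = np.argsort(delays)
        dep = np.zeros_like(raw)
        for t_b, w_b in zip(tb, wb):
            dep += w_b * np.interp(delays - t_b, delays[srt], raw[srt])
    else:
        dep = raw
    return DepletionCurve(delays=delays, depletion=dep, window=window, raw=raw)
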