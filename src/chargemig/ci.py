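"""Exact configuration-interaction propagation on small model molecules.

Full diagonalisation in the fixed-particle-number determinant basis; used
as the validation oracle for the mean-field and GKBA propagators and for
the golden-rule rates. Capacity is limited by design (the determinant
space must stay at or below 2^10); a :class:`CapacityError` is raised
beyond that.

Determinants are spin-orbital occupation bitmasks; matrix elements follow
the Slater-Condon rules with antisymmetrized two-electron integrals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = ["CapacityError", "DeterminantSpace"]

MAX_DETS = 1024


class CapacityError(RuntimeError):
    pass


def _bits(mask: int, n: int):
    return [p for p in range(n) if mask >> p & 1]


def _sign_annihilate(mask: int, p: int) -> int:
    """Fermionic sign of c_p acting on the determinant ``mask``."""
    return -1 if bin(mask & ((1 << p) - 1)).count("1") % 2 else 1


@dataclass
class DeterminantSpace:
    """All determinants of ``n_elec`` electrons in ``n_so`` spin orbitals."""

    n_so: int
    n_elec: int

    def __post_init__(self):
        if self.n_elec < 0 or self.n_elec > self.n_so:
            raise ValueError("invalid electron count")
        dets = [m for m in range(1 << self.n_so) if bin(m).count("1") == self.n_elec]
        if len(dets) > MAX_DETS:
            raise CapacityError(
                f"{len(dets)} determinants exceed the exact-CI capacity of {MAX_DETS}"
            )
        self.dets = dets
        self.index = {m: i for i, m in enumerate(dets)}

    @property
    def dim(self) -> int:
        return len(self.dets)

    # ------------------------------------------------------------------

    def determinant_vector(self, occupied) -> np.ndarray:
        """Unit CI vector on the determinant with the given occupied
        spin orbitals."""
        mask = 0
        for p in occupied:
            mask |= 1 << p
        v = np.zeros(self.dim, dtype=complex)
        v[self.index[mask]] = 1.0
        return v

    def hamiltonian(self, h1: np.ndarray, u: np.ndarray | None = None) -> np.ndarray:
        """Dense many-body Hamiltonian.

        ``h1`` is the (possibly complex, possibly non-Hermitian when
        absorbing widths are present) one-body matrix; ``u`` the
        antisymmetrized two-electron integrals ``<pq||rs>``; both in
        consistent (atomic) units.
        """
        n = self.n_so
        dim = self.dim
        H = np.zeros((dim, dim), dtype=complex)
        for I, DI in enumerate(self.dets):
            occ = _bits(DI, n)
            # diagonal
            e = sum(h1[p, p] for p in occ)
            if u is not None:
                e += 0.5 * sum(u[p, q, p, q] for p in occ for q in occ)
            H[I, I] = e
            # single excitations p (occ) -> q (empty)
            for p in occ:
                for q in range(n):
                    if DI >> q & 1:
                        continue
                    DJ = (DI ^ (1 << p)) | (1 << q)
                    sgn = _sign_annihilate(DI, p) * _sign_annihilate(DI ^ (1 << p), q)
                    val = h1[q, p]
                    if u is not None:
                        val = val + sum(u[q, r, p, r] for r in occ if r != p)
                    H[self.index[DJ], I] += sgn * val
            # double excitations (p < p') -> (q < q'): both targets empty
            if u is not None:
                for ip, p in enumerate(occ):
                    for pp in occ[ip + 1:]:
                        rest = DI ^ (1 << p) ^ (1 << pp)
                        for q in range(n):
                            if DI >> q & 1:  # true doubles only
                                continue
                            for qq in range(q + 1, n):
                                if DI >> qq & 1:
                                    continue
                                DJ = rest | (1 << q) | (1 << qq)
                                # operator sequence c_qq'^† c_q^† c_p c_p'
                                s = _sign_annihilate(DI, pp)
                                m1 = DI ^ (1 << pp)
                                s *= _sign_annihilate(m1, p)
                                m2 = m1 ^ (1 << p)
                                s *= _sign_annihilate(m2, q)
                                m3 = m2 | (1 << q)
                                s *= _sign_annihilate(m3, qq)
                                H[self.index[DJ], I] += s * u[qq, q, pp, p]
        return H

    # ------------------------------------------------------------------

    def one_body_rdm(self, psi: np.ndarray) -> np.ndarray:
        """rho_pq = <psi| c_q^dagger c_p |psi> (not renormalised)."""
        n = self.n_so
        rho = np.zeros((n, n), dtype=complex)
        for I, DI in enumerate(self.dets):
            cI = psi[I]
            if cI == 0:
                continue
            for q in _bits(DI, n):
                m1 = DI ^ (1 << q)
                s1 = _sign_annihilate(DI, q)
                for p in range(n):
                    if m1 >> p & 1:
                        continue
                    DJ = m1 | (1 << p)
                    s2 = _sign_annihilate(m1, p)
                    rho[p, q] += s1 * s2 * np.conj(psi[self.index[DJ]]) * cI
        return rho

    def propagate(self, psi0: np.ndarray, h1_of_t, u: np.ndarray | None,
                  times: np.ndarray) -> np.ndarray:
        """Propagate a CI vector over ``times`` (a.u.).

        ``h1_of_t`` is either a constant matrix or a callable
        ``t -> h1``; time-dependent Hamiltonians are stepped with the
        midpoint exponential. Returns the stacked wavefunctions.
        """
        psi = np.array(psi0, dtype=complex)
        out = np.empty((times.size, self.dim), dtype=complex)
        out[0] = psi
        static = not callable(h1_of_t)
        if static:
            H = self.hamiltonian(h1_of_t, u)
            herm = np.allclose(H, H.conj().T, atol=1e-12)
            if herm:
                w, V = np.linalg.eigh(H)
                c0 = V.conj().T @ psi
                for k in range(1, times.size):
                    out[k] = V @ (np.exp(-1j * w * (times[k] - times[0])) * c0)
            else:
                for k in range(1, times.size):
                    dt = times[k] - times[k - 1]
                    psi = sla.expm(-1j * H * dt) @ psi
                    out[k] = psi
            return out
        for k in range(1, times.size):
            dt = times[k] - times[k - 1]
            tm = 0.5 * (times[k] + times[k - 1])
            H = self.hamiltonian(h1_of_t(tm), u)
            psi = sla.expm(-1j * H * dt) @ psi
            out[k] = psi
        return out
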