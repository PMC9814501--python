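"""Few-orbital model molecules.

A :class:`ModelMolecule` is a compact electronic-structure record standing
in for the ionised nucleobase: orbital energies, two-electron Coulomb
integrals, dipole matrix elements, a designated inner-valence hole orbital
(the XUV-created vacancy) and a designated "special" shake-up virtual (the
analogue of the slow bound excited state that clocks the charge-migration
delay).

Conventions
-----------
* Canonical data are stored per *spatial* orbital; spin-orbital arrays are
  derived (spin orbital ``p = 2 * spatial + sigma``, sigma in {0, 1}).
  The ground state is closed shell, so both spins share energies and
  integrals.
* Two-electron integrals use the physicist notation ``<pq|v|rs>`` (orbital
  1 carries p and r) with the 8-fold permutational symmetry of real
  orbitals, in eV.
* Orbitals are ordered occupied block first, each block sorted by energy
  ascending. Every virtual is bound: its binding energy ``-eps_a`` is > 0.
* ``coupling_scale`` multiplies all two-electron integrals wherever they
  enter a calculation; the stored base integrals are never mutated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ModelMolecule"]


def _check_eightfold(w: np.ndarray, tol: float = 1e-9) -> bool:
    return (
        np.allclose(w, w.transpose(1, 0, 3, 2), atol=tol)
        and np.allclose(w, w.transpose(2, 3, 0, 1), atol=tol)
        and np.allclose(w, w.transpose(2, 1, 0, 3), atol=tol)
    )


@dataclass
class ModelMolecule:
    """Adenine-like few-orbital molecule (spatial-orbital storage).

    Parameters
    ----------
    energies_spatial : (n_sp,) array
        Orbital energies in eV, occupied block first, both blocks ascending.
    n_occ_spatial : int
        Number of doubly occupied spatial orbitals in the neutral.
    two_electron_spatial : (n_sp, n_sp, n_sp, n_sp) array
        Base Coulomb integrals ``<pq|v|rs>`` in eV (before coupling_scale).
    dipoles_spatial : (n_sp, n_sp, 3) array
        Dipole matrix elements in atomic units, symmetric in (p, q).
    hole_spatial : int
        Spatial index of the designated inner-valence hole orbital.
    special_spatial : int
        Spatial index of the designated special shake-up virtual.
    hole_weights_spatial : (n_occ_spatial,) array
        XUV ionisation weights per occupied spatial orbital; sum to 1.
    coupling_scale : float
        Dimensionless multiplier applied to all two-electron integrals.
    """

    energies_spatial: np.ndarray
    n_occ_spatial: int
    two_electron_spatial: np.ndarray
    dipoles_spatial: np.ndarray
    hole_spatial: int
    special_spatial: int
    hole_weights_spatial: np.ndarray
    coupling_scale: float = 1.0
    #: optional correlated active space (spatial indices); orbitals left
    #: out are treated at the one-body level by the propagators (used for
    #: channels that are inert for the designated-hole dynamics)
    active_spatial: list | None = None

    def __post_init__(self):
        self.energies_spatial = np.asarray(self.energies_spatial, dtype=float)
        self.two_electron_spatial = np.asarray(self.two_electron_spatial, dtype=float)
        self.dipoles_spatial = np.asarray(self.dipoles_spatial, dtype=float)
        self.hole_weights_spatial = np.asarray(self.hole_weights_spatial, dtype=float)
        n = self.energies_spatial.size
        if self.two_electron_spatial.shape != (n, n, n, n):
            raise ValueError("two_electron_spatial shape mismatch")
        if self.dipoles_spatial.shape != (n, n, 3):
            raise ValueError("dipoles_spatial shape mismatch")
        if not (0 < self.n_occ_spatial < n):
            raise ValueError("need at least one occupied and one virtual orbital")
        if not (0 <= self.hole_spatial < self.n_occ_spatial):
            raise ValueError("hole_spatial must index an occupied orbital")
        if not (self.n_occ_spatial <= self.special_spatial < n):
            raise ValueError("special_spatial must index a virtual orbital")
        occ = self.energies_spatial[: self.n_occ_spatial]
        vir = self.energies_spatial[self.n_occ_spatial:]
        if np.any(np.diff(occ) < 0) or np.any(np.diff(vir) < 0):
            raise ValueError("energies must be ascending within each block")
        if np.any(vir >= 0):
            raise ValueError("all virtuals must be bound (negative energy)")
        if abs(self.hole_weights_spatial.sum() - 1.0) > 1e-9:
            raise ValueError("hole_weights must sum to 1")
        if not _check_eightfold(self.two_electron_spatial):
            raise ValueError("two-electron integrals lack 8-fold symmetry")
        if self.active_spatial is not None:
            self.active_spatial = [int(p) for p in self.active_spatial]
            if any(p < 0 or p >= n for p in self.active_spatial):
                raise ValueError("active_spatial index out of range")
        self._cache: dict = {}

    # ------------------------------------------------------------------
    # sizes and index helpers
    # ------------------------------------------------------------------

    @property
    def n_spatial(self) -> int:
        return self.energies_spatial.size

    @property
    def n_virt_spatial(self) -> int:
        return self.n_spatial - self.n_occ_spatial

    @property
    def n_so(self) -> int:
        """Number of spin orbitals."""
        return 2 * self.n_spatial

    @property
    def n_electrons(self) -> int:
        """Electron count of the neutral closed-shell ground state."""
        return 2 * self.n_occ_spatial

    @property
    def occupied_so(self) -> np.ndarray:
        return np.arange(2 * self.n_occ_spatial)

    @property
    def virtual_so(self) -> np.ndarray:
        return np.arange(2 * self.n_occ_spatial, self.n_so)

    @property
    def hole_index(self) -> int:
        """Spin orbital id of the designated hole (alpha spin by convention)."""
        return 2 * self.hole_spatial

    @property
    def special_index(self) -> int:
        """Spin orbital id of the designated special virtual (alpha spin)."""
        return 2 * self.special_spatial

    def spatial_of(self, p: int) -> int:
        return p // 2

    def is_occupied_so(self, p: int) -> bool:
        return p < 2 * self.n_occ_spatial

    # ------------------------------------------------------------------
    # derived spin-orbital arrays (cached; base integrals, no lambda)
    # ------------------------------------------------------------------

    @property
    def orbital_energies(self) -> np.ndarray:
        """Spin-orbital energies in eV."""
        if "eps_so" not in self._cache:
            self._cache["eps_so"] = np.repeat(self.energies_spatial, 2)
        return self._cache["eps_so"]

    @property
    def two_electron_so(self) -> np.ndarray:
        """Base spin-orbital integrals ``<pq|v|rs>`` in eV (no coupling_scale)."""
        if "v_so" not in self._cache:
            n = self.n_spatial
            w = self.two_electron_spatial
            nso = 2 * n
            v = np.zeros((nso, nso, nso, nso))
            sp = np.arange(nso) // 2
            sz = np.arange(nso) % 2
            d13 = (sz[:, None] == sz[None, :]).astype(float)  # spin delta
            # <p q | r s>: spin delta between p,r and between q,s
            v = (
                w[np.ix_(sp, sp, sp, sp)]
                * d13[:, None, :, None]
                * d13[None, :, None, :]
            )
            self._cache["v_so"] = v
        return self._cache["v_so"]

    @property
    def two_electron_integrals(self) -> np.ndarray:
        """Effective spin-orbital integrals, coupling_scale included (eV)."""
        return self.coupling_scale * self.two_electron_so

    @property
    def antisymmetrized_so(self) -> np.ndarray:
        """``<pq||rs> = <pq|rs> - <pq|sr>`` base integrals (eV)."""
        if "u_so" not in self._cache:
            v = self.two_electron_so
            self._cache["u_so"] = v - v.transpose(0, 1, 3, 2)
        return self._cache["u_so"]

    @property
    def dipole_elements(self) -> np.ndarray:
        """Spin-orbital dipole matrix elements (n_so, n_so, 3), a.u."""
        if "d_so" not in self._cache:
            nso = self.n_so
            sp = np.arange(nso) // 2
            sz = np.arange(nso) % 2
            dsz = (sz[:, None] == sz[None, :]).astype(float)
            self._cache["d_so"] = self.dipoles_spatial[np.ix_(sp, sp)] * dsz[..., None]
        return self._cache["d_so"]

    @property
    def hole_weights_so(self) -> np.ndarray:
        """Ionisation weights per occupied spin orbital (sum to 1)."""
        return np.repeat(self.hole_weights_spatial / 2.0, 2)

    # ------------------------------------------------------------------

    def with_coupling_scale(self, lam: float) -> "ModelMolecule":
        """Copy of this molecule with a different coupling scale."""
        return replace(self, coupling_scale=float(lam))

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "energies_spatial": self.energies_spatial.tolist(),
            "n_occ_spatial": int(self.n_occ_spatial),
            "two_electron_spatial": self.two_electron_spatial.tolist(),
            "dipoles_spatial": self.dipoles_spatial.tolist(),
            "hole_spatial": int(self.hole_spatial),
            "special_spatial": int(self.special_spatial),
            "hole_weights_spatial": self.hole_weights_spatial.tolist(),
            "coupling_scale": float(self.coupling_scale),
            "active_spatial": self.active_spatial,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelMolecule":
        return cls(
            energies_spatial=np.asarray(d["energies_spatial"], dtype=float),
            n_occ_spatial=int(d["n_occ_spatial"]),
            two_electron_spatial=np.asarray(d["two_electron_spatial"], dtype=float),
            dipoles_spatial=np.asarray(d["dipoles_spatial"], dtype=float),
            hole_spatial=int(d["hole_spatial"]),
            special_spatial=int(d["special_spatial"]),
            hole_weights_spatial=np.asarray(d["hole_weights_spatial"], dtype=float),
            coupling_scale=float(d.get("coupling_scale", 1.0)),
            active_spatial=d.get("active_spatial"),
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "ModelMolecule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
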