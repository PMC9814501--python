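"""Fermi's-golden-rule shake-up rates and characteristic times.

After XUV ionisation leaves a hole in an inner-valence orbital ``h``, the
residual Coulomb interaction can de-excite the hole while promoting a
second electron to a bound virtual ``a`` (a shake-up). Treating the
Coulomb interaction as the perturbation between the one-hole state and
the two-hole-one-particle states gives the golden-rule rate

    Gamma(h -> a) = (2 pi / hbar) * sum_{i<j occ} |<ah||ij>|^2
                                      * delta_eta(e_i + e_j - e_h - e_a)

with the energy-conserving delta broadened to a Lorentzian of half-width
``eta``. Rates from the different XUV-populated hole channels are summed
with their statistical (ionisation) weights; the inverse of the summed
rate is the characteristic shake-up time of the virtual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._units import HBAR_EV_FS
from .molecule import ModelMolecule

__all__ = [
    "FgrOptions",
    "ShakeupRateTable",
    "slater_condon_element",
    "shakeup_rate",
    "characteristic_times",
    "photon_group",
]

#: default NIR photon energy, eV
NIR_PHOTON_EV = 1.77


@dataclass
class FgrOptions:
    """Options of the golden-rule evaluation.

    broadening_eta : Lorentzian half-width (eV) standing in for the
        energy-conserving delta function.
    pair_restriction : ``"distinct_pairs"`` sums each occupied pair
        (i < j) once; ``"all_ordered"`` sums ordered pairs and halves,
        which is numerically identical for antisymmetrized elements and
        kept for cross-checking the convention.
    """

    broadening_eta: float = 0.2
    pair_restriction: str = "distinct_pairs"

    def __post_init__(self):
        if self.broadening_eta <= 0:
            raise ValueError("broadening_eta must be > 0")
        if self.pair_restriction not in ("distinct_pairs", "all_ordered"):
            raise ValueError("unknown pair_restriction")


@dataclass
class ShakeupRateTable:
    """Per-virtual golden-rule rates, times and NIR-photon groups.

    One row per *spatial* virtual orbital (both spin states of the
    promoted electron are summed into the rate, as are the weighted hole
    channels). ``tau_fs`` is ``inf`` where the rate vanishes.
    """

    virtual_spatial: np.ndarray
    energy_ev: np.ndarray
    gamma_per_fs: np.ndarray
    tau_fs: np.ndarray
    photon_group: np.ndarray
    hole_breakdown: list  # per row: dict spatial hole -> rate contribution
    special_spatial: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "virtual_id": self.virtual_spatial,
                "energy_eV": self.energy_ev,
                "gamma_per_fs": self.gamma_per_fs,
                "tau_fs": self.tau_fs,
                "photon_group": self.photon_group,
                "special": self.virtual_spatial == self.special_spatial,
            }
        )

    @property
    def special_row(self) -> int:
        return int(np.nonzero(self.virtual_spatial == self.special_spatial)[0][0])

    @property
    def special_tau(self) -> float:
        return float(self.tau_fs[self.special_row])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def _lorentzian(x, eta):
    return (eta / math.pi) / (x * x + eta * eta)


def slater_condon_element(mol: ModelMolecule, h: int, i: int, j: int, a: int) -> float:
    """Coulomb matrix element (eV) between the one-hole determinant
    (hole in spin orbital ``h``) and the two-hole-one-particle
    determinant (holes in ``i``, ``j``; particle in ``a``).

    The determinants differ by exactly two spin orbitals, so only the
    antisymmetrized two-body element survives:
    ``<ah||ij> = <ah|v|ij> - <ah|v|ji>`` (physicist convention, including
    the molecule's coupling scale). Vanishes for ``i == j``.
    """
    for k, name in ((h, "h"), (i, "i"), (j, "j")):
        if not mol.is_occupied_so(k):
            raise ValueError(f"index {name}={k} must be an occupied spin orbital")
    if a < 0 or a >= mol.n_so or mol.is_occupied_so(a):
        raise ValueError(f"index a={a} must be a virtual spin orbital")
    if i == j:
        return 0.0
    v = mol.two_electron_so
    return mol.coupling_scale * (v[a, h, i, j] - v[a, h, j, i])


def shakeup_rate(mol: ModelMolecule, h: int, a: int, opts: FgrOptions | None = None) -> float:
    """Golden-rule shake-up rate (1/fs) for hole spin orbital ``h``
    decaying into the bound virtual spin orbital ``a``."""
    opts = opts or FgrOptions()
    eps = mol.orbital_energies
    occ = mol.occupied_so
    eta = opts.broadening_eta
    pref = 2.0 * math.pi / HBAR_EV_FS
    total = 0.0
    if opts.pair_restriction == "distinct_pairs":
        pairs = ((i, j) for k, i in enumerate(occ) for j in occ[k + 1:])
        scale = 1.0
    else:
        pairs = ((i, j) for i in occ for j in occ if i != j)
        scale = 0.5
    for i, j in pairs:
        if i == h or j == h:
            continue  # not a two-orbital difference
        m = slater_condon_element(mol, h, int(i), int(j), a)
        if m == 0.0:
            continue
        de = eps[i] + eps[j] - eps[h] - eps[a]
        total += m * m * _lorentzian(de, eta)
    return pref * scale * total


def characteristic_times(mol: ModelMolecule, opts: FgrOptions | None = None) -> ShakeupRateTable:
    """Statistically summed shake-up rates and characteristic times.

    For every spatial virtual ``A``, the rate is the ionisation-weighted
    sum over hole channels of the golden-rule rates into both spin states
    of ``A``; the characteristic time is its inverse.
    """
    opts = opts or FgrOptions()
    w_h = mol.hole_weights_so
    if abs(w_h.sum() - 1.0) > 1e-9:
        raise ValueError("hole weights must sum to 1")
    n_occ_sp = mol.n_occ_spatial
    rows_gamma, rows_breakdown = [], []
    virt_sp = np.arange(n_occ_sp, mol.n_spatial)
    for A in virt_sp:
        breakdown = {}
        for h_so, w in enumerate(w_h):
            if w == 0.0:
                continue
            g = sum(
                shakeup_rate(mol, h_so, 2 * A + s, opts) for s in (0, 1)
            )
            breakdown[h_so // 2] = breakdown.get(h_so // 2, 0.0) + w * g
        rows_breakdown.append(breakdown)
        rows_gamma.append(sum(breakdown.values()))
    gamma = np.asarray(rows_gamma)
    with np.errstate(divide="ignore"):
        tau = np.where(gamma > 0, 1.0 / np.where(gamma > 0, gamma, 1.0), np.inf)
    energy = mol.energies_spatial[virt_sp]
    groups = np.array([photon_group(-e) for e in energy])
    return ShakeupRateTable(
        virtual_spatial=virt_sp,
        energy_ev=energy,
        gamma_per_fs=gamma,
        tau_fs=tau,
        photon_group=groups,
        hole_breakdown=rows_breakdown,
        special_spatial=mol.special_spatial,
    )


def photon_group(binding_energy: float, photon_energy: float = NIR_PHOTON_EV) -> int:
    """Minimum number of probe photons needed to ionise an electron of
    the given binding energy (eV). Exact multiples (within 1e-9 eV) are
    assigned to the lower group."""
    if binding_energy <= 0 or photon_energy <= 0:
        raise ValueError("binding_energy and photon_energy must be > 0")
    n = int(math.ceil((binding_energy - 1e-9) / photon_energy))
    return max(1, n)
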