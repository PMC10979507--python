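"""One-electron properties of the effective Hamiltonian.

The pseudo-Hamiltonian lives in an implicit orthonormal minimal basis, so the
MO problem is an ordinary symmetric eigensolve.  Properties follow closed-shell
aufbau filling with double occupation; a partially-occupied degenerate frontier
shell (e.g. icosahedral C60 with an open degenerate level under integer
filling) is occupied fractionally and uniformly so that the density matrix
retains the molecular point-group symmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BasisLayout
from .constants import HARTREE_EV
from .geometry import MolecularGeometry

DEGENERACY_TOL = 1e-8


@dataclass
class MOSolution:
    """MO energies (Hartree, ascending), coefficients (orbital x MO) and the
    closed-shell occupation vector (per-MO electron counts summing to the
    electron count; 2 per fully-occupied MO)."""

    energies: np.ndarray
    coefficients: np.ndarray
    occupations: np.ndarray

    @property
    def n_occ(self) -> int:
        """Number of (at least partially) occupied MOs."""
        return int(np.sum(self.occupations > 0))

    @property
    def n_electrons(self) -> int:
        return int(round(self.occupations.sum()))


def _occupations(energies: np.ndarray, n_electrons: int) -> np.ndarray:
    occ = np.zeros_like(energies)
    n_full = n_electrons // 2
    occ[:n_full] = 2.0
    if n_full == 0 or n_full == energies.size:
        return occ
    homo, lumo = energies[n_full - 1], energies[n_full]
    if lumo - homo < DEGENERACY_TOL:
        # partially-occupied degenerate frontier shell: spread uniformly
        shell = np.abs(energies - homo) < DEGENERACY_TOL
        n_shell_elec = n_electrons - 2 * np.sum(energies < homo - DEGENERACY_TOL)
        occ[:] = 0.0
        occ[energies < homo - DEGENERACY_TOL] = 2.0
        occ[shell] = n_shell_elec / np.sum(shell)
        warnings.warn("partially occupied degenerate frontier shell; "
                      "occupation symmetrized over the degenerate level",
                      stacklevel=2)
    return occ


def solve_mos(hamiltonian, n_electrons: int) -> MOSolution:
    """Eigensolve of the effective Hamiltonian with deterministic MO signs
    (largest-magnitude coefficient of each MO made positive)."""
    H = hamiltonian.matrix if hasattr(hamiltonian, "matrix") else np.asarray(hamiltonian)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite Hamiltonian entries")
    if n_electrons % 2 != 0:
        raise ValueError("closed-shell only: electron count must be even")
    if n_electrons > 2 * H.shape[0]:
        raise ValueError("more electrons than 2 x orbital count")
    eps, C = np.linalg.eigh(H)
    flip = np.sign(C[np.argmax(np.abs(C), axis=0), np.arange(C.shape[1])])
    flip[flip == 0] = 1.0
    C = C * flip
    return MOSolution(eps, C, _occupations(eps, n_electrons))


@dataclass
class ChargeVector:
    q: np.ndarray  # per-atom Löwdin charge, e


def loewdin_charges(solution: MOSolution, geometry: MolecularGeometry,
                    layout: BasisLayout) -> ChargeVector:
    """q_A = Z_A - sum_{mu in A} sum_n f_n C_{mu n}^2 (f_n = 2 for occupied)."""
    atom_of = layout.atom_of_orbital(geometry)
    pops = (solution.coefficients ** 2) @ solution.occupations  # per-orbital
    q = geometry.atomic_numbers.astype(float)
    np.add.at(q, atom_of, -pops)
    total = q.sum()
    if abs(total - geometry.net_charge) > 1e-8:
        raise RuntimeError(f"Löwdin charge sum rule violated by {total:.2e}")
    return ChargeVector(q)


def transition_charges(solution: MOSolution, geometry: MolecularGeometry,
                       layout: BasisLayout, p: int, q: int) -> np.ndarray:
    """Löwdin transition charges q_pq^A = sum_{mu in A} C_{mu p} C_{mu q}."""
    n_mo = solution.coefficients.shape[1]
    if not (0 <= p < n_mo and 0 <= q < n_mo):
        raise IndexError(f"MO indices ({p},{q}) out of range 0..{n_mo - 1}")
    atom_of = layout.atom_of_orbital(geometry)
    prod = solution.coefficients[:, p] * solution.coefficients[:, q]
    out = np.zeros(geometry.n_atoms)
    np.add.at(out, atom_of, prod)
    return out


def transition_charge_matrix(solution: MOSolution, geometry: MolecularGeometry,
                             layout: BasisLayout, mos_left, mos_right) -> np.ndarray:
    """q^A_pq for all p in mos_left, q in mos_right: (n_atoms, len_p, len_q)."""
    atom_of = layout.atom_of_orbital(geometry)
    Cp = solution.coefficients[:, mos_left]
    Cq = solution.coefficients[:, mos_right]
    out = np.zeros((geometry.n_atoms, Cp.shape[1], Cq.shape[1]))
    prod = Cp[:, :, None] * Cq[:, None, :]
    np.add.at(out, atom_of, prod)
    return out


def homo_lumo_gap(solution: MOSolution) -> float:
    """HOMO-LUMO gap in eV."""
    n_occ = solution.n_occ
    if n_occ >= solution.energies.size:
        raise ValueError("no virtual MOs: gap undefined")
    if n_occ == 0:
        raise ValueError("no occupied MOs: gap undefined")
    return float((solution.energies[n_occ] - solution.energies[n_occ - 1]) * HARTREE_EV)
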