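"""Simplified Tamm-Dancoff (sTDA) excited states on top of the effective
Hamiltonian's MOs.

The singlet TDA matrix is built in the monopole approximation:

    A_{ia,jb} = delta_ij delta_ab (eps_a - eps_i)
                + 2 sum_AB q_ia^A gammaK_AB q_jb^B
                -   sum_AB q_ij^A gammaJ_AB q_ab^B

with Löwdin transition charges q_pq^A and Mataga-Nishimoto-Ohno-Klopman
gamma kernels.  The CI space of occupied->virtual single excitations is
truncated by an energy window on the diagonal elements plus second-order
perturbative selection of strongly coupled secondary configurations, then
AX = Omega X is solved by dense symmetric diagonalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisLayout
from .constants import BOHR_ANGSTROM, HARTREE_EV
from .geometry import MolecularGeometry
from .properties import MOSolution, transition_charge_matrix

# chemical hardness eta = IP - EA (Hartree), Pearson-scale values
DEFAULT_HARDNESS = {
    "H": 0.4720,   # 12.84 eV
    "C": 0.3674,   # 10.00 eV
    "N": 0.5355,
    "O": 0.5822,
}


@dataclass(frozen=True)
class STDAParameters:
    """Monopole-kernel parameters of the original sTDA parametrization:
    alpha = alpha1 + alpha2*a_x (exchange channel), beta = beta1 + beta2*a_x
    (Coulomb channel); a_x is the global hybrid exchange fraction (0.2 for
    B3LYP)."""

    a_x: float = 0.2
    alpha1: float = 1.42
    alpha2: float = 0.48
    beta1: float = 0.2
    beta2: float = 1.83
    hardness: dict = field(default_factory=lambda: dict(DEFAULT_HARDNESS))

    @property
    def alpha(self) -> float:
        return self.alpha1 + self.alpha2 * self.a_x

    @property
    def beta(self) -> float:
        return self.beta1 + self.beta2 * self.a_x


@dataclass
class GammaKernel:
    """Atom-pair Coulomb (J) and exchange (K) monopole integrals, Hartree."""

    gamma_J: np.ndarray
    gamma_K: np.ndarray
    parameters: STDAParameters


def build_gamma(geometry: MolecularGeometry,
                parameters: STDAParameters | None = None) -> GammaKernel:
    """Mataga-Nishimoto-Ohno-Klopman kernels: finite at R=0 (controlled by the
    mean chemical hardness), -> 1/R at large separation (atomic units)."""
    p = parameters or STDAParameters()
    try:
        eta = np.array([p.hardness[s] for s in geometry.symbols])
    except KeyError as exc:
        raise KeyError(f"no chemical hardness for element {exc.args[0]!r}")
    R = np.linalg.norm(geometry.coordinates[:, None, :]
                       - geometry.coordinates[None, :, :], axis=-1) / BOHR_ANGSTROM
    eta_mean = 0.5 * (eta[:, None] + eta[None, :])
    a_x = p.a_x
    gJ = (1.0 / (R ** p.beta + (a_x * eta_mean) ** (-p.beta))) ** (1.0 / p.beta)
    gK = (1.0 / (R ** p.alpha + eta_mean ** (-p.alpha))) ** (1.0 / p.alpha)
    return GammaKernel(gJ, gK, p)


@dataclass
class CISpace:
    """Occupied->virtual configurations (i, a) retained in the CI space."""

    configurations: list[tuple[int, int]]
    secondary: np.ndarray | None = None  # True where perturbatively promoted

    def __post_init__(self):
        if len(set(self.configurations)) != len(self.configurations):
            raise ValueError("duplicate configurations")


@dataclass
class ExcitationResult:
    energies: np.ndarray     # Omega_k ascending, eV
    amplitudes: np.ndarray   # X columns, unit-normalized
    space: CISpace | None = None


def full_ci_space(solution: MOSolution) -> CISpace:
    n_occ = solution.n_occ
    n_mo = solution.energies.size
    return CISpace([(i, a) for i in range(n_occ) for a in range(n_occ, n_mo)])


def build_A(solution: MOSolution, kernel: GammaKernel, space: CISpace,
            geometry: MolecularGeometry, layout: BasisLayout) -> np.ndarray:
    """Dense symmetric monopole-approximated singlet TDA matrix (Hartree)."""
    if not space.configurations:
        raise ValueError("empty CI space")
    occ = sorted({i for i, a in space.configurations})
    vir = sorted({a for i, a in space.configurations})
    o_idx = {i: k for k, i in enumerate(occ)}
    v_idx = {a: k for k, a in enumerate(vir)}
    q_ov = transition_charge_matrix(solution, geometry, layout, occ, vir)
    q_oo = transition_charge_matrix(solution, geometry, layout, occ, occ)
    q_vv = transition_charge_matrix(solution, geometry, layout, vir, vir)
    eps = solution.energies
    n = len(space.configurations)
    gK, gJ = kernel.gamma_K, kernel.gamma_J
    Kq = np.einsum("AB,Bjb->Ajb", gK, q_ov)
    coul = 2.0 * np.einsum("Aia,Ajb->iajb", q_ov, Kq)
    exch = np.einsum("Aij,AB,Bab->iajb", q_oo, gJ, q_vv)
    Afull = coul - exch
    ri = np.array([o_idx[i] for i, a in space.configurations])
    ra = np.array([v_idx[a] for i, a in space.configurations])
    A = Afull[ri[:, None], ra[:, None], ri[None, :], ra[None, :]]
    A[np.arange(n), np.arange(n)] += np.array(
        [eps[a] - eps[i] for i, a in space.configurations])
    A = 0.5 * (A + A.T)
    return A


def ci_diagonal(solution: MOSolution, kernel: GammaKernel,
                geometry: MolecularGeometry, layout: BasisLayout,
                space: CISpace) -> np.ndarray:
    """Diagonal elements A_{ia,ia} (Hartree) without building the full matrix."""
    eps = solution.energies
    out = np.empty(len(space.configurations))
    for r, (i, a) in enumerate(space.configurations):
        q_ia = transition_charge_matrix(solution, geometry, layout, [i], [a])[:, 0, 0]
        q_ii = transition_charge_matrix(solution, geometry, layout, [i], [i])[:, 0, 0]
        q_aa = transition_charge_matrix(solution, geometry, layout, [a], [a])[:, 0, 0]
        out[r] = (eps[a] - eps[i]
                  + 2.0 * q_ia @ kernel.gamma_K @ q_ia
                  - q_ii @ kernel.gamma_J @ q_aa)
    return out


def truncate_ci(solution: MOSolution, kernel: GammaKernel,
                geometry: MolecularGeometry, layout: BasisLayout,
                energy_threshold_ev: float = 10.0,
                perturbation_cutoff: float = 1e-4) -> CISpace:
    """Energy-window truncation plus perturbative selection.

    Primary configurations have diagonal elements below the threshold;
    excluded ones whose summed second-order coupling to the primaries exceeds
    ``perturbation_cutoff`` (Hartree) are promoted into the space.
    """
    if energy_threshold_ev <= 0:
        raise ValueError("energy threshold must be positive")
    full = full_ci_space(solution)
    diag = ci_diagonal(solution, kernel, geometry, layout, full)
    thresh = energy_threshold_ev / HARTREE_EV
    primary = diag <= thresh
    if not np.any(primary):
        raise ValueError("no configuration below the energy threshold; "
                         "increase it (smallest diagonal "
                         f"{diag.min() * HARTREE_EV:.2f} eV)")
    if np.all(primary):
        return CISpace(full.configurations, np.zeros(diag.size, bool))
    A = build_A(solution, kernel, full, geometry, layout)
    p_idx = np.where(primary)[0]
    s_idx = np.where(~primary)[0]
    promoted = []
    for u in s_idx:
        denom = diag[u] - diag[p_idx]
        denom = np.where(np.abs(denom) < 1e-6, 1e-6, denom)
        e2 = float(np.sum(A[u, p_idx] ** 2 / denom))
        if abs(e2) > perturbation_cutoff:
            promoted.append(u)
    keep = sorted(list(p_idx) + promoted)
    secondary = np.array([k not in set(p_idx) for k in keep])
    return CISpace([full.configurations[k] for k in keep], secondary)


def solve_tda(A: np.ndarray, n_states: int, space: CISpace | None = None
              ) -> ExcitationResult:
    """Lowest ``n_states`` eigenpairs of AX = Omega X; energies in eV."""
    if n_states > A.shape[0]:
        raise ValueError(f"requested {n_states} states from a "
                         f"{A.shape[0]}-dimensional CI space")
    from scipy.linalg import eigh
    w, X = eigh(A, subset_by_index=(0, n_states - 1))
    # deterministic phase: largest amplitude positive
    flip = np.sign(X[np.argmax(np.abs(X), axis=0), np.arange(X.shape[1])])
    flip[flip == 0] = 1.0
    X = X * flip
    return ExcitationResult(w * HARTREE_EV, X, space)


def excitations(solution: MOSolution, geometry: MolecularGeometry,
                layout: BasisLayout, n_states: int = 5,
                parameters: STDAParameters | None = None,
                energy_threshold_ev: float | None = 10.0,
                perturbation_cutoff: float = 1e-4) -> ExcitationResult:
    """Full sTDA pipeline: gamma kernels -> CI truncation -> A -> eigenpairs.

    ``energy_threshold_ev=None`` disables truncation (full CIS space).
    """
    kernel = build_gamma(geometry, parameters)
    if energy_threshold_ev is None:
        space = full_ci_space(solution)
    else:
        space = truncate_ci(solution, kernel, geometry, layout,
                            energy_threshold_ev, perturbation_cutoff)
    A = build_A(solution, kernel, space, geometry, layout)
    n_states = min(n_states, A.shape[0])
    return solve_tda(A, n_states, space)


def transition_density_atoms(result: ExcitationResult, solution: MOSolution,
                             geometry: MolecularGeometry, layout: BasisLayout,
                             state: int) -> np.ndarray:
    """Per-atom transition-density weights sum_ia X_{ia,k} q_ia^A of state k."""
    if not 0 <= state < result.energies.size:
        raise IndexError(f"state {state} out of range")
    out = np.zeros(geometry.n_atoms)
    X = result.amplitudes[:, state]
    for x, (i, a) in zip(X, result.space.configurations):
        q = transition_charge_matrix(solution, geometry, layout, [i], [a])[:, 0, 0]
        out += x * q
    return out
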