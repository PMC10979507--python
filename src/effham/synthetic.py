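"""Synthetic study inputs: toy geometries, teacher models with known weights,
a distance-dependent tight-binding reference, and stochastic excitation-energy
trajectories with known spectral content.

The teacher model draws random weights for the same feature/block structure
used in fitting, so teacher targets are exactly realizable and weight recovery
is well-posed.  The tight-binding reference is a Slater-Koster-style model
that is *not* in the linear feature class: it emulates the symmetry and
smooth distance dependence of mean-field minimal-basis targets, not their
values, and exercises the under-determination that separates eigenvalue-only
from eigenvalue+charge training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisLayout, minimal_layout
from .constants import KB_EV, HBAR_EV_FS, EV_CM
from .features import RadialBasisSpec, compute_features, default_species_order
from .geometry import MolecularGeometry, PairList, neighbor_pairs
from .hamiltonian import (EffectiveHamiltonian, ModelWeights, assemble_hamiltonian,
                          predict_blocks, predict_hamiltonian)

CC_SINGLE = 1.54  # Å
CC_DOUBLE = 1.34
CC_AROMATIC = 1.40
CH_BOND = 1.09
GOLDEN = (1 + np.sqrt(5.0)) / 2


# ---------------------------------------------------------------------------
# geometries


def _alkane_chain(n_carbon: int) -> tuple[tuple[str, ...], np.ndarray]:
    """All-trans alkane-like zig-zag C_n chain saturated with hydrogens
    (tetrahedral CH2/CH3 groups; H2 for n_carbon = 0 is not supported)."""
    half = np.deg2rad(112.0) / 2
    dx, dy = CC_SINGLE * np.sin(half), CC_SINGLE * np.cos(half)
    cpos = [np.array([i * dx, (i % 2) * dy, 0.0]) for i in range(n_carbon)]
    symbols = ["C"] * n_carbon
    coords = list(cpos)
    zhat = np.array([0.0, 0.0, 1.0])
    tet_cos, tet_sin = 1.0 / np.sqrt(3.0), np.sqrt(2.0 / 3.0)
    for i, c in enumerate(cpos):
        nbs = [(cpos[j] - c) / np.linalg.norm(cpos[j] - c)
               for j in (i - 1, i + 1) if 0 <= j < n_carbon]
        if len(nbs) == 2:
            b = -(nbs[0] + nbs[1])
            b /= np.linalg.norm(b)
            for sz in (+1.0, -1.0):
                symbols.append("H")
                coords.append(c + CH_BOND * (tet_cos * b + sz * tet_sin * zhat))
        elif len(nbs) == 1:
            # methyl: three H at 109.47 deg from the C-C bond, staggered
            u = nbs[0]
            e1 = np.cross(u, zhat)
            e1 /= np.linalg.norm(e1)
            for alpha in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                          np.pi / 2 + 4 * np.pi / 3):
                d = (-u / 3.0 + (2.0 * np.sqrt(2.0) / 3.0)
                     * (np.cos(alpha) * e1 + np.sin(alpha) * zhat))
                symbols.append("H")
                coords.append(c + CH_BOND * d)
        else:  # single carbon: methane
            for d in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
                symbols.append("H")
                coords.append(c + CH_BOND * np.array(d) / np.sqrt(3.0))
    return tuple(symbols), np.array(coords)


def _ring(n_carbon: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Planar C_n H_n ring with aromatic-like bond lengths."""
    r = CC_AROMATIC / (2 * np.sin(np.pi / n_carbon))
    ang = 2 * np.pi * np.arange(n_carbon) / n_carbon
    cpos = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_carbon)], axis=1)
    hpos = cpos * (1 + CH_BOND / r)
    symbols = ("C",) * n_carbon + ("H",) * n_carbon
    return symbols, np.vstack([cpos, hpos])


def make_geometries(family: str, n_structures: int, seed: int, *,
                    n_carbon: int = 4, jitter: float = 0.03,
                    rigid_motion: bool = True) -> list[MolecularGeometry]:
    """Seeded toy structures.

    family 'chain': all-trans alkane-like C_n chains; 'ring': C_nH_n rings;
    'perturbed': chains with coordinate jitter (σ = ``jitter`` Å per Cartesian
    component) and, when ``rigid_motion``, random rigid rotations/translations.
    """
    rng = np.random.default_rng(seed)
    if family == "chain":
        base = _alkane_chain(n_carbon)
        amp = 0.0
    elif family == "ring":
        base = _ring(n_carbon)
        amp = 0.0
    elif family == "perturbed":
        base = _alkane_chain(n_carbon)
        amp = jitter
    else:
        raise ValueError(f"unknown geometry family {family!r}")
    symbols, coords = base
    out = []
    for _ in range(n_structures):
        c = coords + rng.normal(0.0, amp, coords.shape) if amp else coords.copy()
        if rigid_motion and family == "perturbed":
            from .rotations import random_rotation
            c = c @ random_rotation(rng).T + rng.normal(0, 1.0, 3)
        out.append(MolecularGeometry(symbols, c))
    return out


def make_c60(bond_length: float = 1.44) -> MolecularGeometry:
    """Programmatic truncated-icosahedron C60 (icosahedral symmetry, uniform
    edge length equal to ``bond_length`` Å)."""
    phi = GOLDEN
    bases = [(0.0, 1.0, 3 * phi), (1.0, 2 + phi, 2 * phi), (2.0, 1 + 2 * phi, phi)]
    verts = set()
    for b in bases:
        for cyc in range(3):
            v = np.roll(b, cyc)
            for sx in (1, -1):
                for sy in (1, -1):
                    for sz in (1, -1):
                        w = (sx * v[0], sy * v[1], sz * v[2])
                        verts.add(tuple(np.round(w, 9)))
    coords = np.array(sorted(verts))
    assert coords.shape == (60, 3)
    coords *= bond_length / 2.0  # the unscaled polyhedron has edge length 2
    return MolecularGeometry(("C",) * 60, coords)


# ---------------------------------------------------------------------------
# teacher model


@dataclass
class TeacherModel:
    """Equivariant linear model with known random weights (the recovery oracle)."""

    weights: ModelWeights
    spec: RadialBasisSpec
    layout: BasisLayout
    species: tuple[str, ...]
    lam_max: int = 2

    @staticmethod
    def random(seed: int, spec: RadialBasisSpec | None = None,
               layout: BasisLayout | None = None,
               species: tuple[str, ...] | None = None,
               scale: float = 0.1, lam_max: int = 2) -> "TeacherModel":
        spec = spec or RadialBasisSpec()
        layout = layout or minimal_layout()
        species = species or default_species_order(layout)
        rng = np.random.default_rng(seed)
        w = ModelWeights.zeros(layout, spec, species, lam_max)
        for k in w.weights:
            n = w.weights[k].size
            w.weights[k] = rng.normal(0.0, scale / np.sqrt(max(n, 1)), n)
        return TeacherModel(w, spec, layout, species, lam_max)

    def hamiltonian(self, geometry: MolecularGeometry) -> EffectiveHamiltonian:
        return predict_hamiltonian(geometry, self.weights, self.layout,
                                   self.spec, self.species, self.lam_max)


# ---------------------------------------------------------------------------
# tight-binding reference


@dataclass
class ToyReference:
    """Slater-Koster-style exponential-decay tight-binding reference.

    Shell-resolved on-site energies (Hartree) and two-center hoppings
    V(r) = V0 * exp(-(r - r0)/decay) resolved into sigma/pi channels.  Chosen
    once to give bounded, gapped spectra for hydrocarbon-like topologies at
    equilibrium bonds; no claim of chemical accuracy.
    """

    onsite: dict = field(default_factory=lambda: {
        ("C", 0): -10.0,   # 1s core
        ("C", 1): -0.70,   # 2s
        ("C", 2): -0.35,   # 2p
        ("H", 0): -0.45,   # 1s
    })
    # (elem1, shell1, elem2, shell2, channel) -> (V0 at r0, decay Å); channel
    # "sigma"/"pi"; keys stored with (elem1, shell1) <= (elem2, shell2) by name
    hoppings: dict = field(default_factory=lambda: {
        ("C", 1, "C", 1, "sigma"): (-0.45, 0.8),
        ("C", 1, "C", 2, "sigma"): (0.40, 0.8),
        ("C", 2, "C", 2, "sigma"): (0.50, 0.8),
        ("C", 2, "C", 2, "pi"): (-0.20, 0.8),
        ("C", 1, "H", 0, "sigma"): (-0.50, 0.8),
        ("C", 2, "H", 0, "sigma"): (0.45, 0.8),
        ("H", 0, "H", 0, "sigma"): (-0.30, 0.8),
    })
    r0: float = 1.5  # Å, reference bond length for the decay laws

    def _v(self, el1, s1, el2, s2, channel, r):
        key = (el1, s1, el2, s2, channel)
        alt = (el2, s2, el1, s1, channel)
        par = self.hoppings.get(key) or self.hoppings.get(alt)
        if par is None:
            return 0.0
        v0, decay = par
        return v0 * np.exp(-(r - self.r0) / decay)

    def hamiltonian(self, geometry: MolecularGeometry,
                    layout: BasisLayout | None = None) -> np.ndarray:
        layout = layout or minimal_layout()
        n = layout.n_orbitals(geometry)
        H = np.zeros((n, n))
        offsets = layout.atom_offsets(geometry)
        # on-site
        for a, el in enumerate(geometry.symbols):
            pos = int(offsets[a])
            for s, (_, l) in enumerate(layout.shells(el)):
                e0 = self.onsite[(el, s)]
                for k in range(2 * l + 1):
                    H[pos + k, pos + k] = e0
                pos += 2 * l + 1
        # two-center hoppings; real-p component order (m=-1,0,1) = (y, z, x)
        coords = geometry.coordinates
        for i in range(geometry.n_atoms):
            for j in range(i + 1, geometry.n_atoms):
                rij = coords[j] - coords[i]
                r = np.linalg.norm(rij)
                nv = rij / r
                n_real = np.array([nv[1], nv[2], nv[0]])  # (y, z, x)
                eli, elj = geometry.symbols[i], geometry.symbols[j]
                soff_i = layout.shell_offsets(eli)
                soff_j = layout.shell_offsets(elj)
                for si, (_, li) in enumerate(layout.shells(eli)):
                    for sj, (_, lj) in enumerate(layout.shells(elj)):
                        if (eli, si) == ("C", 0) or (elj, sj) == ("C", 0):
                            continue  # frozen core: no hopping
                        oi = offsets[i] + soff_i[si]
                        oj = offsets[j] + soff_j[sj]
                        if li == 0 and lj == 0:
                            blk = np.array([[self._v(eli, si, elj, sj, "sigma", r)]])
                        elif li == 0 and lj == 1:
                            vsp = self._v(eli, si, elj, sj, "sigma", r)
                            blk = vsp * n_real[None, :]
                        elif li == 1 and lj == 0:
                            vsp = self._v(elj, sj, eli, si, "sigma", r)
                            blk = -vsp * n_real[:, None]  # p lobe toward j
                        else:
                            # Slater-Koster p-p block, Harrison sign convention
                            # (V_ppsigma > 0, V_pppi < 0)
                            vs = self._v(eli, si, elj, sj, "sigma", r)
                            vp = self._v(eli, si, elj, sj, "pi", r)
                            P = np.outer(n_real, n_real)
                            blk = vs * P + vp * (np.eye(3) - P)
                        H[oi:oi + blk.shape[0], oj:oj + blk.shape[1]] = blk
                        H[oj:oj + blk.shape[1], oi:oi + blk.shape[0]] = blk.T
        return H


# ---------------------------------------------------------------------------
# targets


def project_teacher(teacher: TeacherModel, structures, svd_floor: float = 1e-2
                    ) -> TeacherModel:
    """Project teacher weights onto the identifiable subspace of a design.

    The linear feature map has gauge directions (channel combinations whose
    output vanishes on every structure of a family), so weights are only
    identifiable modulo that null space.  This keeps, per block family, the
    singular directions of the stacked design with s >= svd_floor * s_max,
    making teacher-weight recovery a well-posed oracle; the projected teacher
    generates identical targets on data within the family's span.
    """
    from .training import PreparedStructure, _feature_array, prepare_structures
    if structures and not isinstance(structures[0], PreparedStructure):
        structures = prepare_structures(structures, teacher.spec, teacher.layout,
                                        teacher.species, teacher.lam_max)
    new = {}
    for key, w in teacher.weights.weights.items():
        Xs = []
        for ps in structures:
            F = _feature_array(ps, teacher.layout, key)
            if F is not None and F.shape[0]:
                Xs.append(F.transpose(0, 2, 1).reshape(-1, F.shape[1]))
        if not Xs:
            new[key] = np.zeros_like(w)
            continue
        X = np.vstack(Xs)
        _, s, Vt = np.linalg.svd(X, full_matrices=False)
        keep = Vt[s >= svd_floor * s[0]]
        new[key] = keep.T @ (keep @ w)
    return TeacherModel(ModelWeights(new), teacher.spec, teacher.layout,
                        teacher.species, teacher.lam_max)


def teacher_targets(structures, teacher: TeacherModel, kind: str):
    """Run the teacher forward (features -> blocks -> H -> MOs -> charges) and
    package the requested target kind; ground-truth weights stay on the teacher."""
    from .properties import loewdin_charges, solve_mos
    from .training import (PreparedStructure, TrainingTarget, _forward_matrix,
                           prepare_structures)
    if structures and not isinstance(structures[0], PreparedStructure):
        structures = prepare_structures(structures, teacher.spec, teacher.layout,
                                        teacher.species, teacher.lam_max)
    hams, eigs, chgs = [], [], []
    for ps in structures:
        H = _forward_matrix(ps, teacher.layout, teacher.weights)
        hams.append(H)
        if kind != "hamiltonian":
            sol = solve_mos(H, ps.n_electrons)
            eigs.append(sol.energies)
            chgs.append(loewdin_charges(sol, ps.geometry, teacher.layout).q)
    if kind == "hamiltonian":
        return TrainingTarget(kind, hamiltonians=hams)
    if kind == "eigenvalues":
        return TrainingTarget(kind, eigenvalues=eigs)
    return TrainingTarget(kind, eigenvalues=eigs, charges=chgs)


def toy_reference_targets(geometries, reference: ToyReference,
                          layout: BasisLayout | None = None,
                          include_hamiltonians: bool = False,
                          kind: str = "eigenvalues_and_charges"):
    """Eigenvalues and Löwdin charges (optionally the matrices) of the
    tight-binding reference — targets *outside* the linear model class."""
    from .properties import loewdin_charges, solve_mos
    from .training import TrainingTarget
    layout = layout or minimal_layout()
    hams, eigs, chgs = [], [], []
    for geo in geometries:
        H = reference.hamiltonian(geo, layout)
        hams.append(H)
        sol = solve_mos(H, geo.n_electrons)
        eigs.append(sol.energies)
        chgs.append(loewdin_charges(sol, geo, layout).q)
    return TrainingTarget(kind,
                          hamiltonians=hams if include_hamiltonians else None,
                          eigenvalues=eigs,
                          charges=chgs if kind == "eigenvalues_and_charges" else None)


# ---------------------------------------------------------------------------
# energy trajectories


@dataclass
class EnergyTrajectory:
    """Uniformly sampled excitation-energy time series."""

    times: np.ndarray        # fs
    energies: np.ndarray     # eV
    temperature: float = 300.0  # K

    def __post_init__(self):
        if self.times.size < 2:
            raise ValueError("trajectory needs at least 2 frames")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("non-uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def make_energy_trajectory(modes, n_steps: int, dt: float, temperature: float,
                           seed: int, mean_energy: float = 3.0,
                           ou_tau: float | None = None) -> EnergyTrajectory:
    """U(t) = mean + sum_k A_k cos(w_k t + phi_k) with seeded random phases;
    with ``ou_tau`` (fs) an Ornstein-Uhlenbeck background of unit-variance
    times the first amplitude is used instead of the cosines.

    ``modes`` is a list of (frequency cm^-1, amplitude eV); the analytic
    fluctuation autocorrelation of the cosine form is sum_k A_k^2 cos(w_k t)/2.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_steps) * dt
    u = np.full(n_steps, float(mean_energy))
    if ou_tau is not None:
        amp = modes[0][1] if modes else 1.0
        x = 0.0
        a = np.exp(-dt / ou_tau)
        b = np.sqrt(1 - a * a)
        xs = np.empty(n_steps)
        for k in range(n_steps):
            x = a * x + b * rng.normal()
            xs[k] = x
        u += amp * xs
    else:
        for freq_cm, amp in modes:
            w = freq_cm / EV_CM / HBAR_EV_FS  # rad/fs
            phi = rng.uniform(0, 2 * np.pi)
            u += amp * np.cos(w * t + phi)
    return EnergyTrajectory(t, u, temperature)
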