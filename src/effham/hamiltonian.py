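"""Irreducible-representation algebra for Hamiltonian pair blocks, the linear
feature -> block map, and assembly of the full symmetric matrix.

A pair block between shells with angular momenta (l, l') decomposes into
spherical-tensor components of orders lam = |l-l'|..l+l' through the real
Clebsch-Gordan tables; the transform is orthogonal (Parseval to 1e-12).  The
linear model carries one invariant weight vector per

    (species pair, shell pair, tau, lam)

acting on the feature channels with matching (tau, lam) and O(3) parity.  For
like-element pairs the i<->j symmetric/antisymmetric target combinations are
regressed on the tau=+1/-1 feature channels; the transpose block is never
modeled independently, so the assembled matrix is exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisLayout
from .constants import ATOMIC_NUMBERS
from .features import SQRT2, TwoCenterFeatures
from .geometry import MolecularGeometry, PairList, neighbor_pairs
from .rotations import cg_real, cg_swap_sign


# ---------------------------------------------------------------------------
# plain irrep transform for a single (l, l') sub-block


def block_to_irreps(block: np.ndarray, l1: int, l2: int) -> dict[int, np.ndarray]:
    """Decompose a (2l1+1, 2l2+1) sub-block into components T[lam] (2lam+1,)."""
    if block.shape != (2 * l1 + 1, 2 * l2 + 1):
        raise ValueError(f"block shape {block.shape} mismatches l=({l1},{l2})")
    return {lam: np.einsum("xyu,xy->u", cg_real(l1, l2, lam), block)
            for lam in range(abs(l1 - l2), l1 + l2 + 1)}


def irreps_to_block(irreps: dict[int, np.ndarray], l1: int, l2: int) -> np.ndarray:
    """Inverse of :func:`block_to_irreps` (orthogonal transform)."""
    block = np.zeros((2 * l1 + 1, 2 * l2 + 1))
    for lam in range(abs(l1 - l2), l1 + l2 + 1):
        if lam not in irreps:
            raise KeyError(f"missing lam={lam} channel for (l1,l2)=({l1},{l2})")
        block += np.einsum("xyu,u->xy", cg_real(l1, l2, lam), irreps[lam])
    return block


def decompose_to_irreps(block_matrix: np.ndarray, shells1, shells2) -> dict:
    """Decompose a full per-pair orbital sub-matrix into irrep components.

    Returns {(a, b, lam): vector} over shell pairs; exact linear change of
    basis (sum of squares preserved).
    """
    out = {}
    off1 = np.cumsum([0] + [2 * l + 1 for _, l in shells1])
    off2 = np.cumsum([0] + [2 * l + 1 for _, l in shells2])
    if block_matrix.shape != (off1[-1], off2[-1]):
        raise ValueError(f"sub-matrix shape {block_matrix.shape} mismatches shells")
    for a, (_, la) in enumerate(shells1):
        for b, (_, lb) in enumerate(shells2):
            sub = block_matrix[off1[a]:off1[a + 1], off2[b]:off2[b + 1]]
            for lam, v in block_to_irreps(sub, la, lb).items():
                out[(a, b, lam)] = v
    return out


def recompose_from_irreps(irreps: dict, shells1, shells2) -> np.ndarray:
    """Inverse of :func:`decompose_to_irreps`."""
    off1 = np.cumsum([0] + [2 * l + 1 for _, l in shells1])
    off2 = np.cumsum([0] + [2 * l + 1 for _, l in shells2])
    out = np.zeros((off1[-1], off2[-1]))
    for a, (_, la) in enumerate(shells1):
        for b, (_, lb) in enumerate(shells2):
            comp = {lam: irreps[(a, b, lam)]
                    for lam in range(abs(la - lb), la + lb + 1)}
            out[off1[a]:off1[a + 1], off2[b]:off2[b + 1]] = \
                irreps_to_block(comp, la, lb)
    return out


# ---------------------------------------------------------------------------
# model block labels


@dataclass(frozen=True)
class BlockKey:
    """Label of one independently-modeled irrep family.

    kind 'off': species pair (higher Z first), canonical shell pair (a, b)
    (a <= b for like elements), permutation channel tau (±1 like / 0 unlike).
    kind 'on': single element, shell pair a <= b.
    """

    kind: str                  # "off" | "on"
    species: tuple[str, ...]   # (el1, el2) or (el,)
    a: int
    b: int
    tau: int
    lam: int


def _sigma_of(layout: BasisLayout, key: BlockKey) -> int:
    el1 = key.species[0]
    el2 = key.species[-1]
    la = layout.shells(el1)[key.a][1]
    lb = layout.shells(el2)[key.b][1]
    return (-1) ** (la + lb + key.lam)


def model_block_keys(layout: BasisLayout, species: tuple[str, ...],
                     lam_max: int = 2) -> list[BlockKey]:
    """All irrep families a model must carry for the given layout/species."""
    keys = []
    # on-site
    for el in species:
        shells = layout.shells(el)
        for a, (_, la) in enumerate(shells):
            for b, (_, lb) in enumerate(shells):
                if a > b:
                    continue
                for lam in range(abs(la - lb), min(la + lb, lam_max) + 1):
                    if a == b and (-1) ** (la + lb - lam) == -1:
                        continue  # symmetric diagonal sub-block: odd part vanishes
                    keys.append(BlockKey("on", (el,), a, b, 0, lam))
    # off-site
    for i1, el1 in enumerate(species):
        for el2 in species[i1:]:
            pair = ((el1, el2) if ATOMIC_NUMBERS[el1] >= ATOMIC_NUMBERS[el2]
                    else (el2, el1))
            s1, s2 = layout.shells(pair[0]), layout.shells(pair[1])
            same = pair[0] == pair[1]
            for a, (_, la) in enumerate(s1):
                for b, (_, lb) in enumerate(s2):
                    if same and a > b:
                        continue
                    for lam in range(abs(la - lb), min(la + lb, lam_max) + 1):
                        if same:
                            s = cg_swap_sign(la, lb, lam)
                            if a == b:
                                keys.append(BlockKey("off", pair, a, b, int(s), lam))
                            else:
                                keys.append(BlockKey("off", pair, a, b, +1, lam))
                                keys.append(BlockKey("off", pair, a, b, -1, lam))
                        else:
                            keys.append(BlockKey("off", pair, a, b, 0, lam))
    return keys


def feature_key(layout: BasisLayout, key: BlockKey):
    """Feature-store key whose channels feed this block family."""
    sig = _sigma_of(layout, key)
    if key.kind == "on":
        return (key.species[0], key.lam, sig)
    return ((key.species[0], key.species[1]), key.tau, key.lam, sig)


# ---------------------------------------------------------------------------
# weights and prediction


@dataclass
class ModelWeights:
    """Invariant weights w^{p,tau,lam}: one vector over feature channels per
    block family; intercepts are fixed to zero."""

    weights: dict[BlockKey, np.ndarray]

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.weights[k] for k in sorted(self.weights,
                               key=lambda k: repr(k))])

    def from_vector(self, vec: np.ndarray) -> "ModelWeights":
        out, pos = {}, 0
        for k in sorted(self.weights, key=lambda k: repr(k)):
            n = self.weights[k].size
            out[k] = vec[pos:pos + n].copy()
            pos += n
        if pos != vec.size:
            raise ValueError("weight vector length mismatch")
        return ModelWeights(out)

    @staticmethod
    def zeros(layout: BasisLayout, spec, species: tuple[str, ...],
              lam_max: int = 2) -> "ModelWeights":
        from .features import offsite_channel_count, onsite_channel_count
        w = {}
        n_sp = len(species)
        for key in model_block_keys(layout, species, lam_max):
            sig = _sigma_of(layout, key)
            if key.kind == "on":
                n = onsite_channel_count(spec, n_sp, key.lam, sig)
            else:
                n = offsite_channel_count(spec, n_sp, key.lam, sig, key.tau)
            w[key] = np.zeros(n)
        return ModelWeights(w)


@dataclass
class IrrepBlocks:
    """Predicted (or target) irrep components per block family.

    values[key] has shape (n_rows, 2*lam+1); rows follow the feature row order
    (``pair_rows`` for off-site families, ``atom_rows`` on-site).
    """

    values: dict[BlockKey, np.ndarray]
    pair_rows: dict
    atom_rows: dict


def predict_blocks(feats: TwoCenterFeatures, weights: ModelWeights,
                   layout: BasisLayout) -> IrrepBlocks:
    """Linear map H_ij^{p,tau,lam,mu} = sum_q w_q^{p,tau,lam} xi_q^{tau,lam,mu}."""
    vals = {}
    for key, w in weights.weights.items():
        fk = feature_key(layout, key)
        store = feats.onsite if key.kind == "on" else feats.offsite
        arr = store.get(fk)
        if arr is None:
            vals[key] = np.zeros((0, 2 * key.lam + 1))
            continue
        if arr.shape[1] != w.size:
            raise ValueError(f"channel mismatch for {key}: "
                             f"{arr.shape[1]} features vs {w.size} weights")
        vals[key] = np.einsum("rqm,q->rm", arr, w)
    return IrrepBlocks(vals, dict(feats.pair_rows), dict(feats.atom_rows))


# ---------------------------------------------------------------------------
# assembly


@dataclass
class EffectiveHamiltonian:
    """Dense real symmetric effective Hamiltonian (Hartree) plus the per-pair
    sub-matrices it was assembled from."""

    matrix: np.ndarray
    pair_blocks: dict[tuple[int, int], np.ndarray]
    geometry: MolecularGeometry
    layout: BasisLayout


def _family_tensors(layout: BasisLayout, el1: str, el2: str, key: BlockKey):
    la = layout.shells(el1)[key.a][1]
    lb = layout.shells(el2)[key.b][1]
    return la, lb, cg_real(la, lb, key.lam)


def assemble_hamiltonian(irreps: IrrepBlocks, geometry: MolecularGeometry,
                         layout: BasisLayout) -> EffectiveHamiltonian:
    """Assemble the symmetric matrix; (j, i) blocks are transposes of (i, j),
    pairs beyond the cutoff are exactly zero."""
    n = layout.n_orbitals(geometry)
    H = np.zeros((n, n))
    offsets = layout.atom_offsets(geometry)
    blocks: dict[tuple[int, int], np.ndarray] = {}

    def add(i, j, a, b, la, lb, contrib):
        el_i = geometry.symbols[i]
        el_j = geometry.symbols[j]
        oa = offsets[i] + layout.shell_offsets(el_i)[a]
        ob = offsets[j] + layout.shell_offsets(el_j)[b]
        H[oa:oa + 2 * la + 1, ob:ob + 2 * lb + 1] += contrib
        blk = blocks.setdefault((i, j), np.zeros((layout.orbitals_per_element(el_i),
                                                  layout.orbitals_per_element(el_j))))
        sa = oa - offsets[i]
        sb = ob - offsets[j]
        blk[sa:sa + 2 * la + 1, sb:sb + 2 * lb + 1] += contrib

    for key, T in irreps.values.items():
        if key.kind == "on":
            el = key.species[0]
            rows = irreps.atom_rows.get(el, [])
            la, lb, K = _family_tensors(layout, el, el, key)
            for r, atom in enumerate(rows):
                sub = np.einsum("xyu,u->xy", K, T[r])
                add(atom, atom, key.a, key.b, la, lb, sub)
                if key.a != key.b:
                    add(atom, atom, key.b, key.a, lb, la, sub.T)
        else:
            el1, el2 = key.species
            rows = irreps.pair_rows.get((el1, el2), [])
            la, lb, K = _family_tensors(layout, el1, el2, key)
            same = el1 == el2
            s = cg_swap_sign(la, lb, key.lam) if same else None
            for r, (i, j) in enumerate(rows):
                if same:
                    if key.a == key.b:
                        Tab = T[r] / SQRT2
                        sub = np.einsum("xyu,u->xy", K, Tab)
                        add(i, j, key.a, key.b, la, lb, sub)
                        add(j, i, key.b, key.a, lb, la, sub.T)
                    else:
                        # this family carries one tau component; its partner
                        # family fills the complementary combination
                        Tab = T[r] / SQRT2
                        Tba = key.tau * s * T[r] / SQRT2
                        sub = np.einsum("xyu,u->xy", K, Tab)
                        add(i, j, key.a, key.b, la, lb, sub)
                        add(j, i, key.b, key.a, lb, la, sub.T)
                        Kba = cg_real(lb, la, key.lam)
                        sub2 = np.einsum("xyu,u->xy", Kba, Tba)
                        add(i, j, key.b, key.a, lb, la, sub2)
                        add(j, i, key.a, key.b, la, lb, sub2.T)
                else:
                    sub = np.einsum("xyu,u->xy", K, T[r])
                    add(i, j, key.a, key.b, la, lb, sub)
                    add(j, i, key.b, key.a, lb, la, sub.T)

    asym = np.abs(H - H.T).max()
    if asym > 1e-10:
        raise RuntimeError(f"assembled Hamiltonian asymmetric by {asym:.2e}")
    return EffectiveHamiltonian(H, blocks, geometry, layout)


def decompose_targets(H: np.ndarray, geometry: MolecularGeometry,
                      layout: BasisLayout, feats: TwoCenterFeatures,
                      lam_max: int = 2) -> IrrepBlocks:
    """Project a reference symmetric Hamiltonian onto the modeled irrep
    families (exact right-inverse of prediction+assembly for realizable H)."""
    offsets = layout.atom_offsets(geometry)

    def sub(i, j, a, b, la, lb):
        oa = offsets[i] + layout.shell_offsets(geometry.symbols[i])[a]
        ob = offsets[j] + layout.shell_offsets(geometry.symbols[j])[b]
        return H[oa:oa + 2 * la + 1, ob:ob + 2 * lb + 1]

    vals = {}
    for key in model_block_keys(layout, feats.species, lam_max):
        if key.kind == "on":
            el = key.species[0]
            rows = feats.atom_rows.get(el, [])
            la, lb, K = _family_tensors(layout, el, el, key)
            T = np.empty((len(rows), 2 * key.lam + 1))
            for r, atom in enumerate(rows):
                T[r] = np.einsum("xyu,xy->u", K, sub(atom, atom, key.a, key.b, la, lb))
            vals[key] = T
        else:
            el1, el2 = key.species
            rows = feats.pair_rows.get((el1, el2), [])
            la, lb, K = _family_tensors(layout, el1, el2, key)
            same = el1 == el2
            T = np.empty((len(rows), 2 * key.lam + 1))
            for r, (i, j) in enumerate(rows):
                Tab = np.einsum("xyu,xy->u", K, sub(i, j, key.a, key.b, la, lb))
                if same:
                    if key.a == key.b:
                        T[r] = SQRT2 * Tab
                    else:
                        s = cg_swap_sign(la, lb, key.lam)
                        Kba = cg_real(lb, la, key.lam)
                        Tba = np.einsum("xyu,xy->u", Kba,
                                        sub(i, j, key.b, key.a, lb, la))
                        T[r] = (Tab + key.tau * s * Tba) / SQRT2
                else:
                    T[r] = Tab
            vals[key] = T
    return IrrepBlocks(vals, dict(feats.pair_rows), dict(feats.atom_rows))


def lowdin_orthogonalize(hamiltonian: np.ndarray, overlap: np.ndarray) -> np.ndarray:
    """Löwdin-symmetrized matrix S^{-1/2} H S^{-1/2}."""
    w, V = np.linalg.eigh(np.asarray(overlap, dtype=float))
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            f"overlap not positive-definite (smallest eigenvalue {w.min():.3e})")
    S_inv_half = (V / np.sqrt(w)) @ V.T
    out = S_inv_half @ np.asarray(hamiltonian, dtype=float) @ S_inv_half
    return 0.5 * (out + out.T)


def predict_hamiltonian(geometry: MolecularGeometry, weights: ModelWeights,
                        layout: BasisLayout, spec, species=None,
                        lam_max: int = 2) -> EffectiveHamiltonian:
    """Features -> irrep blocks -> assembled matrix for one geometry."""
    from .features import compute_features, default_species_order
    if species is None:
        species = default_species_order(layout)
    pairs = neighbor_pairs(geometry, spec.cutoff)
    feats = compute_features(geometry, pairs, spec, species, lam_max)
    irr = predict_blocks(feats, weights, layout)
    return assemble_hamiltonian(irr, geometry, layout)
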