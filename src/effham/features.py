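"""Two-center, one-neighbor symmetry-adapted descriptors.

The descriptors are built from pair-density coefficients

    c_nlm(A_ij) = R_n(|r_ij|) * f_cut(|r_ij|) * Y_lm(r_hat_ij)

with Gaussian radial functions centered on a uniform grid inside the cutoff
and real spherical harmonics.  Summing over neighbors gives the
species-resolved neighbor density c_nlm(A_i); Clebsch-Gordan coupling of the
neighbor density with the pair density yields equivariant pair features
xi^{tau,lam,mu}(A_ij) of order lam, and coupling the neighbor density with
itself yields the on-site (i, i) features.  Channels carry a parity label
sigma = (-1)^(l+l'+lam) so that each Hamiltonian irrep component is regressed
only on features with its own O(3) behavior.

For pairs of like elements the i<->j permutation is enforced exactly by
splitting channels into symmetric (tau=+1) and antisymmetric (tau=-1)
combinations; unlike-element pairs are keyed by the ordered species pair
(higher atomic number first, tau=0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_NUMBERS
from .geometry import MolecularGeometry, PairList
from .rotations import cg_real, real_sph_harm

SQRT2 = np.sqrt(2.0)


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RadialBasisSpec:
    """Radial/angular discretization of the pair density.

    n_max Gaussian radial functions sit on a uniform grid of centers
    r_n = n*cutoff/(n_max+1), n = 1..n_max; their width combines half the grid
    spacing with the atomic smearing ``gaussian_width`` (Å).  A cosine-squared
    taper over the outer ``taper_width`` Å makes every coefficient go to zero
    continuously at the cutoff.
    """

    n_max: int = 6
    l_max: int = 4
    gaussian_width: float = 0.2
    cutoff: float = 4.5
    taper_width: float = 0.5

    def __post_init__(self):
        if self.n_max < 1 or self.l_max < 0 or self.cutoff <= 0:
            raise ValueError("invalid radial basis spec")

    @property
    def centers(self) -> np.ndarray:
        step = self.cutoff / (self.n_max + 1)
        return step * np.arange(1, self.n_max + 1)

    @property
    def width(self) -> float:
        step = self.cutoff / (self.n_max + 1)
        return float(np.hypot(0.5 * step, self.gaussian_width))

    def radial(self, r: np.ndarray) -> np.ndarray:
        """R_n(r), shape (..., n_max)."""
        r = np.asarray(r, dtype=float)[..., None]
        return np.exp(-0.5 * ((r - self.centers) / self.width) ** 2)

    def taper(self, r: np.ndarray) -> np.ndarray:
        """C^1 cutoff switch: 1 inside, cos^2 ramp over the outer taper_width."""
        r = np.asarray(r, dtype=float)
        inner = self.cutoff - self.taper_width
        x = np.clip((r - inner) / self.taper_width, 0.0, 1.0)
        return np.where(r > self.cutoff, 0.0, np.cos(0.5 * np.pi * x) ** 2)


@dataclass
class PairDensity:
    """c_nlm(A_ij) for each off-site pair in the i->j direction.

    coefficients[l] has shape (n_offsite, n_max, 2l+1); the reversed direction
    follows from parity: c_nlm(A_ji) = (-1)^l c_nlm(A_ij).
    """

    coefficients: dict[int, np.ndarray]
    spec: RadialBasisSpec


@dataclass
class NeighborDensity:
    """Species-resolved neighbor density c_nlm(A_i).

    coefficients[l] has shape (n_atoms, n_species, n_max, 2l+1); ``species``
    fixes the neighbor-species channel order.
    """

    coefficients: dict[int, np.ndarray]
    species: tuple[str, ...]
    spec: RadialBasisSpec


def pair_density(geometry: MolecularGeometry, pairs: PairList,
                 spec: RadialBasisSpec) -> PairDensity:
    """Pair-density coefficients for every off-site pair (i->j direction)."""
    offsite = pairs.offsite
    coords = geometry.coordinates
    n_off = len(offsite)
    out = {l: np.zeros((n_off, spec.n_max, 2 * l + 1)) for l in range(spec.l_max + 1)}
    if n_off:
        rij = np.array([coords[j] - coords[i] for i, j in offsite])
        r = np.linalg.norm(rij, axis=1)
        if np.any(r < 1e-8):
            k = int(np.argmin(r))
            raise DegenerateGeometryError(
                f"atoms {offsite[k]} are coincident (separation {r[k]:.2e} Å)")
        rad = spec.radial(r) * spec.taper(r)[:, None]  # (n_off, n_max)
        rhat = rij / r[:, None]
        for l in range(spec.l_max + 1):
            Y = real_sph_harm(l, rhat)  # (n_off, 2l+1)
            out[l] = rad[:, :, None] * Y[:, None, :]
    return PairDensity(out, spec)


def neighbor_density(pair_dens: PairDensity, pairs: PairList,
                     geometry: MolecularGeometry,
                     species: tuple[str, ...]) -> NeighborDensity:
    """Per-center, per-neighbor-species sums of pair coefficients."""
    spec = pair_dens.spec
    n_at = geometry.n_atoms
    s_index = {s: k for k, s in enumerate(species)}
    out = {l: np.zeros((n_at, len(species), spec.n_max, 2 * l + 1))
           for l in range(spec.l_max + 1)}
    for k, (i, j) in enumerate(pairs.offsite):
        si, sj = s_index[geometry.symbols[i]], s_index[geometry.symbols[j]]
        for l in range(spec.l_max + 1):
            c = pair_dens.coefficients[l][k]
            out[l][i, sj] += c                      # j seen from i
            out[l][j, si] += (-1.0) ** l * c        # i seen from j
    return NeighborDensity(out, species, spec)


def _coupling_triples(l_max: int, lam: int, sig: int):
    """(l', l) pairs whose coupling produces order lam with parity sig."""
    out = []
    for lp in range(l_max + 1):
        for l in range(l_max + 1):
            if abs(lp - l) <= lam <= lp + l and (-1) ** (lp + l + lam) == sig:
                out.append((lp, l))
    return out


def offsite_channel_count(spec: RadialBasisSpec, n_species: int, lam: int,
                          sig: int, tau: int) -> int:
    """Number of feature channels for an off-site (tau, lam, sig) family.

    tau = ±1: like-element pair (one center-combination per coupled channel;
    pure pair channels only in the tau = (-1)^lam class).  tau = 0:
    unlike-element pair (coupled channels for both centers).
    """
    n_coupled = len(_coupling_triples(spec.l_max, lam, sig)) * n_species * spec.n_max ** 2
    n_pair = spec.n_max if (sig == 1 and lam <= spec.l_max) else 0
    if tau == 0:
        return n_pair + 2 * n_coupled
    return n_coupled + (n_pair if tau == (-1) ** lam else 0)


def onsite_channel_count(spec: RadialBasisSpec, n_species: int, lam: int,
                         sig: int) -> int:
    """Number of on-site channels: constant (lam=0 only) plus ordered
    density (x) density couplings."""
    nf = n_species * spec.n_max
    count = 1 if (lam == 0 and sig == 1) else 0
    for lp, l in _coupling_triples(spec.l_max, lam, sig):
        if lp > l:
            continue
        if lp == l:
            count += nf * (nf + 1) // 2 if lam % 2 == 0 else nf * (nf - 1) // 2
        else:
            count += nf * nf
    return count


def default_species_order(layout_or_symbols) -> tuple[str, ...]:
    """Element channel order: descending atomic number."""
    if hasattr(layout_or_symbols, "shells_per_element"):
        syms = layout_or_symbols.shells_per_element.keys()
    else:
        syms = set(layout_or_symbols)
    return tuple(sorted(syms, key=lambda s: -ATOMIC_NUMBERS[s]))


@dataclass
class TwoCenterFeatures:
    """Symmetry-adapted features for one structure.

    ``offsite[(sp_pair, tau, lam, sig)]`` -> (n_pairs_of_kind, n_chan, 2lam+1)
    ``onsite[(element, lam, sig)]``       -> (n_atoms_of_element, n_chan, 2lam+1)

    sp_pair is an ordered species pair (higher Z first); tau is +1/-1 for the
    i<->j symmetric/antisymmetric channels of like-element pairs and 0 for
    unlike pairs.  Row order follows ``pair_rows`` / ``atom_rows``.
    """

    spec: RadialBasisSpec
    species: tuple[str, ...]
    offsite: dict = field(default_factory=dict)
    onsite: dict = field(default_factory=dict)
    pair_rows: dict = field(default_factory=dict)   # sp_pair -> [(i, j) canonical]
    atom_rows: dict = field(default_factory=dict)   # element -> [atom index]
    channel_meta: dict = field(default_factory=dict)

    def n_channels(self, key) -> int:
        store = self.offsite if len(key) == 4 else self.onsite
        return store[key].shape[1]


def couple_features(neighbor: NeighborDensity, pair_dens: PairDensity,
                    pairs: PairList, geometry: MolecularGeometry,
                    lam_max: int = 2):
    """Raw (unsymmetrized) per-direction pair features and on-site features.

    Returns ``(directed, onsite_raw, meta)`` where ``directed[(lam, sig)]`` is
    an array (n_offsite, 2, n_chan, 2lam+1) — axis 1 is the expansion center
    (0: atom i, 1: atom j) — whose channels are the pure pair channels
    followed by the neighbor-density (x) pair-density coupled channels, and
    ``onsite_raw[(lam, sig)]`` is (n_atoms, n_chan, 2lam+1) from coupling the
    neighbor density with itself (plus a constant lam=0 channel).
    """
    spec = pair_dens.spec
    n_off = len(pairs.offsite)
    n_at = geometry.n_atoms
    n_sp = len(neighbor.species)
    nmax = spec.n_max
    directed = {}
    onsite_raw = {}
    meta = {"offsite": {}, "onsite": {}}

    # density flattened per l for on-site coupling: (n_at, n_sp*nmax, 2l+1)
    dens = {l: neighbor.coefficients[l].reshape(n_at, n_sp * nmax, 2 * l + 1)
            for l in range(spec.l_max + 1)}

    for lam in range(lam_max + 1):
        for sig in (+1, -1):
            chunks_dir = []
            meta_dir = []
            # pure pair channels: l = lam, even parity class
            if sig == 1 and lam <= spec.l_max:
                c = pair_dens.coefficients[lam]  # (n_off, nmax, 2lam+1)
                both = np.stack([c, (-1.0) ** lam * c], axis=1)
                chunks_dir.append(both)
                meta_dir.extend([("pair", n) for n in range(nmax)])
            # coupled channels: density (l') x pair (l) -> lam
            for lp, l in _coupling_triples(spec.l_max, lam, sig):
                K = cg_real(lp, l, lam)
                d = neighbor.coefficients[lp]          # (n_at, n_sp, nmax, 2lp+1)
                c = pair_dens.coefficients[l]          # (n_off, nmax, 2l+1)
                if n_off:
                    idx_i = np.array([i for i, j in pairs.offsite])
                    idx_j = np.array([j for i, j in pairs.offsite])
                    di = d[idx_i]                      # (n_off, n_sp, nmax, 2lp+1)
                    dj = d[idx_j]
                    cji = (-1.0) ** l * c
                    fi = np.einsum("kspx,kny,xyu->kspnu", di, c, K)
                    fj = np.einsum("kspx,kny,xyu->kspnu", dj, cji, K)
                    f = np.stack([fi, fj], axis=1).reshape(
                        n_off, 2, n_sp * nmax * nmax, 2 * lam + 1)
                else:
                    f = np.zeros((0, 2, n_sp * nmax * nmax, 2 * lam + 1))
                chunks_dir.append(f)
                meta_dir.extend([("coupled", s, npr, lp, n, l)
                                 for s in neighbor.species
                                 for npr in range(nmax) for n in range(nmax)])
            if chunks_dir:
                directed[(lam, sig)] = (np.concatenate(chunks_dir, axis=2)
                                        if n_off else
                                        np.zeros((0, 2, len(meta_dir), 2 * lam + 1)))
                meta["offsite"][(lam, sig)] = meta_dir

            # on-site: density (x) density, ordered channel pairs
            chunks_on = []
            meta_on = []
            if lam == 0 and sig == 1:
                chunks_on.append(np.ones((n_at, 1, 1)))
                meta_on.append(("const",))
            for lp, l in _coupling_triples(spec.l_max, lam, sig):
                if lp > l:
                    continue  # unordered factor pairs: keep lp <= l only
                K = cg_real(lp, l, lam)
                f = np.einsum("apx,aqy,xyu->apqu", dens[lp], dens[l], K)
                nf = n_sp * nmax
                if lp == l:
                    iu, ju = np.triu_indices(nf, k=0 if (lam % 2 == 0) else 1)
                    f = f[:, iu, ju, :]
                    meta_on.extend([("dd", lp, int(a), l, int(b)) for a, b in zip(iu, ju)])
                else:
                    f = f.reshape(n_at, nf * nf, 2 * lam + 1)
                    meta_on.extend([("dd", lp, a, l, b)
                                    for a in range(nf) for b in range(nf)])
                chunks_on.append(f)
            if chunks_on:
                onsite_raw[(lam, sig)] = np.concatenate(chunks_on, axis=1)
                meta["onsite"][(lam, sig)] = meta_on
    return directed, onsite_raw, meta


def symmetrize_pair_channels(directed, onsite_raw, meta, pairs: PairList,
                             geometry: MolecularGeometry,
                             spec: RadialBasisSpec,
                             species: tuple[str, ...]) -> TwoCenterFeatures:
    """Enforce i<->j permutation symmetry and group rows by species pair.

    Like-element pairs: channels are replaced by (xi_i ± xi_j)/sqrt(2) keyed
    tau=±1; the pure pair channels carry a definite permutation character
    ((-1)^lam) and are assigned wholly to that tau with weight sqrt(2).
    Unlike-element pairs pass through in the canonical orientation (higher-Z
    atom first), tau=0, with both centers' coupled channels as channels.
    """
    feats = TwoCenterFeatures(spec=spec, species=species, channel_meta=meta)
    offsite = pairs.offsite
    symbols = geometry.symbols

    # group off-site pairs by species-pair key with canonical orientation
    groups: dict[tuple[str, str], list] = {}
    for k, (i, j) in enumerate(offsite):
        si, sj = symbols[i], symbols[j]
        if ATOMIC_NUMBERS[si] >= ATOMIC_NUMBERS[sj]:
            key, flip, row = (si, sj), False, (i, j)
        else:
            key, flip, row = (sj, si), True, (j, i)
        groups.setdefault(key, []).append((k, row, flip))

    for key, rows in groups.items():
        same = key[0] == key[1]
        feats.pair_rows[key] = [r[1] for r in rows]
        kidx = np.array([r[0] for r in rows])
        flips = np.array([r[2] for r in rows])
        for (lam, sig), arr in directed.items():
            md = meta["offsite"][(lam, sig)]
            is_pair = np.array([m[0] == "pair" for m in md])
            a = arr[kidx]  # (rows, 2, n_chan, 2lam+1)
            if same:
                xi_i, xi_j = a[:, 0], a[:, 1]
                sym = (xi_i + xi_j) / SQRT2
                anti = (xi_i - xi_j) / SQRT2
                # pair channels: definite character (-1)^lam, weight sqrt(2)*xi
                tau_pair = (-1) ** lam
                plus = sym if tau_pair > 0 else sym[:, ~is_pair]
                minus = anti if tau_pair < 0 else anti[:, ~is_pair]
                feats.offsite[(key, +1, lam, sig)] = plus
                feats.offsite[(key, -1, lam, sig)] = minus
            else:
                # canonical orientation: center 0 must be the higher-Z atom
                ordered = np.where(flips[:, None, None, None],
                                   a[:, ::-1], a)
                out = np.concatenate([ordered[:, 0], ordered[:, 1, ~is_pair]], axis=1)
                # reversed-direction pure pair channels are (-1)^lam multiples
                # of the forward ones and are dropped as redundant
                feats.offsite[(key, 0, lam, sig)] = out

    for el in species:
        rows = [a for a, s in enumerate(symbols) if s == el]
        feats.atom_rows[el] = rows
        for (lam, sig), arr in onsite_raw.items():
            feats.onsite[(el, lam, sig)] = arr[rows]
    return feats


def compute_features(geometry: MolecularGeometry, pairs: PairList,
                     spec: RadialBasisSpec, species: tuple[str, ...] | None = None,
                     lam_max: int = 2) -> TwoCenterFeatures:
    """Full feature pipeline for one structure."""
    if species is None:
        species = default_species_order(geometry.symbols)
    pd = pair_density(geometry, pairs, spec)
    nd = neighbor_density(pd, pairs, geometry, species)
    directed, onsite_raw, meta = couple_features(nd, pd, pairs, geometry, lam_max)
    return symmetrize_pair_channels(directed, onsite_raw, meta, pairs,
                                    geometry, spec, species)
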