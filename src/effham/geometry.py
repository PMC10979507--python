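"""Molecular geometries, XYZ I/O and neighbor-pair bookkeeping.

Coordinates are stored in Å (the on-disk convention); electronic-structure
routines convert to atomic units where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_NUMBERS


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass(frozen=True)
class MolecularGeometry:
    """A molecular structure: element symbols, Cartesian coordinates (Å), net charge."""

    symbols: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Å
    net_charge: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {coords.shape}")
        if coords.shape[0] != len(self.symbols):
            raise ValueError("number of symbols and coordinate rows differ")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for s in self.symbols:
            if s not in ATOMIC_NUMBERS:
                raise ValueError(f"unsupported element symbol {s!r}")
        if self.net_charge != 0:
            raise ValueError("only neutral closed-shell systems are supported")
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.net_charge

    def rotated(self, rotation: np.ndarray) -> "MolecularGeometry":
        """Geometry with coordinates rigidly rotated by a 3x3 matrix."""
        return MolecularGeometry(self.symbols, self.coordinates @ np.asarray(rotation).T,
                                 self.net_charge)

    def translated(self, shift) -> "MolecularGeometry":
        return MolecularGeometry(self.symbols, self.coordinates + np.asarray(shift),
                                 self.net_charge)


def read_xyz(path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment, one record per atom).

    The comment line may carry ``charge=<int>``; it defaults to 0.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise XYZParseError(f"{path}: empty file or missing atom-count line (line 1)")
    try:
        n_atoms = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}: malformed atom-count line (line 1): {lines[0]!r}")
    if len(lines) < n_atoms + 2:
        raise XYZParseError(f"{path}: expected {n_atoms} atom records, file too short")
    comment = lines[1] if len(lines) > 1 else ""
    net_charge = 0
    for token in comment.split():
        if token.startswith("charge="):
            try:
                net_charge = int(token[len("charge="):])
            except ValueError:
                raise XYZParseError(f"{path}: malformed charge token in comment: {token!r}")
    symbols, coords = [], []
    for k in range(n_atoms):
        line_no = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: malformed atom record (line {line_no})")
        sym = parts[0]
        if sym not in ATOMIC_NUMBERS:
            raise XYZParseError(f"{path}: unknown element {sym!r} (line {line_no})")
        try:
            xyz = [float(p) for p in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}: non-numeric coordinate (line {line_no})")
        symbols.append(sym)
        coords.append(xyz)
    return MolecularGeometry(tuple(symbols), np.array(coords), net_charge)


def write_xyz(path, geometry: MolecularGeometry, comment: str = "") -> None:
    if geometry.net_charge != 0:
        comment = (comment + f" charge={geometry.net_charge}").strip()
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(geometry.symbols, geometry.coordinates):
            fh.write(f"{sym} {x:.12f} {y:.12f} {z:.12f}\n")


@dataclass(frozen=True)
class PairList:
    """On-site pairs (i, i) for every atom plus off-site pairs (i, j), i < j,
    for every interatomic separation within the cutoff (Å)."""

    pairs: tuple[tuple[int, int], ...]
    distances: np.ndarray
    cutoff: float

    @property
    def offsite(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.pairs if i != j]


def neighbor_pairs(geometry: MolecularGeometry, cutoff: float) -> PairList:
    """All on-site pairs and the off-site pairs with separation <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = geometry.coordinates
    pairs = [(i, i) for i in range(geometry.n_atoms)]
    dists = [0.0] * geometry.n_atoms
    delta = coords[:, None, :] - coords[None, :, :]
    dmat = np.linalg.norm(delta, axis=-1)
    for i in range(geometry.n_atoms):
        for j in range(i + 1, geometry.n_atoms):
            if dmat[i, j] <= cutoff:
                pairs.append((i, j))
                dists.append(dmat[i, j])
    return PairList(tuple(pairs), np.array(dists), float(cutoff))
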