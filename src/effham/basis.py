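"""Minimal-basis orbital layout and (atom, shell, m) -> matrix-index bookkeeping.

The default layout is the minimal set: H contributes a single 1s orbital and C
contributes 1s, 2s and 2p (five orbitals).  Within an atom, orbitals are
ordered shell-major with real-spherical-harmonic components m = -l..+l.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MolecularGeometry

# (radial index n~, angular momentum l~) per shell, in fixed order
MINIMAL_SHELLS: dict[str, tuple[tuple[int, int], ...]] = {
    "H": ((1, 0),),
    "C": ((1, 0), (2, 0), (2, 1)),
}

# An extended layout used to emulate "large basis" reference calculations:
# one extra diffuse shell per element.
EXTENDED_SHELLS: dict[str, tuple[tuple[int, int], ...]] = {
    "H": ((1, 0), (2, 0)),
    "C": ((1, 0), (2, 0), (2, 1), (3, 0), (3, 1)),
}


class LayoutError(KeyError):
    pass


@dataclass(frozen=True)
class BasisLayout:
    """Orbital layout: shells per element plus the flattened orbital index map."""

    shells_per_element: dict[str, tuple[tuple[int, int], ...]]

    def shells(self, element: str) -> tuple[tuple[int, int], ...]:
        try:
            return self.shells_per_element[element]
        except KeyError:
            raise LayoutError(f"element {element!r} has no shell list in this layout")

    def orbitals_per_element(self, element: str) -> int:
        return sum(2 * l + 1 for _, l in self.shells(element))

    def n_orbitals(self, geometry: MolecularGeometry) -> int:
        return sum(self.orbitals_per_element(s) for s in geometry.symbols)

    def atom_offsets(self, geometry: MolecularGeometry) -> np.ndarray:
        """Starting orbital index of each atom."""
        counts = [self.orbitals_per_element(s) for s in geometry.symbols]
        return np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(int)

    def shell_offsets(self, element: str) -> list[int]:
        """Within-atom starting index of each shell."""
        offs, acc = [], 0
        for _, l in self.shells(element):
            offs.append(acc)
            acc += 2 * l + 1
        return offs

    def orbital_index(self, geometry: MolecularGeometry) -> dict[tuple[int, int, int], int]:
        """Bijective map (atom, shell, m) -> matrix index, m = -l..+l."""
        index = {}
        offsets = self.atom_offsets(geometry)
        for a, sym in enumerate(geometry.symbols):
            pos = int(offsets[a])
            for s, (_, l) in enumerate(self.shells(sym)):
                for k, m in enumerate(range(-l, l + 1)):
                    index[(a, s, m)] = pos + k
                pos += 2 * l + 1
        return index

    def atom_of_orbital(self, geometry: MolecularGeometry) -> np.ndarray:
        """Atom index owning each orbital row/column."""
        out = []
        for a, sym in enumerate(geometry.symbols):
            out.extend([a] * self.orbitals_per_element(sym))
        return np.array(out, dtype=int)


def minimal_layout() -> BasisLayout:
    return BasisLayout(dict(MINIMAL_SHELLS))


def extended_layout() -> BasisLayout:
    return BasisLayout(dict(EXTENDED_SHELLS))


def build_orbital_index(geometry: MolecularGeometry, layout: BasisLayout):
    """Orbital-index map and total orbital count for a geometry under a layout."""
    return layout.orbital_index(geometry), layout.n_orbitals(geometry)
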