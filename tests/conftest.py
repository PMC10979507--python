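"""Shared fixtures and independent oracles.

The rotational oracles here deliberately avoid the package's own spherical
harmonics: real spherical harmonics are evaluated through sympy's symbolic
Ynm (associated Legendre route) and Wigner matrices are least-squares fitted
to those values, so equivariance checks compare two independent evaluation
paths.
"""

from __future__ import annotations

import numpy as np
import pytest
from sympy import Symbol, Ynm

from effham.basis import minimal_layout
from effham.features import RadialBasisSpec, default_species_order
from effham.geometry import MolecularGeometry
from effham.synthetic import TeacherModel


# --------------------------------------------------------------------------
# independent real-spherical-harmonic / Wigner oracle


def sympy_real_sph(l: int, vecs: np.ndarray) -> np.ndarray:
    """Real spherical harmonics (Condon-Shortley, m = -l..l) via sympy Ynm."""
    vecs = np.atleast_2d(vecs)
    out = np.empty((vecs.shape[0], 2 * l + 1))
    th, ph = Symbol("theta"), Symbol("phi")
    for k, v in enumerate(vecs):
        theta = float(np.arccos(np.clip(v[2] / np.linalg.norm(v), -1, 1)))
        phi = float(np.arctan2(v[1], v[0]))
        for m in range(0, l + 1):
            y = complex(Ynm(l, m, th, ph).subs({th: theta, ph: phi}).evalf())
            if m == 0:
                out[k, l] = y.real
            else:
                out[k, l + m] = np.sqrt(2.0) * (-1) ** m * y.real
                out[k, l - m] = np.sqrt(2.0) * (-1) ** m * y.imag
    return out


def oracle_wigner(l: int, R: np.ndarray, rng=None) -> np.ndarray:
    """Real Wigner matrix from sympy-evaluated harmonics (independent path)."""
    rng = rng or np.random.default_rng(1234 + l)
    pts = rng.normal(size=(3 * (2 * l + 1), 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    Y0 = sympy_real_sph(l, pts)
    Y1 = sympy_real_sph(l, pts @ np.asarray(R).T)
    D, *_ = np.linalg.lstsq(Y0, Y1, rcond=None)
    return D.T


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def layout():
    return minimal_layout()


@pytest.fixture(scope="session")
def spec():
    return RadialBasisSpec()


@pytest.fixture(scope="session")
def species(layout):
    return default_species_order(layout)


@pytest.fixture(scope="session")
def ethene():
    """A slightly distorted ethene-like C2H4 (no special symmetry)."""
    rng = np.random.default_rng(7)
    coords = np.array([[0, 0, 0], [1.33, 0, 0], [-0.55, 0.92, 0],
                       [-0.55, -0.92, 0], [1.88, 0.92, 0], [1.88, -0.92, 0.0]])
    return MolecularGeometry(("C", "C", "H", "H", "H", "H"),
                             coords + rng.normal(0, 0.04, (6, 3)))


@pytest.fixture(scope="session")
def teacher(spec, layout, species):
    return TeacherModel.random(17, spec, layout, species, scale=0.1)
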