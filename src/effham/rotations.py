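"""Real spherical harmonics, real Clebsch-Gordan tables and real Wigner matrices.

All angular algebra uses real spherical harmonics with Condon-Shortley phase,
components ordered m = -l..+l.  Clebsch-Gordan coefficients are generated
exactly (rational arithmetic) in the complex basis and transformed once to the
real basis; per-(l1, l2) tables are cached and checked for orthogonality.

Conventions
-----------
A rotation R acts on a real spherical tensor of order l through the real
Wigner matrix ``D(l, R)``::

    Y_lm(R r) = sum_m' D[m, m'] Y_lm'(r)

Coupling two tensors of orders (l1, l2) into order lam uses the real tensor
``cg_real(l1, l2, lam)[m1, m2, mu]``; stacking over lam gives an orthogonal
change of basis on the (2l1+1)(2l2+1)-dimensional product space.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y
from sympy.physics.wigner import clebsch_gordan as _sympy_cg


def real_sph_harm(l: int, unit_vectors: np.ndarray) -> np.ndarray:
    """Real spherical harmonics Y_lm at unit vectors; returns (n_points, 2l+1)."""
    v = np.atleast_2d(np.asarray(unit_vectors, dtype=float))
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    out = np.empty((v.shape[0], 2 * l + 1))
    for m in range(0, l + 1):
        y = sph_harm_y(l, m, theta, phi)
        if m == 0:
            out[:, l] = y.real
        else:
            out[:, l + m] = np.sqrt(2.0) * (-1.0) ** m * y.real
            out[:, l - m] = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out


@lru_cache(maxsize=None)
def _complex_to_real(l: int) -> np.ndarray:
    """Unitary U with  Y_real = U @ Y_complex  (rows mu, columns m, both -l..l)."""
    U = np.zeros((2 * l + 1, 2 * l + 1), dtype=complex)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        U[l + m, l + m] = (-1.0) ** m / np.sqrt(2.0)
        U[l + m, l - m] = 1.0 / np.sqrt(2.0)
        U[l - m, l + m] = -1j * (-1.0) ** m / np.sqrt(2.0)
        U[l - m, l - m] = 1j / np.sqrt(2.0)
    return U


@lru_cache(maxsize=None)
def _complex_cg(l1: int, l2: int, lam: int) -> np.ndarray:
    """Complex CG tensor <l1 m1 l2 m2 | lam mu>, shape (2l1+1, 2l2+1, 2lam+1)."""
    C = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * lam + 1))
    for i1, m1 in enumerate(range(-l1, l1 + 1)):
        for i2, m2 in enumerate(range(-l2, l2 + 1)):
            mu = m1 + m2
            if abs(mu) <= lam:
                C[i1, i2, lam + mu] = float(_sympy_cg(l1, l2, lam, m1, m2, mu))
    return C


@lru_cache(maxsize=None)
def cg_real(l1: int, l2: int, lam: int) -> np.ndarray:
    """Real-basis coupling tensor K[m1, m2, mu] for l1 (x) l2 -> lam.

    Real-valued by construction: the complex-basis tensor conjugated into the
    real basis is purely real for parity (-1)^(l1+l2+lam) = +1 and purely
    imaginary otherwise; the imaginary case is rotated by -i onto the reals
    (a constant phase, which preserves equivariance).
    """
    if not abs(l1 - l2) <= lam <= l1 + l2:
        raise ValueError(f"lam={lam} outside |l1-l2|..l1+l2 for l1={l1}, l2={l2}")
    C = _complex_cg(l1, l2, lam)
    U1 = _complex_to_real(l1)
    U2 = _complex_to_real(l2)
    Ul = _complex_to_real(lam)
    K = np.einsum("uM,abM,xa,yb->xyu", Ul, C, U1.conj(), U2.conj())
    if (-1) ** (l1 + l2 + lam) == 1:
        assert np.abs(K.imag).max() < 1e-12
        return np.ascontiguousarray(K.real)
    assert np.abs(K.real).max() < 1e-12
    return np.ascontiguousarray(K.imag)


@lru_cache(maxsize=None)
def cg_swap_sign(l1: int, l2: int, lam: int) -> float:
    """Sign s with cg_real(l2,l1,lam)[m2,m1,mu] = s * cg_real(l1,l2,lam)[m1,m2,mu]."""
    K12 = cg_real(l1, l2, lam)
    K21 = cg_real(l2, l1, lam)
    s = (-1.0) ** (l1 + l2 - lam)
    assert np.allclose(K21.transpose(1, 0, 2), s * K12, atol=1e-12)
    return s


@lru_cache(maxsize=None)
def _check_orthogonal(l1: int, l2: int) -> bool:
    """Stacked coupling over all lam must be an orthogonal matrix (1e-12)."""
    blocks = [cg_real(l1, l2, lam).reshape((2 * l1 + 1) * (2 * l2 + 1), 2 * lam + 1)
              for lam in range(abs(l1 - l2), l1 + l2 + 1)]
    Q = np.concatenate(blocks, axis=1)
    err = np.abs(Q @ Q.T - np.eye(Q.shape[0])).max()
    if err > 1e-12:
        raise AssertionError(f"real CG table for ({l1},{l2}) not orthogonal: {err}")
    return True


_WIGNER_POINTS: dict[int, np.ndarray] = {}


def _sample_points(l: int) -> np.ndarray:
    if l not in _WIGNER_POINTS:
        rng = np.random.default_rng(20240517 + l)
        v = rng.normal(size=(4 * (2 * l + 1), 3))
        _WIGNER_POINTS[l] = v / np.linalg.norm(v, axis=1, keepdims=True)
    return _WIGNER_POINTS[l]


def real_wigner_d(l: int, rotation: np.ndarray) -> np.ndarray:
    """Real Wigner matrix D with Y_l(R r) = D @ Y_l(r), from a least-squares
    fit on a fixed overdetermined set of sample directions (exact to ~1e-13)."""
    if l == 0:
        return np.ones((1, 1))
    R = np.asarray(rotation, dtype=float)
    pts = _sample_points(l)
    Y0 = real_sph_harm(l, pts)
    Y1 = real_sph_harm(l, pts @ R.T)
    D, *_ = np.linalg.lstsq(Y0, Y1, rcond=None)
    return D.T


def block_wigner(geometry, layout, rotation: np.ndarray) -> np.ndarray:
    """Block-diagonal real Wigner matrix over all orbitals of a geometry."""
    from scipy.linalg import block_diag
    blocks = []
    for sym in geometry.symbols:
        for _, l in layout.shells(sym):
            blocks.append(real_wigner_d(l, rotation))
    return block_diag(*blocks)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
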