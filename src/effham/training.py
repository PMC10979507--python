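"""Training of the equivariant linear Hamiltonian model.

Three modes:

* ``h`` (model 1): direct ridge regression of the irrep components of
  reference Hamiltonian matrices — convex, solved in closed form per block
  family via SVD.
* ``eps`` (model 2): indirect loss on sorted MO energies obtained by
  diagonalizing the predicted matrix.
* ``eps_q`` (model 3): MO energies plus Löwdin charges.

The indirect losses are minimized with L-BFGS using analytic gradients
propagated through the eigendecomposition: Hellmann-Feynman terms for the
eigenvalues and first-order perturbation theory (occupied-virtual response of
the density matrix) for the charges.  Large-basis targets (more reference
levels than minimal-basis orbitals) are handled by selecting the lowest
``n_select`` reference eigenvalues (all occupied valence states plus the
lowest virtuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .basis import BasisLayout, minimal_layout
from .features import (RadialBasisSpec, TwoCenterFeatures, compute_features,
                       default_species_order)
from .geometry import MolecularGeometry, neighbor_pairs
from .hamiltonian import (BlockKey, IrrepBlocks, ModelWeights, _sigma_of,
                          assemble_hamiltonian, decompose_targets, feature_key,
                          model_block_keys, predict_blocks)
from .properties import _occupations, loewdin_charges, solve_mos
from .rotations import cg_real, cg_swap_sign
from .features import SQRT2


# ---------------------------------------------------------------------------
# targets and configuration


@dataclass
class TrainingTarget:
    """Reference data for one of the three training modes.

    kind: 'hamiltonian' | 'eigenvalues' | 'eigenvalues_and_charges'.
    eigenvalues are per-structure ascending arrays (Hartree); for large-basis
    targets they may be longer than the minimal-basis orbital count, in which
    case ``n_select`` (default: minimal orbital count) lowest levels are used.
    """

    kind: str
    hamiltonians: list | None = None
    eigenvalues: list | None = None
    charges: list | None = None
    n_select: int | None = None

    def __post_init__(self):
        kinds = ("hamiltonian", "eigenvalues", "eigenvalues_and_charges")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.eigenvalues is not None:
            for e in self.eigenvalues:
                if np.any(np.diff(e) < -1e-10):
                    raise ValueError("target eigenvalues must be sorted ascending")


@dataclass
class LossConfig:
    """Loss mode and optimizer settings.

    ``charge_weight`` multiplies the charge term of model 3; inside the
    optimizer both terms are additionally standardized by the target variance
    so the default weight 1.0 balances them regardless of units.
    """

    mode: str = "h"            # 'h' | 'eps' | 'eps_q'
    charge_weight: float = 1.0
    ridge_lambda: float = 1e-8
    max_iterations: int = 500
    gtol: float = 1e-8
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self):
        if self.charge_weight < 0 or self.ridge_lambda < 0:
            raise ValueError("charge_weight and ridge_lambda must be >= 0")
        if self.mode not in ("h", "eps", "eps_q"):
            raise ValueError("mode must be 'h', 'eps' or 'eps_q'")


@dataclass
class TrainedModel:
    weights: ModelWeights
    loss_history: list
    config: LossConfig
    spec: RadialBasisSpec
    layout: BasisLayout
    species: tuple
    lam_max: int = 2


# ---------------------------------------------------------------------------
# prepared structures: features plus a fast linear assembly plan


@dataclass
class _Placement:
    K: np.ndarray
    coeff: float
    transpose: bool
    oa: np.ndarray  # per-row row-offset
    ob: np.ndarray  # per-row col-offset
    wa: int
    wb: int


@dataclass
class PreparedStructure:
    geometry: MolecularGeometry
    feats: TwoCenterFeatures
    plan: dict          # BlockKey -> list[_Placement]
    n_orbitals: int
    n_electrons: int


def _build_plan(geometry, layout, feats, keys):
    offsets = layout.atom_offsets(geometry)

    def orb(i, shell):
        return int(offsets[i] + layout.shell_offsets(geometry.symbols[i])[shell])

    plan = {}
    for key in keys:
        placements = []
        if key.kind == "on":
            el = key.species[0]
            rows = feats.atom_rows.get(el, [])
            if rows:
                la = layout.shells(el)[key.a][1]
                lb = layout.shells(el)[key.b][1]
                K = cg_real(la, lb, key.lam)
                oa = np.array([orb(i, key.a) for i in rows])
                ob = np.array([orb(i, key.b) for i in rows])
                placements.append(_Placement(K, 1.0, False, oa, ob, 2 * la + 1, 2 * lb + 1))
                if key.a != key.b:
                    placements.append(_Placement(K, 1.0, True, ob, oa, 2 * lb + 1, 2 * la + 1))
        else:
            el1, el2 = key.species
            rows = feats.pair_rows.get((el1, el2), [])
            if rows:
                la = layout.shells(el1)[key.a][1]
                lb = layout.shells(el2)[key.b][1]
                K = cg_real(la, lb, key.lam)
                ia = np.array([orb(i, key.a) for i, j in rows])
                jb = np.array([orb(j, key.b) for i, j in rows])
                same = el1 == el2
                if same:
                    ja = np.array([orb(j, key.a) for i, j in rows])
                    ib = np.array([orb(i, key.b) for i, j in rows])
                    s = cg_swap_sign(la, lb, key.lam)
                    c = 1.0 / SQRT2
                    placements.append(_Placement(K, c, False, ia, jb, 2 * la + 1, 2 * lb + 1))
                    placements.append(_Placement(K, c, True, jb, ia, 2 * lb + 1, 2 * la + 1))
                    if key.a != key.b:
                        Kba = cg_real(lb, la, key.lam)
                        c2 = key.tau * s / SQRT2
                        placements.append(_Placement(Kba, c2, False, ib, ja, 2 * lb + 1, 2 * la + 1))
                        placements.append(_Placement(Kba, c2, True, ja, ib, 2 * la + 1, 2 * lb + 1))
                else:
                    placements.append(_Placement(K, 1.0, False, ia, jb, 2 * la + 1, 2 * lb + 1))
                    placements.append(_Placement(K, 1.0, True, jb, ia, 2 * lb + 1, 2 * la + 1))
        plan[key] = placements
    return plan


def prepare_structures(geometries, spec: RadialBasisSpec, layout: BasisLayout,
                       species=None, lam_max: int = 2) -> list[PreparedStructure]:
    if species is None:
        species = default_species_order(layout)
    keys = model_block_keys(layout, species, lam_max)
    out = []
    for geo in geometries:
        pairs = neighbor_pairs(geo, spec.cutoff)
        feats = compute_features(geo, pairs, spec, species, lam_max)
        plan = _build_plan(geo, layout, feats, keys)
        out.append(PreparedStructure(geo, feats, plan, layout.n_orbitals(geo),
                                     geo.n_electrons))
    return out


def _feature_array(ps: PreparedStructure, layout, key):
    fk = feature_key(layout, key)
    store = ps.feats.onsite if key.kind == "on" else ps.feats.offsite
    return store.get(fk)


def _forward_matrix(ps: PreparedStructure, layout, weights: ModelWeights) -> np.ndarray:
    """Assemble H for one structure from the placement plan (fast path)."""
    H = np.zeros((ps.n_orbitals, ps.n_orbitals))
    for key, w in weights.weights.items():
        F = _feature_array(ps, layout, key)
        if F is None or F.shape[0] == 0:
            continue
        T = np.einsum("rqm,q->rm", F, w)
        for p in ps.plan[key]:
            sub = p.coeff * np.einsum("xyu,ru->rxy", p.K, T)
            if p.transpose:
                sub = sub.transpose(0, 2, 1)
            for r in range(sub.shape[0]):
                H[p.oa[r]:p.oa[r] + p.wa, p.ob[r]:p.ob[r] + p.wb] += sub[r]
    return H


def _adjoint_gradient(ps: PreparedStructure, layout, weights: ModelWeights,
                      G: np.ndarray) -> dict:
    """Map dL/dH (full-matrix gradient) to dL/dw per block family."""
    grads = {}
    for key, w in weights.weights.items():
        F = _feature_array(ps, layout, key)
        if F is None or F.shape[0] == 0:
            grads[key] = np.zeros_like(w)
            continue
        gT = np.zeros((F.shape[0], 2 * key.lam + 1))
        for p in ps.plan[key]:
            subs = np.empty((F.shape[0], p.wa, p.wb))
            for r in range(F.shape[0]):
                subs[r] = G[p.oa[r]:p.oa[r] + p.wa, p.ob[r]:p.ob[r] + p.wb]
            if p.transpose:
                subs = subs.transpose(0, 2, 1)
            gT += p.coeff * np.einsum("xyu,rxy->ru", p.K, subs)
        grads[key] = np.einsum("rqm,rm->q", F, gT)
    return grads


# ---------------------------------------------------------------------------
# model 1: closed-form ridge


def fit_model1(structures: list[PreparedStructure], targets: TrainingTarget,
               config: LossConfig, layout: BasisLayout,
               spec: RadialBasisSpec, species=None,
               lam_max: int = 2) -> TrainedModel:
    """Per-family ridge regression of Hamiltonian irrep components (convex,
    deterministic; solved by SVD)."""
    if targets.hamiltonians is None:
        raise ValueError("model 1 requires Hamiltonian targets")
    if species is None:
        species = default_species_order(layout)
    keys = model_block_keys(layout, species, lam_max)
    decomposed = [decompose_targets(np.asarray(Href), ps.geometry, layout,
                                    ps.feats, lam_max)
                  for Href, ps in zip(targets.hamiltonians, structures)]
    weights = {}
    sq_err = 0.0
    n_entries = 0
    for key in keys:
        Xs, ys = [], []
        for ps, dec in zip(structures, decomposed):
            F = _feature_array(ps, layout, key)
            if F is None or F.shape[0] == 0:
                continue
            Xs.append(F.transpose(0, 2, 1).reshape(-1, F.shape[1]))
            ys.append(dec.values[key].reshape(-1))
        if not Xs:
            nchan = ModelWeights.zeros(layout, spec, species, lam_max).weights[key].size
            weights[key] = np.zeros(nchan)
            continue
        X = np.vstack(Xs)
        y = np.concatenate(ys)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        lam = config.ridge_lambda
        if lam == 0.0 and s.size and s[-1] < 1e-10 * s[0]:
            warnings.warn(f"rank-deficient normal equations for {key}; "
                          "using pseudo-inverse", stacklevel=2)
            shrink = np.where(s > 1e-10 * s[0], 1.0 / np.maximum(s, 1e-300), 0.0)
        else:
            shrink = s / (s * s + lam)
        w = Vt.T @ (shrink * (U.T @ y))
        weights[key] = w
        resid = X @ w - y
        sq_err += float(resid @ resid)
        n_entries += y.size
    mse = sq_err / max(n_entries, 1)
    return TrainedModel(ModelWeights(weights), [mse], config, spec, layout,
                        tuple(species), lam_max)


def select_ridge_lambda(structures: list[PreparedStructure],
                        targets: TrainingTarget, layout: BasisLayout,
                        spec: RadialBasisSpec, species=None, lam_max: int = 2,
                        grid=tuple(10.0 ** -k for k in range(2, 11)),
                        holdout_fraction: float = 0.1,
                        seed: int = 0) -> float:
    """Pick the ridge strength by a logarithmic grid search with a 90/10
    train/validation split, scoring the held-out Hamiltonian MSE."""
    if targets.hamiltonians is None:
        raise ValueError("ridge selection requires Hamiltonian targets")
    if species is None:
        species = default_species_order(layout)
    rng = np.random.default_rng(seed)
    n = len(structures)
    n_val = max(1, int(round(holdout_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    tr = [structures[i] for i in tr_idx]
    tr_t = TrainingTarget("hamiltonian",
                          hamiltonians=[targets.hamiltonians[i] for i in tr_idx])
    best_lam, best_score = grid[0], np.inf
    for lam in grid:
        model = fit_model1(tr, tr_t, LossConfig(ridge_lambda=lam), layout,
                           spec, species, lam_max)
        score = 0.0
        for i in val_idx:
            H_pred = _forward_matrix(structures[i], layout, model.weights)
            d = H_pred - np.asarray(targets.hamiltonians[i])
            score += float(np.sum(d * d))
        if score < best_score:
            best_lam, best_score = lam, score
    return best_lam


# ---------------------------------------------------------------------------
# indirect losses (models 2 and 3)


def _solve_structure(ps: PreparedStructure, layout, weights):
    H = _forward_matrix(ps, layout, weights)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite predicted Hamiltonian")
    try:
        eps, C = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        # rare eigensolver failure: tiny diagonal jitter, then retry
        warnings.warn("eigensolver failure; applying 1e-10 diagonal jitter",
                      stacklevel=2)
        eps, C = np.linalg.eigh(H + 1e-10 * np.eye(H.shape[0]))
    return H, eps, C


def _charges_from(ps: PreparedStructure, layout, eps, C):
    occ = _occupations(eps, ps.n_electrons)
    atom_of = layout.atom_of_orbital(ps.geometry)
    pops = (C ** 2) @ occ
    q = ps.geometry.atomic_numbers.astype(float)
    np.add.at(q, atom_of, -pops)
    return q, occ, atom_of


def loss_model2(weights: ModelWeights, structures: list[PreparedStructure],
                targets: TrainingTarget, layout: BasisLayout) -> float:
    """Plain MSE (Hartree^2) of sorted predicted vs target MO energies."""
    total, count = 0.0, 0
    for ps, e_ref in zip(structures, targets.eigenvalues):
        n_sel = targets.n_select or min(len(e_ref), ps.n_orbitals)
        _, eps, _ = _solve_structure(ps, layout, weights)
        d = eps[:n_sel] - np.asarray(e_ref)[:n_sel]
        total += float(d @ d)
        count += n_sel
    return total / count


def loss_model3(weights: ModelWeights, structures, targets: TrainingTarget,
                config: LossConfig, layout: BasisLayout) -> float:
    """loss_model2 plus charge_weight times the per-atom charge MSE."""
    l2 = loss_model2(weights, structures, targets, layout)
    qt, qc = 0.0, 0
    for ps, q_ref in zip(structures, targets.charges):
        _, eps, C = _solve_structure(ps, layout, weights)
        q, _, _ = _charges_from(ps, layout, eps, C)
        d = q - np.asarray(q_ref)
        qt += float(d @ d)
        qc += q.size
    return l2 + config.charge_weight * qt / qc


def _indirect_objective(weights_template: ModelWeights, structures, targets,
                        config: LossConfig, layout):
    """Objective (MSE_eps + charge_weight * MSE_q) and analytic gradient."""
    use_q = config.mode == "eps_q"
    var_eps = var_q = 1.0
    n_eps_total = sum(targets.n_select or min(len(e), ps.n_orbitals)
                      for ps, e in zip(structures, targets.eigenvalues))
    n_q_total = sum(ps.geometry.n_atoms for ps in structures) if use_q else 1

    def fun(wvec):
        weights = weights_template.from_vector(wvec)
        loss = 0.0
        grad_total = {k: np.zeros_like(v) for k, v in weights.weights.items()}
        for si, ps in enumerate(structures):
            e_ref = np.asarray(targets.eigenvalues[si])
            n_sel = targets.n_select or min(e_ref.size, ps.n_orbitals)
            H, eps, C = _solve_structure(ps, layout, weights)
            d_eps = eps[:n_sel] - e_ref[:n_sel]
            loss += float(d_eps @ d_eps) / (n_eps_total * var_eps)
            g_eps = np.zeros(eps.size)
            g_eps[:n_sel] = 2.0 * d_eps / (n_eps_total * var_eps)
            G = (C * g_eps) @ C.T
            if use_q:
                q_ref = np.asarray(targets.charges[si])
                q, occ, atom_of = _charges_from(ps, layout, eps, C)
                d_q = q - q_ref
                wq = config.charge_weight / (n_q_total * var_q)
                loss += wq * float(d_q @ d_q)
                # density-matrix response: only pairs with different occupation
                g_pop = -2.0 * wq * d_q[atom_of]       # dL/d(per-orbital population)
                A = 2.0 * C.T @ (g_pop[:, None] * C)   # a_nm = 2 v_n^T diag(g) v_m
                df = occ[:, None] - occ[None, :]
                de = eps[:, None] - eps[None, :]
                mask = np.abs(df) > 1e-12
                denom = np.where(mask, np.where(np.abs(de) > 1e-10, de,
                                                np.sign(de) * 1e-10 + (de == 0) * 1e-10), 1.0)
                Cmat = np.where(mask, A * df / denom, 0.0)
                G = G + 0.5 * (C @ Cmat @ C.T)
            G = 0.5 * (G + G.T)
            g_w = _adjoint_gradient(ps, layout, weights, G)
            for k in grad_total:
                grad_total[k] += g_w[k]
        gvec = ModelWeights(grad_total).as_vector()
        return loss, gvec

    return fun


def fit_indirect(structures: list[PreparedStructure], targets: TrainingTarget,
                 config: LossConfig, layout: BasisLayout, spec: RadialBasisSpec,
                 species=None, lam_max: int = 2,
                 init: ModelWeights | None = None) -> TrainedModel:
    """Gradient-based minimization of the indirect (eigenvalue / charge) loss.

    Initialization (staged, mirroring how the reference workflow promotes a
    cheap solution to a richer loss): explicit ``init`` > model-1 ridge
    solution when Hamiltonian targets are available > for the joint
    eigenvalue+charge loss, an eigenvalue-only pre-fit from small seeded
    random weights > small seeded random weights.  The joint loss from a cold
    random start is dominated by the charge term and reliably traps the
    optimizer away from the eigenvalue solution.
    """
    if config.mode not in ("eps", "eps_q"):
        raise ValueError("fit_indirect handles modes 'eps' and 'eps_q'")
    if targets.eigenvalues is None:
        raise ValueError("indirect training requires eigenvalue targets")
    if config.mode == "eps_q" and targets.charges is None:
        raise ValueError("mode 'eps_q' requires charge targets")
    if species is None:
        species = default_species_order(layout)

    if init is not None:
        weights = ModelWeights({k: v.copy() for k, v in init.weights.items()})
    elif targets.hamiltonians is not None:
        weights = fit_model1(structures, targets, config, layout, spec,
                             species, lam_max).weights
    elif config.mode == "eps_q":
        stage1 = fit_indirect(structures, targets, replace(config, mode="eps"),
                              layout, spec, species, lam_max)
        weights = stage1.weights
    else:
        rng = np.random.default_rng(config.seed)
        weights = ModelWeights.zeros(layout, spec, species, lam_max)
        for k in weights.weights:
            n = weights.weights[k].size
            weights.weights[k] = rng.normal(0.0, config.init_scale / np.sqrt(max(n, 1)), n)

    fun = _indirect_objective(weights, structures, targets, config, layout)
    history = []
    x0 = weights.as_vector()
    if config.max_iterations == 0:
        history.append(fun(x0)[0])
        return TrainedModel(weights, history, config, spec, layout,
                            tuple(species), lam_max)

    def cb(xk):
        history.append(fun(xk)[0])

    res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=cb,
                   options={"maxiter": config.max_iterations,
                            "gtol": config.gtol, "ftol": 1e-14})
    final = weights.from_vector(res.x)
    if not history:
        history.append(float(res.fun))
    return TrainedModel(final, history, config, spec, layout,
                        tuple(species), lam_max)


# ---------------------------------------------------------------------------
# large-basis target selection


def select_valence_targets(full_eigenvalues, full_charges,
                           layout: BasisLayout, geometry: MolecularGeometry) -> TrainingTarget:
    """Keep the lowest n_minimal reference eigenvalues (all occupied valence
    states plus the lowest virtuals); charges pass through unchanged."""
    n_min = layout.n_orbitals(geometry)
    e = np.sort(np.asarray(full_eigenvalues))
    if e.size < n_min:
        raise ValueError(f"need at least {n_min} reference eigenvalues, got {e.size}")
    kind = "eigenvalues" if full_charges is None else "eigenvalues_and_charges"
    charges = None if full_charges is None else [np.asarray(full_charges)]
    return TrainingTarget(kind, eigenvalues=[e[:n_min]], charges=charges,
                          n_select=n_min)


# ---------------------------------------------------------------------------
# estimator facade


class EffectiveHamiltonianModel(BaseEstimator):
    """Equivariant linear model of an effective minimal-basis Hamiltonian.

    scikit-learn-style estimator: ``fit(geometries, targets)`` trains in one
    of the three modes; ``predict(geometries)`` returns assembled effective
    Hamiltonians; convenience predictors return MO energies (Hartree),
    Löwdin charges (e) and HOMO-LUMO gaps (eV).

    Parameters mirror :class:`RadialBasisSpec` and :class:`LossConfig`.
    """

    def __init__(self, mode="h", cutoff=4.5, n_max=6, l_max=4,
                 gaussian_width=0.2, lam_max=2, ridge_lambda=1e-8,
                 charge_weight=1.0, max_iterations=500, gtol=1e-8, seed=0):
        self.mode = mode
        self.cutoff = cutoff
        self.n_max = n_max
        self.l_max = l_max
        self.gaussian_width = gaussian_width
        self.lam_max = lam_max
        self.ridge_lambda = ridge_lambda
        self.charge_weight = charge_weight
        self.max_iterations = max_iterations
        self.gtol = gtol
        self.seed = seed

    def _spec(self) -> RadialBasisSpec:
        return RadialBasisSpec(n_max=self.n_max, l_max=self.l_max,
                               gaussian_width=self.gaussian_width,
                               cutoff=self.cutoff)

    def _config(self) -> LossConfig:
        return LossConfig(mode=self.mode, charge_weight=self.charge_weight,
                          ridge_lambda=self.ridge_lambda,
                          max_iterations=self.max_iterations, gtol=self.gtol,
                          seed=self.seed)

    def fit(self, X, y, layout: BasisLayout | None = None,
            init: ModelWeights | None = None):
        """Fit on a list of geometries ``X`` and a :class:`TrainingTarget` ``y``."""
        layout = layout or minimal_layout()
        spec = self._spec()
        species = default_species_order(layout)
        structures = prepare_structures(X, spec, layout, species, self.lam_max)
        config = self._config()
        if config.mode == "h":
            model = fit_model1(structures, y, config, layout, spec, species,
                               self.lam_max)
        else:
            model = fit_indirect(structures, y, config, layout, spec, species,
                                 self.lam_max, init=init)
        self.weights_ = model.weights
        self.loss_history_ = model.loss_history
        self.layout_ = layout
        self.spec_ = spec
        self.species_ = tuple(species)
        self.n_structures_ = len(X)
        return self

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise AttributeError("model is not fitted")

    def predict(self, X):
        """Assembled effective Hamiltonians for a list of geometries."""
        from .hamiltonian import predict_hamiltonian
        self._check_fitted()
        return [predict_hamiltonian(g, self.weights_, self.layout_, self.spec_,
                                    self.species_, self.lam_max) for g in X]

    def predict_mos(self, X):
        return [solve_mos(H, g.n_electrons)
                for H, g in zip(self.predict(X), X)]

    def predict_energies(self, X):
        return [s.energies for s in self.predict_mos(X)]

    def predict_charges(self, X):
        self._check_fitted()
        out = []
        for g, sol in zip(X, self.predict_mos(X)):
            out.append(loewdin_charges(sol, g, self.layout_).q)
        return out
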