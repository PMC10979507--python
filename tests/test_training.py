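"""Direct and indirect training: ridge recovery, losses, gradients, staging."""

import numpy as np
import pytest

from effham.basis import extended_layout, minimal_layout
from effham.features import RadialBasisSpec, default_species_order
from effham.hamiltonian import ModelWeights
from effham.properties import _occupations
from effham.synthetic import (TeacherModel, ToyReference, make_geometries,
                              project_teacher, teacher_targets,
                              toy_reference_targets)
from effham.training import (EffectiveHamiltonianModel, LossConfig,
                             TrainingTarget, _adjoint_gradient, _feature_array,
                             _forward_matrix, _indirect_objective, fit_indirect,
                             fit_model1, loss_model2, loss_model3,
                             prepare_structures, select_valence_targets)


@pytest.fixture(scope="module")
def tiny_setup(layout, spec, species):
    """A small but fully determined training problem is too expensive here;
    this fixture provides features/plans for structural tests."""
    geos = make_geometries("perturbed", 6, seed=41, n_carbon=2)
    return geos, prepare_structures(geos, spec, layout, species)


class TestAssemblyPlan:
    def test_fast_forward_matches_reference_assembly(self, tiny_setup, layout,
                                                     spec, species, teacher):
        from effham.hamiltonian import predict_hamiltonian
        geos, structures = tiny_setup
        for ps in structures[:2]:
            H_fast = _forward_matrix(ps, layout, teacher.weights)
            H_ref = predict_hamiltonian(ps.geometry, teacher.weights, layout,
                                        spec, species)
            assert np.abs(H_fast - H_ref.matrix).max() < 1e-13

    def test_adjoint_identity(self, tiny_setup, layout, teacher):
        """<assemble(w), G> == <w, adjoint(G)> for random symmetric G."""
        geos, structures = tiny_setup
        rng = np.random.default_rng(0)
        ps = structures[0]
        G = rng.normal(size=(ps.n_orbitals, ps.n_orbitals))
        G = 0.5 * (G + G.T)
        lhs = float(np.sum(_forward_matrix(ps, layout, teacher.weights) * G))
        g = _adjoint_gradient(ps, layout, teacher.weights, G)
        rhs = sum(float(teacher.weights.weights[k] @ g[k]) for k in g)
        assert abs(lhs - rhs) < 1e-10 * max(abs(lhs), 1.0)


class TestModel1:
    def test_zero_targets_zero_weights(self, tiny_setup, layout, spec, species):
        geos, structures = tiny_setup
        targets = TrainingTarget("hamiltonian",
                                 hamiltonians=[np.zeros((ps.n_orbitals,) * 2)
                                               for ps in structures])
        m = fit_model1(structures, targets, LossConfig(ridge_lambda=1e-10),
                       layout, spec, species)
        assert np.abs(m.weights.as_vector()).max() < 1e-12

    def test_duplicated_structures_leave_solution_unchanged(
            self, tiny_setup, layout, spec, species, teacher):
        geos, structures = tiny_setup
        Hs = [_forward_matrix(ps, layout, teacher.weights) for ps in structures]
        cfg = LossConfig(ridge_lambda=1e-10)
        m1 = fit_model1(structures, TrainingTarget("hamiltonian",
                        hamiltonians=Hs), cfg, layout, spec, species)
        m2 = fit_model1(structures + structures,
                        TrainingTarget("hamiltonian", hamiltonians=Hs + Hs),
                        cfg, layout, spec, species)
        # at small ridge the duplication changes only the (negligible)
        # penalty-to-data balance: fitted predictions coincide
        for ps in structures:
            assert np.abs(_forward_matrix(ps, layout, m1.weights)
                          - _forward_matrix(ps, layout, m2.weights)).max() < 1e-8

    def test_deterministic_convex_solution(self, tiny_setup, layout, spec,
                                           species, teacher):
        geos, structures = tiny_setup
        Hs = [_forward_matrix(ps, layout, teacher.weights) for ps in structures]
        tgt = TrainingTarget("hamiltonian", hamiltonians=Hs)
        w1 = fit_model1(structures, tgt, LossConfig(seed=1, ridge_lambda=1e-10),
                        layout, spec, species).weights.as_vector()
        w2 = fit_model1(structures, tgt, LossConfig(seed=99, ridge_lambda=1e-10),
                        layout, spec, species).weights.as_vector()
        assert np.abs(w1 - w2).max() < 1e-10

    def test_teacher_recovery_small(self, layout, species):
        """Projected teacher weights are recovered from a modest realizable
        problem (reduced feature space keeps this fast)."""
        spec = RadialBasisSpec(n_max=3, l_max=2)
        geos = make_geometries("perturbed", 30, seed=5, n_carbon=2)
        structures = prepare_structures(geos, spec, layout, species)
        teacher = project_teacher(TeacherModel.random(3, spec, layout, species),
                                  structures)
        tgt = teacher_targets(structures, teacher, "hamiltonian")
        m = fit_model1(structures, tgt, LossConfig(ridge_lambda=1e-12),
                       layout, spec, species)
        wt = teacher.weights.as_vector()
        err = np.linalg.norm(m.weights.as_vector() - wt) / np.linalg.norm(wt)
        assert err < 1e-6


class TestIndirectLosses:
    def test_exact_spectrum_zero_loss(self, tiny_setup, layout, spec, species,
                                      teacher):
        geos, structures = tiny_setup
        tgt = teacher_targets(structures, teacher, "eigenvalues")
        assert loss_model2(teacher.weights, structures, tgt, layout) < 1e-16

    def test_isospectral_invariance(self, tiny_setup, layout, spec, species,
                                    teacher):
        """Replacing targets by eigenvalues of Q H Q^T changes nothing:
        the under-constraint motivating charge supervision."""
        geos, structures = tiny_setup
        rng = np.random.default_rng(2)
        tgt = teacher_targets(structures, teacher, "eigenvalues")
        rotated_eigs = []
        for ps, e in zip(structures, tgt.eigenvalues):
            H = _forward_matrix(ps, layout, teacher.weights)
            Q, _ = np.linalg.qr(rng.normal(size=H.shape))
            rotated_eigs.append(np.sort(np.linalg.eigvalsh(Q @ H @ Q.T)))
        tgt2 = TrainingTarget("eigenvalues", eigenvalues=rotated_eigs)
        l1 = loss_model2(teacher.weights, structures, tgt, layout)
        l2 = loss_model2(teacher.weights, structures, tgt2, layout)
        assert abs(l1 - l2) < 1e-16

    def test_two_level_arithmetic(self, layout, spec, species):
        """eps_pred = (0, 1), eps_target = (0, 2) -> MSE 0.5."""
        geo = make_geometries("chain", 1, seed=0, n_carbon=1)[0]
        structures = prepare_structures([geo], spec, layout, species)
        ps = structures[0]
        w = ModelWeights.zeros(layout, spec, species)
        H_pred = _forward_matrix(ps, layout, w)  # all-zero 9x9
        tgt_e = np.zeros(ps.n_orbitals)
        tgt_e[-1] = 2.0  # predicted top level is 0 -> contributes (0-2)^2
        tgt = TrainingTarget("eigenvalues", eigenvalues=[np.sort(tgt_e)])
        got = loss_model2(w, structures, tgt, layout)
        assert np.isclose(got, 4.0 / ps.n_orbitals, atol=1e-14)

    def test_model3_reduces_to_model2_at_zero_weight(self, tiny_setup, layout,
                                                     spec, species, teacher):
        geos, structures = tiny_setup
        tgt = teacher_targets(structures, teacher, "eigenvalues_and_charges")
        cfg = LossConfig(mode="eps_q", charge_weight=0.0)
        l3 = loss_model3(teacher.weights, structures, tgt, cfg, layout)
        l2 = loss_model2(teacher.weights, structures, tgt, layout)
        assert np.isclose(l3, l2, atol=1e-16)

    def test_model3_charge_term_arithmetic(self, tiny_setup, layout, spec,
                                           species, teacher):
        geos, structures = tiny_setup
        tgt = teacher_targets(structures, teacher, "eigenvalues_and_charges")
        # shift every target charge by 0.1: charge term = 0.01 * charge_weight
        shifted = TrainingTarget("eigenvalues_and_charges",
                                 eigenvalues=tgt.eigenvalues,
                                 charges=[q + 0.1 for q in tgt.charges])
        cfg = LossConfig(mode="eps_q", charge_weight=1.0)
        l3 = loss_model3(teacher.weights, structures, shifted, cfg, layout)
        assert np.isclose(l3, 0.01, atol=1e-12)


class TestGradients:
    def test_analytic_vs_finite_difference_on_random_6x6(self):
        """Eigenvalue and density-response derivatives agree with central
        finite differences to 1e-8 on random 6x6 symmetric matrices."""
        rng = np.random.default_rng(6)
        for trial in range(5):
            H = rng.normal(size=(6, 6))
            H = H + H.T
            e_t = np.sort(rng.normal(size=6))
            q_t = rng.normal(size=6)
            occ = np.array([2.0, 2.0, 2.0, 0.0, 0.0, 0.0])

            def loss_of(Hm):
                eps, C = np.linalg.eigh(Hm)
                pops = (C ** 2) @ occ
                return float(np.sum((eps - e_t) ** 2)
                             + np.sum((pops - q_t) ** 2))

            # analytic gradient
            eps, C = np.linalg.eigh(H)
            G = (C * (2 * (eps - e_t))) @ C.T
            g_pop = 2 * ((C ** 2) @ occ - q_t)
            A = 2.0 * C.T @ (g_pop[:, None] * C)
            df = occ[:, None] - occ[None, :]
            de = eps[:, None] - eps[None, :]
            mask = np.abs(df) > 1e-12
            Cm = np.where(mask, A * df / np.where(mask, de, 1.0), 0.0)
            G = G + 0.5 * (C @ Cm @ C.T)
            G = 0.5 * (G + G.T)
            # central FD over symmetric perturbations
            h = 1e-5
            for _ in range(6):
                V = rng.normal(size=(6, 6))
                V = 0.5 * (V + V.T)
                fd = (loss_of(H + h * V) - loss_of(H - h * V)) / (2 * h)
                an = float(np.sum(G * V))
                assert abs(fd - an) < 1e-8 * max(1.0, abs(fd))

    def test_objective_gradient_fd(self, layout, species):
        spec = RadialBasisSpec(n_max=2, l_max=1)
        geos = make_geometries("perturbed", 2, seed=3, n_carbon=2)
        structures = prepare_structures(geos, spec, layout, species)
        tgt = toy_reference_targets(geos, ToyReference(), layout)
        rng = np.random.default_rng(0)
        w = ModelWeights.zeros(layout, spec, species)
        for k in w.weights:
            w.weights[k] = rng.normal(0, 0.05, w.weights[k].size)
        for mode in ("eps", "eps_q"):
            cfg = LossConfig(mode=mode)
            fun = _indirect_objective(w, structures, tgt, cfg, layout)
            x0 = w.as_vector()
            f0, g = fun(x0)
            for _ in range(3):
                d = rng.normal(size=x0.size)
                d /= np.linalg.norm(d)
                h = 1e-6
                fd = (fun(x0 + h * d)[0] - fun(x0 - h * d)[0]) / (2 * h)
                assert abs(fd - float(g @ d)) < 1e-6 * max(1.0, abs(fd))


class TestFitIndirect:
    def test_zero_iterations_returns_init(self, tiny_setup, layout, spec,
                                          species, teacher):
        geos, structures = tiny_setup
        tgt = teacher_targets(structures, teacher, "eigenvalues")
        cfg = LossConfig(mode="eps", max_iterations=0, seed=5)
        m = fit_indirect(structures, tgt, cfg, layout, spec, species,
                         init=teacher.weights)
        assert np.array_equal(m.weights.as_vector(),
                              teacher.weights.as_vector())
        assert len(m.loss_history) == 1

    def test_teacher_weights_are_functional_fixed_point(self, tiny_setup,
                                                        layout, spec, species,
                                                        teacher):
        geos, structures = tiny_setup
        tgt = teacher_targets(structures, teacher, "eigenvalues")
        assert loss_model2(teacher.weights, structures, tgt, layout) < 1e-16

    def test_loss_invariant_under_global_rotation(self, layout, spec, species,
                                                  teacher):
        from effham.rotations import random_rotation
        geos = make_geometries("perturbed", 3, seed=8, n_carbon=2,
                               rigid_motion=False)
        structures = prepare_structures(geos, spec, layout, species)
        tgt = toy_reference_targets(geos, ToyReference(), layout)
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        rot = [g.rotated(R) for g in geos]
        structures_rot = prepare_structures(rot, spec, layout, species)
        w = teacher.weights
        l0 = loss_model2(w, structures, tgt, layout)
        l1 = loss_model2(w, structures_rot, tgt, layout)
        assert abs(l0 - l1) < 1e-8

    def test_mode_validation(self, tiny_setup, layout, spec, species):
        geos, structures = tiny_setup
        with pytest.raises(ValueError):
            fit_indirect(structures, TrainingTarget("eigenvalues",
                         eigenvalues=[np.zeros(4)]),
                         LossConfig(mode="h"), layout, spec, species)


class TestValenceSelection:
    def test_large_basis_selection(self, layout):
        geo = make_geometries("chain", 1, seed=0, n_carbon=2)[0]  # 14 minimal
        n_min = layout.n_orbitals(geo)
        full = np.sort(np.random.default_rng(0).normal(size=100))
        tgt = select_valence_targets(full, None, layout, geo)
        assert tgt.n_select == n_min
        assert np.array_equal(tgt.eigenvalues[0], full[:n_min])

    def test_exact_length_identity(self, layout):
        geo = make_geometries("chain", 1, seed=0, n_carbon=2)[0]
        full = np.sort(np.random.default_rng(1).normal(
            size=layout.n_orbitals(geo)))
        tgt = select_valence_targets(full, np.zeros(geo.n_atoms), layout, geo)
        assert np.array_equal(tgt.eigenvalues[0], full)
        assert tgt.kind == "eigenvalues_and_charges"

    def test_too_few_levels_error(self, layout):
        geo = make_geometries("chain", 1, seed=0, n_carbon=2)[0]
        with pytest.raises(ValueError):
            select_valence_targets(np.zeros(5), None, layout, geo)

    def test_occupied_levels_always_retained(self, layout):
        """N_occ < n_minimal for every neutral hydrocarbon, so the lowest
        n_minimal levels contain all occupied states."""
        for fam, nc in (("chain", 2), ("chain", 5), ("ring", 6)):
            geo = make_geometries(fam, 1, seed=0, n_carbon=nc)[0]
            assert geo.n_electrons // 2 < layout.n_orbitals(geo)

    def test_large_basis_teacher_staging(self, species):
        """LBT flow: targets from an extended-layout teacher feed a
        minimal-layout model via lowest-level selection."""
        lay_min = minimal_layout()
        lay_ext = extended_layout()
        spec = RadialBasisSpec(n_max=2, l_max=1)
        geos = make_geometries("perturbed", 2, seed=12, n_carbon=2)
        big = TeacherModel.random(4, spec, lay_ext, species)
        eigs, chgs = [], []
        from effham.properties import loewdin_charges, solve_mos
        for g in geos:
            sol = solve_mos(big.hamiltonian(g), g.n_electrons)
            eigs.append(sol.energies)
            chgs.append(loewdin_charges(sol, g, lay_ext).q)
        tgts = [select_valence_targets(e, q, lay_min, g)
                for e, q, g in zip(eigs, chgs, geos)]
        merged = TrainingTarget("eigenvalues_and_charges",
                                eigenvalues=[t.eigenvalues[0] for t in tgts],
                                charges=[t.charges[0] for t in tgts],
                                n_select=tgts[0].n_select)
        structures = prepare_structures(geos, spec, lay_min, species)
        cfg = LossConfig(mode="eps_q", max_iterations=5, seed=2)
        m = fit_indirect(structures, merged, cfg, lay_min, spec, species)
        assert np.isfinite(m.loss_history[-1])
        assert m.loss_history[-1] <= m.loss_history[0]


class TestEstimator:
    def test_sklearn_interface_roundtrip(self, species):
        est = EffectiveHamiltonianModel(mode="h", n_max=2, l_max=1,
                                        ridge_lambda=1e-10)
        params = est.get_params()
        assert params["n_max"] == 2
        est2 = EffectiveHamiltonianModel().set_params(**params)
        geos = make_geometries("perturbed", 4, seed=2, n_carbon=2)
        spec = est2._spec()
        layout = minimal_layout()
        teacher = TeacherModel.random(9, spec, layout, species)
        tgt = teacher_targets(prepare_structures(geos, spec, layout, species),
                              teacher, "hamiltonian")
        est2.fit(geos, tgt)
        assert hasattr(est2, "weights_")
        preds = est2.predict(geos)
        assert np.abs(preds[0].matrix
                      - teacher.hamiltonian(geos[0]).matrix).max() < 1e-6
        with pytest.raises(AttributeError):
            EffectiveHamiltonianModel().predict(geos)

    def test_charges_sum_to_zero(self, species):
        est = EffectiveHamiltonianModel(mode="h", n_max=2, l_max=1,
                                        ridge_lambda=1e-10)
        geos = make_geometries("perturbed", 3, seed=2, n_carbon=2)
        layout = minimal_layout()
        teacher = TeacherModel.random(9, est._spec(), layout, species)
        tgt = teacher_targets(prepare_structures(geos, est._spec(), layout,
                                                 species),
                              teacher, "hamiltonian")
        est.fit(geos, tgt)
        for q in est.predict_charges(geos):
            assert abs(q.sum()) < 1e-10


class TestRidgeSelection:
    def test_grid_selection_prefers_small_lambda_on_noiseless_data(
            self, tiny_setup, layout, spec, species, teacher):
        from effham.training import select_ridge_lambda
        geos, structures = tiny_setup
        Hs = [_forward_matrix(ps, layout, teacher.weights) for ps in structures]
        lam = select_ridge_lambda(structures,
                                  TrainingTarget("hamiltonian",
                                                 hamiltonians=Hs),
                                  layout, spec, species, seed=1)
        # realizable noise-free targets: weak regularization must win
        assert lam <= 1e-6

    def test_requires_hamiltonian_targets(self, tiny_setup, layout, spec,
                                          species):
        from effham.training import select_ridge_lambda
        geos, structures = tiny_setup
        with pytest.raises(ValueError):
            select_ridge_lambda(structures,
                                TrainingTarget("eigenvalues",
                                               eigenvalues=[np.zeros(4)]),
                                layout, spec, species)
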