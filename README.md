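# effham

Machine-learned effective Hamiltonians for molecular excited states.

`effham` implements a hybrid machine-learning / quantum-chemistry pipeline
for hydrocarbon molecules: a **symmetry-adapted linear model** predicts an
effective single-particle Hamiltonian H̃ in an implicit orthonormal minimal
basis (H: 1s; C: 1s, 2s, 2p) directly from the molecular geometry, and the
eigenpairs of H̃ feed physics-based downstream models — a **simplified
Tamm–Dancoff (sTDA)** excited-state solver and a **second-order-cumulant
vibronic-spectrum** workflow. It is aimed at method developers who want a
self-contained, fully tested reference implementation of this architecture,
with synthetic data generators so that no quantum-chemistry package is
needed to train, test or reproduce any number.

## The model

Every Hamiltonian pair block is decomposed into irreducible spherical-tensor
components H_ij^{pτλμ} via real Clebsch–Gordan coefficients and modeled
linearly with equivariant two-center descriptors of matching symmetry,

    H_ij^{pτλμ} = Σ_q  w_q^{pτλ} ξ_q^{τλμ}(A_ij),

where ξ are Clebsch–Gordan couplings of a species-resolved neighbor density
with the pair density c_nlm(A_ij) = R_n(r) Y_lm(r̂) inside a smooth cutoff.
Because the weights are invariant scalars, H̃(R·A) = D(R) H̃(A) D(R)ᵀ holds
to machine precision for any rotation, reflection or atom relabeling, and
blocks of pairs beyond the cutoff are exactly zero (linear-scaling
prediction).

Three training modes are provided:

* **model 1** (`mode="h"`) — closed-form ridge regression on reference
  Hamiltonian matrices;
* **model 2** (`mode="eps"`) — gradient-based training on sorted MO energies
  obtained by diagonalizing H̃ (analytic Hellmann–Feynman gradients);
* **model 3** (`mode="eps_q"`) — MO energies plus Löwdin charges
  q_A = Z_A − 2Σ_{μ∈A}Σ_{n occ} C̃²_μn (density-matrix response gradients),
  which removes the eigenvector-gauge freedom that makes eigenvalue-only
  training produce unphysical charges. Large-basis references are handled by
  selecting the lowest n_minimal eigenvalues as targets.

sTDA builds A_{ia,jb} = δδ(ε_a−ε_i) + 2Σq_ia γ^K q_jb − Σq_ij γ^J q_ab from
Löwdin transition charges and Mataga–Nishimoto–Ohno–Klopman kernels,
truncates the CI space by an energy window with perturbative selection, and
solves AX = ΩX. The vibronic pipeline is c_UU(t) → J(ω) → g(t) → absorption
spectrum with Gaussian static disorder; see `docs/methods.md` for all
conventions.

## Worked example

Train on synthetic tight-binding references and predict excitations:

```python
import numpy as np
from effham import EffectiveHamiltonianModel, minimal_layout, solve_mos
from effham.synthetic import make_geometries, ToyReference, toy_reference_targets
from effham.stda import excitations

layout = minimal_layout()
train = make_geometries("perturbed", 40, seed=21, n_carbon=3)   # jittered C3H8
targets = toy_reference_targets(train, ToyReference(), layout)  # eps + charges

model = EffectiveHamiltonianModel(mode="eps_q", max_iterations=300, seed=3)
model.fit(train, targets)

mol = make_geometries("chain", 1, seed=0, n_carbon=3)[0]
sol = solve_mos(model.predict([mol])[0], mol.n_electrons)
res = excitations(sol, mol, layout, n_states=3, energy_threshold_ev=None)
print("charges (e):", np.round(model.predict_charges([mol])[0], 3))
print("lowest excitations (eV):", np.round(res.energies, 2))
```

Output:

```
charges (e): [-0.068 -0.01  -0.068  0.017  0.015  0.023  0.018  0.017  0.017  0.023
  0.015]
lowest excitations (eV): [28.25 29.73 31.03]
```

The charges are small, carbon-negative, and sum to zero (neutral molecule);
the excitation energies are tens of eV because the tight-binding toy
reference has minimal-basis-scale alkane gaps — the numbers validate the
pipeline, not chemistry (`energy_threshold_ev=None` disables the CI window,
which defaults to 10 eV and would otherwise exclude all of this toy's
configurations). The same flow works from the shell:

```bash
effham make-fixtures --family perturbed --n-carbon 3 --target toy --out fix.h5
effham train --mode eps-q --targets fix.h5 --out model.h5
effham predict --model model.h5 --xyz mol.xyz
effham stda --model model.h5 --xyz mol.xyz --n-states 5
effham spectrum --input trajectory.csv --damp-ps 10 --disorder-fwhm-cm1 400
```

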