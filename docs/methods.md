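# Methods

`effham` learns an effective single-particle Hamiltonian H̃ for hydrocarbon
molecules in an *implicit, orthonormal minimal basis* (H: 1s; C: 1s, 2s, 2p)
and uses its eigenpairs to drive two downstream physics pipelines: a
simplified Tamm–Dancoff (sTDA) excited-state solver and a second-order
cumulant vibronic-spectrum workflow. This note records the model, its
assumptions, the numerical choices, and what the synthetic test data do and
do not establish.

## The model

### Symmetry-adapted linear regression of Hamiltonian blocks

The matrix H̃ is assembled from per-atom-pair blocks. Each block between
shells with angular momenta (l, l′) is decomposed into irreducible
spherical-tensor components of order λ ∈ {|l−l′| … l+l′} through real
Clebsch–Gordan tables (generated exactly with rational arithmetic and
transformed once to the real-spherical-harmonic basis; orthogonality is
verified to 1e-12 at build time). Each component H^{pτλμ} — where p labels
the element pair and shell pair, and τ the permutation channel — is a linear
function of equivariant descriptors with the same (τ, λ) symmetry and the
same O(3) parity σ = (−1)^{l+l′+λ}:

    H_ij^{pτλμ} = Σ_q w_q^{pτλ} ξ_q^{τλμ}(A_ij)

Intercepts are fixed to zero. Because every weight is an invariant scalar,
H̃ is exactly equivariant: rotating (or reflecting, or relabeling) the
molecule transforms H̃ by the corresponding block Wigner (and permutation)
matrices to machine precision, and eigenvalues are invariant.

### Descriptors

The pair density c_nlm(A_ij) = R_n(r_ij) f_cut(r_ij) Y_lm(r̂_ij) uses real
spherical harmonics (Condon–Shortley, m = −l…l) and Gaussian radial
functions centered on a uniform grid r_n = n·r_c/(n_max+1). The effective
radial width combines half the grid spacing with an atomic smearing width
(`gaussian_width`, default 0.2 Å), i.e. σ_eff = sqrt((Δ/2)² + σ_atom²): a
grid of narrow Gaussians would leave distance windows that no channel can
see, which makes regression ill-posed; the smeared family keeps full radial
coverage while retaining the SOAP-style smearing parameter. A cosine-squared
taper over the outer 0.5 Å makes all descriptors vanish continuously at the
cutoff (default 4.5 Å), so pairs beyond the cutoff get *exactly* zero blocks
and prediction cost scales linearly in atom count at fixed cutoff.

Summing pair densities over neighbors gives the species-resolved neighbor
density; Clebsch–Gordan coupling of the neighbor density with the pair
density produces the two-center one-neighbor channels, the pure pair
channels are kept as the lowest-order channels, and on-site channels couple
the neighbor density with itself (plus a constant channel so isolated-atom
levels are representable). For like-element pairs the i↔j permutation is
enforced exactly by splitting both features and targets into normalized
symmetric/antisymmetric combinations (τ = ±1) with the analytically known
swap phase (−1)^{l+l′−λ}; unlike pairs are keyed by the ordered species pair.
Default discretization: n_max = 6, l_max = 4, output order λ ≤ 2 (all a
Hamiltonian over s and p shells can use).

### Identifiability and the teacher oracle

The feature map has *structural gauge directions*: channel combinations
whose output vanishes on entire families of structures (for example, when
the only neighbor contributing to an outer radial channel of the density on
i is the partner j itself, coupled channels collapse onto Gaunt-proportional
combinations). Weights are therefore identifiable only modulo this null
space — an intrinsic property of the descriptor, not of the fitting
algorithm. The synthetic teacher generator consequently projects its random
weights onto the well-resolved subspace of the training design (singular
directions with s ≥ 1e-2·s_max, a fixed design constant of the generator)
before producing targets; recovery of the projected weights is then a
well-posed oracle, and teacher targets remain exactly realizable either way.

## Training

* **Direct (model 1).** Ridge regression of the irrep components of
  reference Hamiltonian matrices, solved per block family in closed form by
  SVD (w = V·s/(s²+λ_r)·Uᵀy). Convex and deterministic; with λ_r = 0 and a
  rank-deficient design a pseudo-inverse is used and a warning emitted. The
  penalty uses the plain sum-of-squares convention so the documented
  λ_r = 1e-12 behaves as an absolute regularization scale.
* **Indirect (model 2).** Mean squared error of the sorted eigenvalues of
  H̃ against sorted reference MO energies (lowest n_select levels when the
  reference basis is larger). Minimized by L-BFGS with analytic gradients:
  Hellmann–Feynman terms dε_n/dH = v_n v_nᵀ.
* **Indirect with charges (model 3).** Adds `charge_weight` (default 1.0)
  times the per-atom Löwdin-charge MSE; the objective is the *plain sum*
  MSE_ε + w_q·MSE_q — no variance standardization, which on realistic
  targets over-weights charges by orders of magnitude because the eigenvalue
  variance is inflated by deep core levels. Charge gradients use first-order
  density-matrix response: only occupied–virtual pairs contribute
  (dP ∝ (f_n−f_m)/(ε_n−ε_m)), which makes the expression stable under
  occupied–occupied degeneracies. Analytic gradients are validated against
  central finite differences in the test suite.
* **Staging.** Models 2/3 start from the model-1 ridge solution when
  Hamiltonian targets exist. Without them, the joint eigenvalue+charge loss
  from a cold random start is dominated by the charge term and reliably
  traps the optimizer far from the eigenvalue solution, so model 3 first
  runs an eigenvalue-only phase and then switches the full loss on. The
  large-basis-target (LBT) path keeps the minimal-basis model structure and
  selects the lowest n_minimal reference levels (all occupied valence states
  plus the lowest virtuals) as targets.
* When no ridge strength is specified a priori, `select_ridge_lambda`
  searches the grid 1e-2 … 1e-10 with a 90/10 train/validation split scored
  on held-out Hamiltonian MSE; the documented default for direct use is
  1e-8.
* Eigenvalues are paired to targets by ascending order; a 1e-10 diagonal
  jitter is applied only if the eigensolver itself fails. Closed-shell
  occupation N_occ = Σ Z_A/2 is required; a partially occupied degenerate
  frontier shell (toy C60) is occupied fractionally and uniformly so the
  density matrix keeps the molecular point-group symmetry.

## sTDA

The singlet TDA matrix uses the monopole approximation,

    A_{ia,jb} = δδ(ε_a−ε_i) + 2 Σ_AB q_ia^A γ^K_AB q_jb^B − Σ_AB q_ij^A γ^J_AB q_ab^B,

with Löwdin transition charges q_pq^A = Σ_{μ∈A} C̃_μp C̃_μq and
Mataga–Nishimoto–Ohno–Klopman kernels
γ^J = (R^β + (a_x·η̄)^{−β})^{−1/β}, γ^K = (R^α + η̄^{−α})^{−1/α}
(α = 1.42 + 0.48·a_x, β = 0.2 + 1.83·a_x, a_x = 0.2; chemical hardnesses
are Pearson-scale IP−EA values, all configurable). Both kernels are finite
at R = 0 and tend to 1/R at large separation; for the Coulomb channel the
small exponent β makes that approach logarithmically slow — a property of
the parametrization, not a bug. The CI space keeps occupied→virtual
configurations whose diagonal element lies below an energy window (default
10 eV) and perturbatively promotes excluded configurations whose summed
second-order coupling to the retained set exceeds 1e-4 Ha; with the window
disabled the solver reproduces dense diagonalization of the full monopole
matrix identically. Oscillator strengths are not computed — the basis is
implicit, so no dipole integrals exist; the vibronic pipeline needs only
excitation energies.

## Vibronic spectra

From an excitation-energy trajectory U(t) (uniform grid, fs/eV):

1. Fluctuation autocorrelation c_UU(t) (unbiased lag estimator via FFT;
   c_UU(0) equals the sample variance).
2. Cosine-squared damping to exactly zero over a window (default 10 ps).
3. Spectral density J(ω) = βω·∫₀^∞ c_UU(t)cos(ωt)dt — i.e. the (βω/2)
   harmonic prefactor applied to the full-axis transform of the even
   autocorrelation. This normalization satisfies
   ∫J(ω)·2/(πβω)dω = c_UU(0) and makes the single-mode Huang–Rhys factor
   S = λ/ω₀ with λ = (1/π)∫J/ω dω. A tanh(βω/2) prefactor variant is
   available behind a flag; it changes peak weights, not positions.
4. Line-shape function
   g(t) = (1/π)∫dω J/ω²[coth(βω/2)(1−cos ωt) − i sin ωt], so g(0) = 0 and
   g′(0) = −iλ/ħ. The quadrature restricts ω to the support of J
   (cumulative-contribution cutoff 1e-6) and ~0.75 cm⁻¹ resolution, far
   below any linewidth the damping window can produce.
5. Homogeneous spectrum σ(ω) ∝ Re∫₀^T e^{−i(ω−Ē)t/ħ} e^{−g(t)} dt on a
   ~1 cm⁻¹ grid (near-transform-limited lines must be resolved), normalized
   to unit maximum; if e^{−g} has not decayed, an automatic cosine window is
   applied with a warning. With these conventions a single mode of
   Huang–Rhys factor S produces Poisson progression bands at Ē + kω₀ with
   band-area ratio I₁/I₀ = S at low temperature — the conformance oracle
   used in the tests. Band *areas*, not peak heights, are the
   Franck–Condon weights: the 0-0 line is transform-limited while higher
   bands carry dephasing width.
6. Static disorder: exact Gaussian convolution by default (fwhm parameter);
   a seeded Monte-Carlo shift-averaging mode reproduces it in the
   large-sample limit.
7. Windowed averaging over non-overlapping trajectory segments gives a mean
   and a 95% normal-approximation confidence band.

Trajectory transforms decimate the time grid to ≤ 2 fs steps (Nyquist
≈ 1.6 eV, far above the spectral window) to bound cost.

## Synthetic data: what it shows and what it does not

The generators provide three target families without any quantum-chemistry
dependency:

* **Teacher models** — random weights in the model class itself; targets are
  exactly realizable, which validates solver correctness (recovery, zero
  loss at the generator) but says nothing about how well the class fits real
  electronic structure.
* **A Slater–Koster tight-binding reference** — exponential-decay hoppings
  (Harrison sign conventions) with shell-resolved on-site energies, tuned
  once to give bounded, gapped, smoothly distance-dependent spectra and
  small physically-signed charges for hydrocarbon-like topologies
  (alkane-chain gaps of tens of eV in a minimal-basis sense, ring π gaps of
  a few eV). It shares the *symmetry and smoothness* of mean-field targets,
  not their values, and it is deliberately outside the linear model class:
  residual training loss stays positive, and eigenvalue-only training leaves
  the eigenvector gauge unconstrained — reproducing the qualitative failure
  (order-1 e charge errors) that charge supervision repairs.
* **Geometries** — seeded alkane-like chains, rings, jittered conformers
  (σ = 0.03 Å, with random rigid motions), and a programmatic truncated
  icosahedron C60 (uniform 1.44 Å edges) whose 60 equivalent atoms force
  exactly zero Löwdin charges for any equivariant model.
* **Energy trajectories** — sums of harmonic modes with seeded phases
  (analytic autocorrelation Σ A_k²cos(ω_k t)/2) or an Ornstein–Uhlenbeck
  component with exponential autocorrelation.

Passing tests on these data establish internal consistency, symmetry
exactness, solver correctness and the qualitative training phenomenology;
they do not establish chemical accuracy against ab initio references, which
would require external datasets.

## Numerical choices and limitations

* Units: Å on disk, Bohr/Hartree internally for electronic structure,
  eV/cm⁻¹ for reported energies (1 Ha = 27.211386245988 eV,
  1 eV = 8065.544 cm⁻¹).
* Orbital order within an atom is shell-major with m = −l…+l; MO signs are
  fixed by making each column's largest-magnitude coefficient positive.
* Neutral closed-shell systems only; elements H and C in the default
  layout (N/O constants are present but untrained).
* No overlap matrix is modeled (the basis is implicitly orthonormal);
  `lowdin_orthogonalize` is provided to map explicit-basis references
  (H, S) → S^{−1/2}HS^{−1/2} before use as targets.
* The indirect losses are non-convex; L-BFGS from the documented staged
  initializations is deterministic for a given seed but global optimality is
  not guaranteed.
* Problem sizes in the test-suite and acceptance runs (hundreds of jittered
  C2–C4 conformers, 2^15-step trajectories) were chosen as the smallest
  sizes at which the measured quantities are estimator-noise-limited below
  the stated tolerances.
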