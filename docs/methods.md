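# Methods

This note documents the model, conventions and numerical choices behind
`anharmvoa`. Everything here is implemented and exercised by the test
suite; no empirical statement below goes beyond what the tests and
`scripts/acceptance.py` compute.

## Vibrational model

The potential is a quartic expansion in reduced (dimensionless) normal
coordinates,

    V = 1/2 Σ_i ω_i q_i² + 1/6 Σ_ijk f_ijk q_i q_j q_k
        + 1/24 Σ_ijkl f_ijkl q_i q_j q_k q_l ,

with ω and all force constants in cm⁻¹. Quartic constants are stored
semidiagonally (at least two equal indices) — the set obtainable from
single-mode double displacements; fully off-diagonal quartics read as
zero. The matrix-element convention is fixed by ⟨0|q_i|1_i⟩ = 1/√2
(so q = (a + a†)/√2 and p = i(a† − a)/√2 with [q, p] = i).

Electric and magnetic property surfaces (μ, m, α, G′, A) are Taylor
polynomials of order ≤ 3 in q, in atomic units per reduced coordinate.
The magnetic dipole is expanded in the conjugate momenta,
m = m₀ + Σ A_i p_i + Σ (∂A_i/∂q_j) p_i q_j + ½ Σ (∂²A_i/∂q_j∂q_k) p_i q_j q_k,
so its leading derivative is the atomic axial tensor, while G′ and A
(like μ and α) expand in q. Same-mode p·q products are Weyl-symmetrized,
½(pq + qp), which keeps the operators Hermitian; the phase convention
makes electric-type transition moments real and magnetic ones purely
imaginary, so rotational strengths R = Im(⟨μ⟩*·⟨m⟩) are real.

A modelling restriction inherited from the data model: the mixed second
derivative of the magnetic surface, ∂A_i/∂q_j, is stored as a symmetric
(i, j) tensor. The generator emits symmetric tensors and the
finite-difference module symmetrizes, reporting the pre-symmetrization
spread as a diagnostic.

## VPT2 energies

Ordering: cubic terms enter the perturbation series at second order,
semidiagonal quartics at first order. The level shifts then take the
Dunham form

    E(v) − E(0) = Σ_i ω_i v_i + Σ_{i≤j} χ_ij [(v_i+½)(v_j+½) − ¼] ,

with the anharmonicity matrix assembled in a partial-fraction form whose
resonance-prone denominators are isolated one per term:

    χ_ii = f_iiii/16 − Σ_k (f_iik²/32) [ 4/ω_k + 1/(2ω_i+ω_k) − 1/(2ω_i−ω_k) ]

    χ_ij = f_iijj/4 − Σ_k f_iik f_jjk/(4ω_k)
           − Σ_k (f_ijk²/8) [ 1/(ω_i+ω_j+ω_k) − 1/(ω_i+ω_j−ω_k)
                              + 1/(ω_k+ω_i−ω_j) + 1/(ω_k+ω_j−ω_i) ]
           + Σ_a B_a ζ_a,ij² (ω_i/ω_j + ω_j/ω_i)        (i ≠ j)

The last line is the leading Coriolis (zeroth-rotational-quanta Watson)
contribution; it affects energies only, never intensities. The closed
forms were cross-checked during development against an explicit
sum-over-states Rayleigh–Schrödinger second-order calculation in the
harmonic-oscillator product basis (the constant anharmonic ZPE term,
which the Dunham form cannot carry, cancels in every E(v) − E(0)).

## Resonances

Fermi candidates (i ≤ j → k, ω_i + ω_j ≈ ω_k) pass three criteria
(defaults): |detuning| ≤ 200 cm⁻¹; f_ijk⁴ ≥ 64(1+δ)²·detuning²; and
|f_ijk| ≥ 0.02·|detuning²(1+δ)|. The Kronecker weight δ is applied to
the doubled (overtone) index i = j by default, with a `verbatim` switch
placing it on j = k instead; the third criterion deliberately mixes
cm⁻¹ against cm⁻² — it is implemented in that printed form, with an
option to disable it. Every candidate's numeric criterion values are
retained, not just flags.

Darling–Dennison candidates are pairs of fundamentals (1–1) or pairs of
two-quanta states (2–2) with detuning ≤ 200 cm⁻¹ and an effective
coupling |⟨a|H̃|b⟩| ≥ 10 cm⁻¹; 1–1 pairs additionally require a
second-order wavefunction coefficient max|c²| ≥ 0.03 (the
intensity-singularity guard). The coupling is evaluated as a numerically
exact second-order Van Vleck (contact-transformation) element,

    ⟨a|H̃|b⟩ = ⟨a|V₃+V₄|b⟩ + ½ Σ_w ⟨a|V₃|w⟩⟨w|V₃|b⟩ [1/(E_a−E_w) + 1/(E_b−E_w)] ,

summed over harmonic intermediates outside the model space, rather than
from transcribed closed forms — same second-order content, fewer
transcription risks.

## GVPT2: deperturbation and the variational step

Flagged Fermi terms are removed wherever their denominator appears in χ
(the partial-fraction form makes this a per-term skip), and the
corresponding wavefunction coefficients are set exactly to zero.
Resonant states are grouped by transitive closure over flagged
interactions; each connected block is diagonalized with deperturbed
VPT2 energies on the diagonal, cubic elements ⟨a|V₃|b⟩ on flagged Fermi
links and contact-transformed couplings on flagged DD links. Pairs that
share a block only through chaining keep a zero off-diagonal — their
interaction remains perturbative. A configurable cap (30 states) guards
against runaway polyads. Near the detection threshold the removed
perturbative term and the small variational correction agree closely,
so energies are continuous to well under 0.5 cm⁻¹ across the switch.

## Transition moments

VPT2 wavefunctions are not normalized; a property moment is

    ⟨X⟩_{I,F} = ⟨ψ_F|X|ψ_I⟩ / √(⟨ψ_F|ψ_F⟩⟨ψ_I|ψ_I⟩) .

The numerator is split by operator order (X⁰ = equilibrium value +
first derivatives; X¹ = second; X² = third) and wavefunction order
(0/1/2), producing the eleven-term decomposition (term 1 harmonic,
terms 2/5 pure electrical, 3/4/6/7/10 mechanical, 8/9 mixed, 11 the
renormalization of term 1). Normalization is applied exactly with
N² = (1 + ⟨ψ_F¹|ψ_F¹⟩)(1 + ⟨ψ_I¹|ψ_I¹⟩) — the second-order-consistent
norm (the c² contribution to the norm is fourth order) — and term 11 is
defined as term1·(1/N − 1): the terms then sum to the normalized moment
identically, while term 11 reduces to the familiar
−½⟨F⁰|X⁰|I⁰⟩(⟨F¹|F¹⟩+⟨I¹|I¹⟩) overlap correction at second order.

The decomposition truncates at combined (wavefunction + operator) order
two. One consequence, confirmed against the variational oracle: with
sizable quartic constants, products of second derivatives with
quartic-driven wavefunction components (combined order three) are the
leading omission, so the moment error grows linearly with the quartic
scale. This is a property of the method, not of the implementation, and
it motivates the modest default quartic scale of the generator (below).

For states in a variational block, moments (and their decompositions)
are computed toward the deperturbed states and rotated by the block
eigenvectors.

## Observables

IR/VCD: D = |⟨μ⟩|², R = Im(⟨μ⟩*·⟨m⟩), g = 4R/D; the IR and VCD sticks
carry a common ν prefactor so their ratio is g.

Raman/ROA (far from resonance, 532 nm excitation, SCP backscattering):
invariants a = Tr α̃/3, β(α)² = ½(3 α̃:α̃ − (Tr α̃)²), aG′,
β(G′)² = ½(3 α̃:G̃′ − Tr α̃ Tr G̃′) and
β(A)² = (ω_exc/2) Σ α̃_αβ ε_αγδ Ã_γδβ (ω_exc in hartree). Sticks:
Raman ∝ 4(45a² + 7β(α)²), ROA ∝ (96/c)(β(G′)² + β(A)²/3), with
CID = ROA/Raman. The absolute scale is arbitrary (an instrument
constant in experiments); only ratios and relative intensities are
contract-bearing. The scattered-photon factor ν₀(ν₀−ν)³ is applied by
default and cancels in the CID; thermal populations are not applied
(0 K sticks). Both are switchable.

Assignment: an eigenstate is labelled by its leading zeroth-order
configuration (F_i, O_i, C_ij) when the squared eigenvector weight
exceeds 0.80, otherwise "mixed" with the top contributors listed.

## Spectra and similarity

Sticks are broadened with Lorentzians of 8 cm⁻¹ FWHM (area = stick
intensity, peak = 2I/(π·FWHM)) on a uniform grid (default 1 cm⁻¹,
trapezoidal integration). The similarity factor

    s(a) = ∫S_cal(aω)S_exp(ω)dω / √(∫S_cal²(aω)dω ∫S_exp²(ω)dω)

is maximized over the frequency-scaling factor a ∈ [0.95, 1.05] by a
coarse scan refined with bounded scalar minimization (tolerance 1e-4);
s(1) is reported alongside. s = 1 means identical spectra up to a
positive scale; the overlap functional is maximized (a "minimum"
overlap would not make s = 1 optimal). Sign-carrying spectra (VCD, ROA)
use the same formula without absolute values, so wrong signs lower s.

## Finite differencing

The two-step protocol: cubic f_ijk from central differences of analytic
Hessians over ±one displacement per mode (averaged over the
permutation-equivalent displacement choices, with the spread reported);
semidiagonal quartics f_iijk from the symmetric second difference along
mode i. Property second/semidiagonal-third derivatives come from the
identical stencils applied to analytic first-derivative tensors. The
displacement is specified mass-weighted (default 0.01 amu^1/2 Å) and
converted per mode by q = Q·√(4π²cω/h), so the reduced step grows with
√ω (0.0545 at 1000 cm⁻¹). Central differences are exact through the
stencil's polynomial order, so the generator's polynomial surfaces are
recovered to rounding error; on smooth non-polynomial surfaces the
error falls second order in the step. Evaluators must hold the
normal-mode phase fixed across displacements — sign flips between
displaced evaluations of near-degenerate modes are the classic failure
mode of this protocol and are the evaluator's contract to prevent.

## Synthetic systems

The generator emulates the inputs a quartic anharmonic calculation
would provide, without any electronic-structure run:

* ω drawn uniformly from a configurable window (default 700–3100 cm⁻¹);
  resonance plans pin ω's to realize requested detunings exactly.
* cubic and semidiagonal quartic constants from zero-mean normals with
  default scales 20 and 6 cm⁻¹ — ratios |f|/ω ≤ ~0.1, the perturbative
  regime where VPT2 is meaningful; diagonal quartics are kept positive
  so every single-mode direction of the truncated potential is bounded.
* property surfaces are exact polynomials (order ≤ 3) with coefficient
  scales 0.1/0.02/0.004 a.u. per derivative order — the ~5× fall-off
  mimics the usual hierarchy of electrical anharmonicity and makes
  finite-difference recovery exactly testable.
* Fermi plans set f_ijk directly; 1–1 DD plans plant f_iiij = 8K, whose
  direct quartic element between the two fundamentals is exactly K.
* `mirror_image` negates the pseudo-tensors (m, G′, A) at every order:
  enantiomer pairs then give exactly opposite VCD/ROA and identical
  IR/Raman, to rounding.

What the generator does **not** emulate: realistic mode-density and
force-constant correlations of actual molecules (e.g. a camphor-like
fingerprint), solvent effects, or mode-specific intensity patterns.
Passing tests therefore demonstrate the correctness of the perturbative
machinery and its internal consistency, not predictive accuracy for any
real spectrum.

For oracle cross-validation ensembles the ω window is placed high
(1600–2800 cm⁻¹) so that no ω_i + ω_j can approach any ω_k (margin
≥ 400 cm⁻¹ by construction) — a non-resonant ensemble by design rather
than by rejection — with cubic scale 15 and quartic scale 1 cm⁻¹. The
rationale: the comparison is meant to validate the implementation, not
VPT2's convergence at arbitrary couplings (which no second-order
method could pass), so the ensemble must sit where the method's
intrinsic truncation terms are an order of magnitude below the
comparison tolerances. Those truncation terms were identified against
the oracle during development: second-order quartic energy
contributions and second-derivative × quartic-driven moment terms
(both linear in the quartic scale, hence quartic ≪ cubic shifts), and
fourth-order cubic residuals on worst-case states and weak
overtone/combination moments (growing as the square of the cubic
scale, which bounds the cubic scale in turn). Within the chosen
regime the cubic machinery agrees with the oracle to ~10⁻⁴ cm⁻¹.

## Model-system document

Systems serialize to a single JSON document (`ModelSystem.save/load`),
schema version 1, with keys `modes` (omega list, labels), `cubic` and
`quartic` (maps from space-separated 1-based index strings to cm⁻¹
values; canonical sorted indices; quartic semidiagonal only),
`surfaces` (per tensor: `value0`, `d1`, `d2`, nested lists in atomic
units; `d3` as an index-keyed map; `conjugate` flag), optional
`coriolis` (`zeta`, `rotational_constants`) and free-form `metadata`
(the generator records its seed and random-stream algorithm there).
Indices are 1-based in files, 0-based in memory. Round trips are
lossless at full float precision (shortest round-trip repr).

## The variational oracle

Independent brute-force reference for ≤ 3 modes: the quartic
Hamiltonian in a direct-product HO basis truncated by **total** quanta
(default 20; total-quanta truncation converges faster per basis
dimension than per-mode truncation for coupled modes), dense
symmetric eigensolve, eigenvector phases fixed by a positive leading
component. Convergence is asserted by re-solving with +5 quanta and
requiring the low-lying levels to move less than 0.1 cm⁻¹ (tighter
tolerances are used where the comparison itself is tighter). Ladder
operators are built as dense matrices — no code shared with the
perturbative engine's sparse ladder algebra — so energies and operator
matrix elements are a genuine cross-check. Note that the oracle solves
the *truncated* potential exactly: for the quartic truncation of a
Morse oscillator its fundamental sits ~15 cm⁻¹ above the Morse value,
while VPT2 reproduces the Morse levels exactly through a second-order
cancellation — both behaviors are asserted in the tests.

## Numerical choices and degenerate inputs

* Exact zero resonance denominators not covered by a flagged resonance
  raise immediately with a threshold-review message (at zero detuning
  the coupling thresholds vanish, so any nonzero coupling is flagged).
* Degenerate harmonic frequencies are accepted as input; no symmetry
  blocking is attempted.
* Variational blocks larger than 30 states raise rather than
  diagonalize silently.
* All randomness flows through `numpy.random.default_rng(seed)` (PCG64,
  recorded in system metadata); equal seeds give bit-identical systems.
* Spectra: uniform ascending grids are enforced; zero-norm spectra make
  the similarity undefined and raise.

## Known limitations

* States above two total quanta are outside the enumeration (both for
  energies and intensities).
* Second-order contributions of the quartic potential and
  combined-order-three moment terms are absent by construction of the
  method; both are quantified against the oracle in the tests.
* No Cartesian normal-mode analysis, isotope handling, resonance-Raman
  or temperature effects; wrong-sign band counting against experiment
  is a documented recipe (compare sign patterns of matched band lists),
  not an operation.
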