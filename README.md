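# anharmvoa

Anharmonic vibrational spectroscopy for chiral molecules from quartic
force fields: second-order vibrational perturbation theory with
automatic resonance handling (GVPT2), producing IR, VCD, Raman and ROA
stick and band spectra including overtone and combination transitions.

## Who this is for

Overtone and combination bands — one to two orders of magnitude weaker
than fundamentals — are now routinely measurable in ROA and VCD, and
simulating them takes more than the double-harmonic approximation: the
vibrational wavefunction needs cubic/quartic force constants
(mechanical anharmonicity) and the electric/magnetic property surfaces
need second and third derivatives (electrical anharmonicity).
`anharmvoa` implements that machinery for model vibrational problems:
it consumes a self-contained JSON document holding harmonic wavenumbers
ω_i, cubic f_ijk and semidiagonal quartic f_ijkl constants (cm⁻¹,
reduced normal coordinates) plus Taylor-expanded property tensors
(μ, m, α, G′, A), and is validated end to end against a brute-force
variational solver on synthetic systems — no quantum-chemistry run
required anywhere.

## The model

Energies: VPT2 on `V = ½Σω_i q_i² + 1/6 Σf_ijk q_iq_jq_k + 1/24 Σf_ijkl q_iq_jq_kq_l`
gives Dunham-form levels `E(v) − E(0) = Σω_iv_i + Σ_{i≤j} χ_ij[(v_i+½)(v_j+½) − ¼]`.
Fermi resonances (ω_i+ω_j ≈ ω_k) and Darling–Dennison resonances
(near-degenerate fundamentals or two-quanta states) are detected by
multi-criterion tests, removed from the perturbative sums
(deperturbation), and reintroduced by diagonalizing small variational
blocks — the "generalized" in GVPT2.

Intensities: transition moments
`⟨X⟩ = ⟨ψ_F|X|ψ_I⟩/√(⟨ψ_F|ψ_F⟩⟨ψ_I|ψ_I⟩)` are assembled from an
eleven-term decomposition by operator order × wavefunction order, then
converted to dipole strengths D, rotational strengths R (g = 4R/D),
far-from-resonance Raman/ROA invariants (a², β(α)², aG′, β(G′)²,
β(A)²) and SCP backscattering sticks with CID = ROA/Raman. Sticks are
broadened with 8 cm⁻¹ Lorentzians, and spectra are compared with the
normalized-overlap similarity factor s(a) maximized over a frequency
scaling a. See `docs/methods.md` for formulas and conventions.

## Worked example

A one-mode system built from the quartic Taylor expansion of a Morse
oscillator (ω = 3000 cm⁻¹, ωx = 50 cm⁻¹):

```python
>>> import anharmvoa as av
>>> from anharmvoa.vpt2_engine import anharmonic_constants
>>> s = av.make_morse_system(3000.0, 50.0)
>>> chi = anharmonic_constants(s.force_field)
>>> chi.values[0, 0]
-50.000000000000014
>>> res = av.gvpt2_solve(s.force_field)
>>> res.energy((1,)), res.energy((2,))
(2900.0, 5700.0)
```

χ₁₁ = −ωx exactly, and the VPT2 levels reproduce the Morse fundamental
ω − 2ωx = 2900 cm⁻¹ and first overtone 2ω − 6ωx = 5700 cm⁻¹ — the
classic closed-form check of the χ machinery.

A planted Fermi dyad (2ω₁ ≈ ω₂, detuning 10 cm⁻¹, f₁₁₂ = 40 cm⁻¹):

```python
>>> spec = av.fermi_dyad_spec(seed=0, detuning=10.0)
>>> sys2 = av.make_random_system(spec)
>>> r = av.gvpt2_solve(sys2.force_field)
>>> r.blocks[0].states, r.blocks[0].eigenvalues.round(2)
([(0, 1), (2, 0)], array([2015.75, 2038.39]))
```

The detector logs the criterion values (detuning 10 ≤ 200;
f⁴ = 2.56·10⁶ ≥ 2.56·10⁴; |f| = 40 ≥ 4), the deperturbed dyad
(2021.77, 2032.37 cm⁻¹) is re-coupled with the cubic element
W = f/4 = 10 cm⁻¹, and the mixed eigenstates repel to
(2015.75, 2038.39 cm⁻¹) — within a few hundredths of cm⁻¹ of the
variational reference. `av.compute_transitions(sys2, r)` then yields
the transition table with both dyad members labelled
`mixed(F2+O1)`/`mixed(O1+F2)` at leading weight 0.73 (below the 0.80
assignment threshold, as it should be for a strongly mixed pair).

From a shell, the same pipeline is:

```sh
anharmvoa generate --morse 3000 50 --out morse.json
anharmvoa simulate --system morse.json --out morse
anharmvoa compare --calc morse.ir.dat --exp morse.ir.dat   # s = 1.0
```

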