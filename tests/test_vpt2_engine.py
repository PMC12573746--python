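import numpy as np
import pytest

import anharmvoa as av
from anharmvoa.model_core import CoriolisData, NormalModes, QuarticForceField
from anharmvoa.vpt2_engine import (
    ResonanceError,
    WavefunctionCoeffs,
    anharmonic_constants,
    contact_coupling,
    detect_fermi,
    potential_element,
    state_energy,
)


def harmonic_ff(*omegas):
    return QuarticForceField(NormalModes(list(omegas)))


class TestChiMatrix:
    def test_zero_force_constants_give_zero_chi(self):
        chi = anharmonic_constants(harmonic_ff(1000.0, 1500.0))
        assert np.array_equal(chi.values, np.zeros((2, 2)))

    def test_morse_chi_is_minus_omega_x(self, morse_system):
        # f_iiii/16 - (5/48) f_iii^2/omega reduces symbolically to -omega_x
        chi = anharmonic_constants(morse_system.force_field)
        assert chi.values[0, 0] == pytest.approx(-50.0, abs=1e-10)

    def test_chi_symmetric(self, small_random_system):
        chi = anharmonic_constants(small_random_system.force_field)
        assert np.array_equal(chi.values, chi.values.T)

    def test_coriolis_contribution(self):
        ff = harmonic_ff(1000.0, 1300.0)
        zeta = np.zeros((3, 2, 2))
        zeta[0, 0, 1], zeta[0, 1, 0] = 0.5, -0.5
        cor = CoriolisData(zeta, np.array([5.0, 1.0, 1.0]))
        chi = anharmonic_constants(ff, coriolis=cor)
        expected = 5.0 * 0.25 * (1000.0 / 1300.0 + 1300.0 / 1000.0)
        assert chi.values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_exact_degeneracy_is_always_flagged(self):
        # at zero detuning both coupling thresholds vanish, so any nonzero
        # f_iik is flagged and the resonant chi term is removed
        ff = harmonic_ff(1000.0, 2000.0)  # 2 w1 = w2 exactly
        ff.set_cubic((0, 0, 1), 1e-6)
        res = detect_fermi(ff)
        chi = anharmonic_constants(ff, resonances=res)
        assert ((0, 0), 1) in chi.deperturbed

    def test_unflagged_exact_degeneracy_raises(self):
        ff = harmonic_ff(1000.0, 2000.0)
        ff.set_cubic((0, 0, 1), 10.0)
        with pytest.raises(ResonanceError):
            anharmonic_constants(ff)  # detection skipped


class TestStateEnergy:
    def test_harmonic_fundamental(self):
        chi = anharmonic_constants(harmonic_ff(1234.0, 800.0))
        assert state_energy(chi, np.array([1234.0, 800.0]), (1, 0)) == 1234.0

    def test_morse_levels(self, morse_system):
        chi = anharmonic_constants(morse_system.force_field)
        om = morse_system.force_field.omega
        assert state_energy(chi, om, (1,)) == pytest.approx(2900.0, abs=1e-9)
        assert state_energy(chi, om, (2,)) == pytest.approx(5700.0, abs=1e-9)

    def test_combination_identity(self, small_random_system):
        # E(1,1) = E(1,0) + E(0,1) + chi_12 exactly, by the level formula
        ff = small_random_system.force_field
        chi = anharmonic_constants(ff)
        e11 = state_energy(chi, ff.omega, (1, 1))
        e10 = state_energy(chi, ff.omega, (1, 0))
        e01 = state_energy(chi, ff.omega, (0, 1))
        assert e11 == pytest.approx(e10 + e01 + chi.values[0, 1], abs=1e-9)

    def test_three_quanta_rejected(self):
        chi = anharmonic_constants(harmonic_ff(1000.0))
        with pytest.raises(av.InputError):
            state_energy(chi, np.array([1000.0]), (3,))


class TestFermiDetection:
    def test_worked_triple(self):
        # omega = (2990, 1700, 1300), f_231 = 40: detuning 10, criteria
        # 40^4 = 2.56e6 >= 6400 and 40 >= 2
        ff = harmonic_ff(2990.0, 1700.0, 1300.0)
        ff.set_cubic((0, 1, 2), 40.0)
        res = detect_fermi(ff)
        rec = next(r for r in res.fermi if r.key == ((1, 2), 0))
        assert rec.detuning == pytest.approx(10.0)
        assert rec.lhs_depth == pytest.approx(40.0 ** 4)
        assert rec.rhs_depth == pytest.approx(64.0 * 100.0)
        assert rec.rhs_intensity == pytest.approx(2.0)
        assert rec.flagged

    def test_zero_coupling_never_flagged(self):
        ff = harmonic_ff(2000.0, 1010.0, 990.0)  # detuning 0 but f = 0
        res = detect_fermi(ff)
        assert not any(r.flagged for r in res.fermi)

    def test_large_detuning_gated_regardless_of_f(self):
        ff = harmonic_ff(2300.0, 1000.0, 1000.0)  # detuning -300
        ff.set_cubic((1, 2, 0), 500.0)
        res = detect_fermi(ff)
        assert not any(r.flagged for r in res.fermi)

    def test_delta_convention_switch(self):
        # overtone triple: doubled convention weights (1+d) = 2
        ff = harmonic_ff(1000.0, 1985.0)
        ff.set_cubic((0, 0, 1), 30.0)
        doubled = detect_fermi(ff, delta_convention="doubled")
        verbatim = detect_fermi(ff, delta_convention="verbatim")
        rec_d = next(r for r in doubled.fermi if r.key == ((0, 0), 1))
        rec_v = next(r for r in verbatim.fermi if r.key == ((0, 0), 1))
        assert rec_d.rhs_depth == pytest.approx(4.0 * rec_v.rhs_depth)


class TestDarlingDennison:
    def test_harmonic_coupling_zero(self):
        ff = harmonic_ff(1000.0, 1020.0)
        assert av.dd_coupling(ff, (1, 0), (0, 1)) == 0.0

    def test_coupling_symmetric(self, small_random_system):
        ff = small_random_system.force_field
        ab = av.dd_coupling(ff, (1, 0), (0, 1))
        ba = av.dd_coupling(ff, (0, 1), (1, 0))
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_planted_quartic_coupling_value(self):
        # a single f_0001 = 8 K makes the direct 1-1 element exactly K
        ff = harmonic_ff(1000.0, 1030.0)
        ff.set_quartic((0, 0, 0, 1), 80.0)
        assert contact_coupling(ff, (1, 0), (0, 1)) == pytest.approx(10.0, rel=1e-12)

    def test_coupling_matches_oracle_effective_block(self):
        # extract the effective 2x2 off-diagonal from the oracle eigenpair:
        # |W| = sqrt(((E+ - E-)^2 - (Ea - Eb)^2)/4) with deperturbed diagonals
        ff = harmonic_ff(1000.0, 1025.0)
        ff.set_quartic((0, 0, 0, 1), 120.0)
        res = av.gvpt2_solve(ff)
        blk = res.blocks[0]
        sol = av.variational_solve(ff, max_quanta=20)
        a = sorted(np.round(blk.eigenvalues, 6))
        b = sorted([sol.state_energy((1, 0)), sol.state_energy((0, 1))])
        assert np.allclose(a, b, atol=1.0)
        split_o = b[1] - b[0]
        diag = np.diag(blk.matrix)
        w_eff = np.sqrt(max((split_o ** 2 - (diag[1] - diag[0]) ** 2) / 4.0, 0.0))
        assert abs(blk.matrix[0, 1]) == pytest.approx(w_eff, rel=0.05)


class TestGVPT2:
    def test_no_resonances_reduces_to_plain_vpt2(self, small_random_system):
        ff = small_random_system.force_field
        res = av.gvpt2_solve(ff)
        assert not res.blocks
        chi = anharmonic_constants(ff)
        for s in av.enumerate_final_states(2):
            assert res.energy(s) == pytest.approx(state_energy(chi, ff.omega, s), abs=1e-9)

    def test_fermi_dyad_matches_oracle(self, fermi_dyad_system):
        ff = fermi_dyad_system.force_field
        res = av.gvpt2_solve(ff)
        (blk,) = res.blocks
        assert set(blk.states) == {(2, 0), (0, 1)}
        sol = av.variational_solve(ff, max_quanta=24)
        oracle_pair = sorted([sol.state_energy((2, 0)), sol.state_energy((0, 1))])
        assert np.allclose(np.sort(blk.eigenvalues), oracle_pair, atol=2.0)

    def test_eigenvalue_repulsion(self, fermi_dyad_system):
        res = av.gvpt2_solve(fermi_dyad_system.force_field)
        (blk,) = res.blocks
        dep_split = abs(blk.matrix[0, 0] - blk.matrix[1, 1])
        mixed_split = abs(blk.eigenvalues[1] - blk.eigenvalues[0])
        assert mixed_split >= dep_split - 1e-9

    def test_continuity_across_depth_threshold(self):
        # overtone dyad at detuning 10; coupling-depth boundary f = (256 det^2)^(1/4)
        det = 10.0
        f_thr = (64.0 * 4.0 * det ** 2) ** 0.25
        energies = {}
        for f in (f_thr - 0.02, f_thr + 0.02):
            spec = av.GeneratorSpec(n_modes=2, omega_range=(800, 1500), cubic_scale=10,
                                    quartic_scale=2, seed=11,
                                    resonance_plan=[av.FermiPlan(0, 0, 1, detuning=det, f=f)])
            s = av.make_random_system(spec)
            res = av.gvpt2_solve(s.force_field)
            if res.blocks:
                energies[f] = np.sort(res.blocks[0].eigenvalues[:2])
            else:
                energies[f] = np.sort([res.energy((2, 0)), res.energy((0, 1))])
        lo, hi = energies[f_thr - 0.02], energies[f_thr + 0.02]
        assert np.max(np.abs(hi - lo)) < 0.5

    def test_deperturbed_coefficients_exactly_zero(self, fermi_dyad_system):
        ff = fermi_dyad_system.force_field
        res = av.gvpt2_solve(ff)
        flags = res.resonances.fermi_flags()
        wf = WavefunctionCoeffs(ff, (0, 1), flags)
        assert (2, 0) not in wf.c1
        assert wf.c2((2, 0)) == 0.0
        assert wf.normalization >= 1.0

    def test_oracle_agreement_nonresonant(self, small_random_system):
        ff = small_random_system.force_field
        res = av.gvpt2_solve(ff)
        sol = av.variational_solve(ff, max_quanta=16)
        shifts, errs = [], []
        for s in av.enumerate_final_states(2):
            harm = sum(w * v for w, v in zip(ff.omega, s))
            e_oracle = sol.state_energy(s)
            shifts.append(abs(e_oracle - harm))
            errs.append(abs(res.energy(s) - e_oracle))
        assert max(errs) <= 0.01 * max(shifts)


class TestChiAgainstExplicitPerturbationTheory:
    def test_chi_form_matches_sum_over_states_rspt2(self):
        """The closed-form chi matrix must reproduce explicit second-order
        Rayleigh-Schrodinger energies (quartic at first order, cubic at
        second) in E(v) - E(0); the constant anharmonic ZPE term, which the
        Dunham form cannot carry, cancels in the differences."""
        import itertools
        rng = np.random.default_rng(7)
        omega = rng.uniform(900.0, 2600.0, 2)
        ff = QuarticForceField(NormalModes(omega))
        for key in itertools.combinations_with_replacement(range(2), 3):
            ff.set_cubic(key, rng.normal(0.0, 15.0))
        for key in itertools.combinations_with_replacement(range(2), 4):
            if len(set(key)) < len(key):
                ff.set_quartic(key, rng.normal(0.0, 5.0))

        # independent dense sum-over-states RSPT2
        vmax = 11
        states = [s for s in itertools.product(range(vmax + 1), repeat=2)
                  if sum(s) <= vmax]
        nmax = vmax + 5
        a = np.diag(np.sqrt(np.arange(1.0, nmax)), 1)
        q1 = (a + a.T) / np.sqrt(2.0)
        qp = {0: np.eye(nmax)}
        for k in range(1, 5):
            qp[k] = qp[k - 1] @ q1

        def monos(items, order):
            from collections import Counter
            from math import factorial
            out = []
            for key, f in items:
                counts = Counter(key)
                mult = factorial(order)
                for c in counts.values():
                    mult //= factorial(c)
                out.append((f * mult / factorial(order),
                            {m: counts.get(m, 0) for m in range(2)}))
            return out

        m3 = monos(ff.cubic_items(), 3)
        m4 = monos(ff.quartic_items(), 4)

        def op_el(bra, ket, powers):
            return qp[powers[0]][bra[0], ket[0]] * qp[powers[1]][bra[1], ket[1]]

        def e0(s):
            return omega[0] * (s[0] + 0.5) + omega[1] * (s[1] + 0.5)

        def rspt2(t):
            e = e0(t) + sum(c * op_el(t, t, p) for c, p in m4)
            for u in states:
                if u == t:
                    continue
                el = sum(c * op_el(u, t, p) for c, p in m3)
                if el:
                    e += el * el / (e0(t) - e0(u))
            return e

        chi = anharmonic_constants(ff)
        ref0 = rspt2((0, 0))
        for v in [(1, 0), (0, 1), (2, 0), (1, 1)]:
            expected = rspt2(v) - ref0
            got = state_energy(chi, omega, v)
            assert got == pytest.approx(expected, abs=1e-6)


class TestPotentialElements:
    def test_cubic_fermi_elements(self):
        # <1i 1j|V3|1k> = f_ijk/(2 sqrt 2); overtone variant f_iik/4
        ff = harmonic_ff(1000.0, 1100.0, 2080.0)
        ff.set_cubic((0, 1, 2), 24.0)
        el = potential_element(ff, (1, 1, 0), (0, 0, 1), orders=(3,))
        assert el == pytest.approx(24.0 / (2.0 * np.sqrt(2.0)), rel=1e-12)
        ff2 = harmonic_ff(1000.0, 1980.0)
        ff2.set_cubic((0, 0, 1), 24.0)
        el2 = potential_element(ff2, (2, 0), (0, 1), orders=(3,))
        assert el2 == pytest.approx(24.0 / 4.0, rel=1e-12)
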