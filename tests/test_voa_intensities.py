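import itertools

import numpy as np
import pytest

import anharmvoa as av
from anharmvoa.model_core import NormalModes, PropertySurface, QuarticForceField
from anharmvoa.vpt2_engine import WavefunctionCoeffs
from anharmvoa.voa_intensities import (
    TERM_NAMES,
    TransitionRecord,
    assign_bands,
    compute_transitions,
    derivative_order_contributions,
    ir_vcd_observables,
    raman_roa_observables,
    transition_moment,
)
from anharmvoa.spectra_io import convolve


def harmonic_wf(omegas, state):
    ff = QuarticForceField(NormalModes(list(omegas)))
    return ff, WavefunctionCoeffs(ff, state)


class TestHarmonicLimits:
    def test_fundamental_moment_is_d1_over_sqrt2(self):
        ff, wf0 = harmonic_wf([1000.0], (0,))
        _, wf1 = harmonic_wf([1000.0], (1,))
        surf = PropertySurface("mu", 1, d1=[[0.3, -0.2, 0.1]])
        dec = transition_moment(surf, wf0, wf1)
        assert np.allclose(dec.total.real, np.array([0.3, -0.2, 0.1]) / np.sqrt(2.0))
        for name in TERM_NAMES[1:]:
            assert np.allclose(dec.terms[name], 0.0)

    def test_overtone_moment_is_d2_over_2sqrt2(self):
        ff, wf0 = harmonic_wf([1000.0], (0,))
        _, wf2 = harmonic_wf([1000.0], (2,))
        surf = PropertySurface("mu", 1, d2=[[[0.08, 0.0, 0.0]]])
        dec = transition_moment(surf, wf0, wf2)
        assert dec.total[0].real == pytest.approx(0.08 / (2.0 * np.sqrt(2.0)), rel=1e-12)
        assert np.allclose(dec.terms["term2"], dec.total)

    def test_derivative_cap_removes_higher_orders(self):
        ff, wf0 = harmonic_wf([1000.0], (0,))
        _, wf2 = harmonic_wf([1000.0], (2,))
        surf = PropertySurface("mu", 1, d2=[[[0.08, 0.0, 0.0]]])
        dec = transition_moment(surf, wf0, wf2, derivative_order_cap=1)
        assert np.allclose(dec.total, 0.0)


class TestDecompositionConservation:
    def test_terms_sum_to_total_anharmonic(self, small_random_system):
        ff = small_random_system.force_field
        wf0 = WavefunctionCoeffs(ff, (0, 0))
        for state in av.enumerate_final_states(2):
            wf = WavefunctionCoeffs(ff, state)
            for name, surf in small_random_system.surfaces.items():
                dec = transition_moment(surf, wf0, wf)
                assert np.allclose(dec.sum_of_terms(), dec.total, atol=1e-14)

    def test_term11_matches_overlap_correction(self, small_random_system):
        # term 11 ~ -1/2 <F0|X0|I0> (<F1|F1> + <I1|I1>) at second order
        ff = small_random_system.force_field
        wf0 = WavefunctionCoeffs(ff, (0, 0))
        wf1 = WavefunctionCoeffs(ff, (1, 0))
        dec = transition_moment(small_random_system.surfaces["mu"], wf0, wf1)
        approx = -0.5 * dec.terms["term1"] * (wf0.norm1_sq + wf1.norm1_sq)
        assert np.allclose(dec.terms["term11"], approx, rtol=0.01)


class TestParity:
    def test_mirror_image_flips_vcd_and_roa_only(self, small_random_system):
        mir = av.mirror_image(small_random_system)
        res = av.gvpt2_solve(small_random_system.force_field)
        rec = compute_transitions(small_random_system, res)
        rec_m = compute_transitions(mir, res)
        for a, b in zip(rec, rec_m):
            assert a.energy == b.energy
            assert a.observables["D"] == b.observables["D"]
            assert a.observables["R"] == -b.observables["R"]
            assert a.observables["raman_stick"] == b.observables["raman_stick"]
            assert a.observables["roa_stick"] == -b.observables["roa_stick"]

    def test_mirror_spectra_pointwise_negation(self, small_random_system):
        mir = av.mirror_image(small_random_system)
        res = av.gvpt2_solve(small_random_system.force_field)
        for key in ("vcd_stick", "roa_stick"):
            sa = convolve([(r.energy, r.observables[key] or 0.0)
                           for r in compute_transitions(small_random_system, res)],
                          grid=(0.0, 4000.0, 2.0))
            sb = convolve([(r.energy, r.observables[key] or 0.0)
                           for r in compute_transitions(mir, res)],
                          grid=(0.0, 4000.0, 2.0))
            assert np.array_equal(sa.intensity, -sb.intensity)


class TestObservables:
    def test_rotational_strength_zero_without_magnetic_moment(self):
        obs = ir_vcd_observables(np.array([1.0, 0.0, 0.0]), np.zeros(3), 1000.0)
        assert obs["R"] == 0.0 and obs["vcd_stick"] == 0.0

    def test_g_factor_collinear_unit_moments(self):
        # |mu| = |m| = 1, collinear: g = 4 R / D = 4 under the phase convention
        obs = ir_vcd_observables(np.array([1.0, 0.0, 0.0]),
                                 np.array([1.0j, 0.0, 0.0]), 1000.0)
        assert obs["g"] == pytest.approx(4.0)
        assert obs["R"] == pytest.approx(1.0)

    def test_missing_tensor_marked_unavailable(self):
        obs = ir_vcd_observables(None, None, 1000.0)
        assert obs["D"] is None and obs["R"] is None

    def test_isotropic_alpha_has_no_anisotropy_and_no_roa(self):
        alpha = 0.7 * np.eye(3)
        obs = raman_roa_observables(alpha, np.zeros((3, 3)), np.zeros((3, 3, 3)),
                                    1000.0, include_nu4=False)
        assert obs["beta_alpha2"] == pytest.approx(0.0, abs=1e-14)
        assert obs["roa_stick"] == pytest.approx(0.0, abs=1e-14)
        assert obs["raman_stick"] == pytest.approx(4.0 * 45.0 * 0.7 ** 2, rel=1e-12)

    def test_invariants_match_bruteforce_contraction(self):
        rng = np.random.default_rng(5)
        al = rng.normal(size=(3, 3)); al = 0.5 * (al + al.T)
        G = rng.normal(size=(3, 3))
        A = rng.normal(size=(3, 3, 3)); A = 0.5 * (A + np.swapaxes(A, 1, 2))
        obs = raman_roa_observables(al, G, A, 1000.0, include_nu4=False)
        # explicit index sums
        beta_a = sum(0.5 * (3.0 * al[i, j] * al[i, j] - al[i, i] * al[j, j])
                     for i in range(3) for j in range(3))
        beta_g = sum(0.5 * (3.0 * al[i, j] * G[i, j] - al[i, i] * G[j, j])
                     for i in range(3) for j in range(3))
        eps = np.zeros((3, 3, 3))
        for p in itertools.permutations(range(3)):
            i, j, k = p
            eps[i, j, k] = (j - i) * (k - j) * (k - i) / 2
        beta_A = sum(al[a, b] * eps[a, g, d] * A[g, d, b]
                     for a in range(3) for b in range(3)
                     for g in range(3) for d in range(3))
        assert obs["beta_alpha2"] == pytest.approx(beta_a, rel=1e-12)
        assert obs["beta_G2"] == pytest.approx(beta_g, rel=1e-12)
        nu0 = 1e7 / 532.0
        assert obs["beta_A2"] == pytest.approx(0.5 * nu0 / 219474.6313632 * beta_A, rel=1e-9)

    def test_cid_independent_of_nu4_factor(self):
        rng = np.random.default_rng(6)
        al = rng.normal(size=(3, 3)); al = 0.5 * (al + al.T)
        G = rng.normal(size=(3, 3))
        A = rng.normal(size=(3, 3, 3)); A = 0.5 * (A + np.swapaxes(A, 1, 2))
        with_nu = raman_roa_observables(al, G, A, 1000.0, include_nu4=True)
        without = raman_roa_observables(al, G, A, 1000.0, include_nu4=False)
        assert with_nu["cid"] == pytest.approx(without["cid"], rel=1e-12)


class TestMomentOracleAgreement:
    def test_moments_match_variational_oracle(self, small_random_system):
        from anharmvoa.oracle import oracle_transition_moment, variational_solve
        ff = small_random_system.force_field
        sol = variational_solve(ff, max_quanta=14)
        wf0 = WavefunctionCoeffs(ff, (0, 0))
        for state in av.enumerate_final_states(2):
            wf = WavefunctionCoeffs(ff, state)
            for name in ("mu", "alpha"):
                dec = transition_moment(small_random_system.surfaces[name], wf0, wf)
                om = oracle_transition_moment(sol, small_random_system.surfaces[name],
                                              (0, 0), state)
                scale = max(np.max(np.abs(om)), 1e-10)
                assert np.max(np.abs(dec.total - om)) / scale < 0.02


class TestAssignment:
    def _record(self, weights):
        comps = dict(weights)
        leading = max(comps, key=lambda s: abs(comps[s]))
        norm = sum(c * c for c in comps.values())
        return TransitionRecord(
            initial=(0, 0), final_label="", leading_state=leading,
            leading_weight=comps[leading] ** 2 / norm, energy=1000.0,
            kind_weights=comps, moments={}, decompositions={})

    def test_unmixed_state_labeled(self):
        rec = self._record({(1, 0): 1.0})
        assign_bands([rec])
        assert rec.final_label == "F1"

    def test_even_dyad_labeled_mixed(self):
        rec = self._record({(2, 0): np.sqrt(0.5), (0, 1): np.sqrt(0.5)})
        assign_bands([rec])
        assert rec.final_label.startswith("mixed(")

    def test_20_degree_mixing_angle_major_state_labeled(self):
        c, s = np.cos(np.radians(20.0)), np.sin(np.radians(20.0))
        rec = self._record({(2, 0): c, (0, 1): s})
        assert rec.leading_weight == pytest.approx(0.883, abs=1e-3)
        assign_bands([rec])
        assert rec.final_label == "O1"


class TestDerivativeOrderContributions:
    def test_formula_arithmetic(self):
        # I1 = 50, I12 = 75, I123 = 100 -> (50, 25, 25) percent
        i1, i12, i123 = 50.0, 75.0, 100.0
        n3 = (i123 - i12) / i123 * 100.0
        n2 = (i12 - i1) / i123 * 100.0
        assert (100.0 - n2 - n3, n2, n3) == (50.0, 25.0, 25.0)

    def test_harmonic_system_all_first_order(self):
        spec = av.GeneratorSpec(n_modes=2, cubic_scale=0.0, quartic_scale=0.0,
                                d2_scale=0.0, d3_scale=0.0, seed=8)
        s = av.make_random_system(spec)
        contrib = derivative_order_contributions(s, grid_step=4.0)
        for kind in contrib:
            for region, vals in contrib[kind].items():
                if not np.isnan(vals["first"]):
                    assert vals["first"] == pytest.approx(100.0, abs=1e-9)
                    assert vals["second"] == pytest.approx(0.0, abs=1e-9)

    def test_percentages_sum_to_100(self, small_random_system):
        contrib = derivative_order_contributions(small_random_system, grid_step=4.0)
        for kind in contrib:
            for region, vals in contrib[kind].items():
                total = vals["first"] + vals["second"] + vals["third"]
                if not np.isnan(total):
                    assert total == pytest.approx(100.0, abs=1e-9)


class TestAnharmonicBandOrigin:
    def test_voa_overtone_intensity_dominated_by_second_derivatives(self):
        # weak mechanical anharmonicity: overtone/combination VCD and ROA
        # should originate almost entirely from term 2 (second derivatives)
        spec = av.GeneratorSpec(n_modes=2, omega_range=(800, 2400), cubic_scale=5,
                                quartic_scale=1, min_fermi_detuning=400, seed=21)
        s = av.make_random_system(spec)
        res = av.gvpt2_solve(s.force_field)
        recs = compute_transitions(s, res)
        for r in recs:
            if sum(r.leading_state) != 2:
                continue
            for name in ("m", "Gprime"):
                dec = r.decompositions[name]
                tot = np.linalg.norm(dec.total)
                if tot < 1e-12:
                    continue
                frac = np.linalg.norm(dec.terms["term2"]) / tot
                assert frac > 0.9
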