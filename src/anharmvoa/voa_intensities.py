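"""Anharmonic transition moments and IR/VCD/Raman/ROA observables.

A transition moment of a property X between VPT2 wavefunctions is
``<X>_{I,F} = <psi_F|X|psi_I> / sqrt(<psi_F|psi_F><psi_I|psi_I>)`` and is
assembled term by term from the order split of the operator
(X0 = equilibrium value + first derivatives, X1 = second derivatives,
X2 = third derivatives) and of the wavefunctions (orders 0/1/2), giving
an eleven-term decomposition:

  1  <F0|X0|I0>          harmonic-oscillator approximation
  2  <F0|X1|I0>          pure electrical (second derivatives)
  3  <F1|X0|I0>   4  <F0|X0|I1>      mechanical, first order
  5  <F0|X2|I0>          pure electrical (third derivatives)
  6  <F2|X0|I0>   7  <F0|X0|I2>      mechanical, second order
  8  <F1|X1|I0>   9  <F0|X1|I1>      mixed
  10 <F1|X0|I1>
  11 renormalization of term 1

The exact normalization of the moment is applied: terms 2-10 are divided
by N = sqrt(<psi_F|psi_F><psi_I|psi_I>) (with <psi|psi> = 1 + <psi1|psi1>,
the second-order-consistent norm) and term 11 is term1*(1/N - 1), so the
eleven terms sum to the normalized moment identically while term 11
reduces to the familiar -1/2 <F0|X0|I0>(<F1|F1>+<I1|I1>) overlap
correction at second order.

For states belonging to a variational (GVPT2) block, moments are first
computed toward the deperturbed states and then rotated by the block
eigenvectors.

Observables: dipole strength D = |<mu>|^2, rotational strength
R = Im(<mu>* . <m>) (dimensionless g = 4R/D); far-from-resonance Raman/ROA
invariants a^2, beta(alpha)^2, aG', beta(G')^2, beta(A)^2 with
backscattering SCP combinations Raman ~ 4(45 a^2 + 7 beta(alpha)^2) and
ROA ~ (96/c)(beta(G')^2 + beta(A)^2 / 3); CID = ROA/Raman.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    InputError,
    ModelSystem,
    PropertySurface,
    VibState,
    enumerate_final_states,
    ground,
    state_label,
)
from .vpt2_engine import (
    GVPT2Result,
    WavefunctionCoeffs,
    elem_1d,
    gvpt2_solve,
)

SPEED_OF_LIGHT_AU = 137.035999  # atomic units
CM1_PER_HARTREE = 219474.6313632
DEFAULT_EXCITATION_NM = 532.0

TERM_NAMES = [f"term{i}" for i in range(1, 12)]


# ---------------------------------------------------------------------------
# operators: component-vectorized polynomials in q (and at most one p factor)
# ---------------------------------------------------------------------------

@dataclass
class _OpTerm:
    coeff: np.ndarray             # per-Cartesian-component coefficients (flattened)
    ops: Dict[int, str]           # mode -> ordered op string, e.g. {0: "pq", 2: "q"}


def _mode_ops(entries: Sequence[Tuple[int, str]]) -> List[Tuple[float, Dict[int, str]]]:
    """Group (mode, op) factors; same-mode p/q products are Weyl-symmetrized."""
    by_mode: Dict[int, List[str]] = {}
    for mode, op in entries:
        by_mode.setdefault(mode, []).append(op)
    variants: List[Tuple[float, Dict[int, str]]] = [(1.0, {})]
    for mode, ops in by_mode.items():
        if "p" in ops and len(ops) > 1:
            qs = "q" * (len(ops) - 1)
            choices = [(0.5, "p" + qs), (0.5, qs + "p")]
        else:
            choices = [(1.0, "".join(ops))]
        new = []
        for w0, d0 in variants:
            for w, s in choices:
                d = dict(d0)
                d[mode] = s
                new.append((w0 * w, d))
        variants = new
    return variants


def operator_terms(surface: PropertySurface, part: int) -> List[_OpTerm]:
    """Operator terms for one order part of the property expansion.

    part 0: equilibrium value + first derivatives (harmonic operator);
    part 1: second derivatives; part 2: third derivatives.  Electric-type
    tensors expand in q with the Taylor 1/2 and 1/6 weights; the magnetic
    dipole expands in p_i times a polynomial in q (unit weight at first
    derivative order, 1/2 at second), with same-mode p q products
    symmetrized.
    """
    n = surface.n_modes
    conj = surface.conjugate
    terms: List[_OpTerm] = []

    def add(scalar: float, comps: np.ndarray, entries: Sequence[Tuple[int, str]]):
        flat = np.asarray(comps, dtype=float).reshape(-1)
        if not np.any(flat):
            return
        for w, ops in _mode_ops(entries):
            terms.append(_OpTerm(scalar * w * flat, ops))

    lead = "p" if conj else "q"
    if part == 0:
        add(1.0, surface.value0, [])
        for i in range(n):
            add(1.0, surface.d1[i], [(i, lead)])
    elif part == 1:
        w2 = 1.0 if conj else 0.5
        for i in range(n):
            for j in range(n):
                add(w2, surface.d2[i, j], [(i, lead), (j, "q")])
    elif part == 2:
        w3 = 0.5 if conj else 1.0 / 6.0
        for key, val in surface.d3_items():
            for perm in sorted(set(itertools.permutations(key))):
                i, j, k = perm
                add(w3, val, [(i, lead), (j, "q"), (k, "q")])
    else:
        raise InputError("part must be 0, 1 or 2")
    return terms


def _term_element(term: _OpTerm, bra: VibState, ket: VibState) -> complex:
    val = 1.0 + 0.0j
    for m, ops in term.ops.items():
        val *= elem_1d(bra[m], ops, ket[m])
        if val == 0.0:
            return 0.0j
    for m in range(len(bra)):
        if m not in term.ops and bra[m] != ket[m]:
            return 0.0j
    return val


def operator_matrix_element(terms: List[_OpTerm], bra: VibState, ket: VibState,
                            ncomp: int) -> np.ndarray:
    out = np.zeros(ncomp, dtype=complex)
    for t in terms:
        el = _term_element(t, bra, ket)
        if el != 0.0:
            out += t.coeff * el
    return out


# ---------------------------------------------------------------------------
# transition moments with the eleven-term decomposition
# ---------------------------------------------------------------------------

@dataclass
class TermDecomposition:
    terms: Dict[str, np.ndarray]
    total: np.ndarray

    def __post_init__(self):
        assert set(self.terms) == set(TERM_NAMES)

    def sum_of_terms(self) -> np.ndarray:
        return sum(self.terms.values())


def _half_states(state: VibState):
    """state itself and its single-quantum neighbours (reach of a linear operator)."""
    yield state
    n = len(state)
    for m in range(n):
        up = list(state); up[m] += 1
        yield tuple(up)
        if state[m] > 0:
            dn = list(state); dn[m] -= 1
            yield tuple(dn)


def transition_moment(surface: PropertySurface,
                      wf_i: WavefunctionCoeffs, wf_f: WavefunctionCoeffs,
                      derivative_order_cap: int = 3) -> TermDecomposition:
    """Normalized transition moment of one property with its term decomposition.

    ``derivative_order_cap`` selects which operator parts enter: 1 keeps
    only the harmonic operator (value + first derivatives), 2 adds second
    derivatives, 3 adds the semidiagonal third derivatives.
    """
    if derivative_order_cap not in (1, 2, 3):
        raise InputError("derivative_order_cap must be 1, 2 or 3")
    I, F = wf_i.state, wf_f.state
    if sum(F) > 2 or sum(I) > 2:
        raise InputError("transition states outside the enumerated manifold")
    ncomp = int(np.prod(surface.comp_shape))
    x0 = operator_terms(surface, 0)
    x1 = operator_terms(surface, 1) if derivative_order_cap >= 2 else []
    x2 = operator_terms(surface, 2) if derivative_order_cap >= 3 else []

    def elem(terms, bra, ket):
        return operator_matrix_element(terms, bra, ket, ncomp)

    z = np.zeros(ncomp, dtype=complex)
    raw = {name: z.copy() for name in TERM_NAMES}
    raw["term1"] = elem(x0, F, I)
    raw["term2"] = elem(x1, F, I)
    raw["term5"] = elem(x2, F, I)
    for u, c in wf_f.c1.items():
        raw["term3"] += c * elem(x0, u, I)
        raw["term8"] += c * elem(x1, u, I)
    for u, c in wf_i.c1.items():
        raw["term4"] += c * elem(x0, F, u)
        raw["term9"] += c * elem(x1, F, u)
    for u, cf in wf_f.c1.items():
        for v, ci in wf_i.c1.items():
            raw["term10"] += cf * ci * elem(x0, u, v)
    # second-order wavefunction terms: only states the harmonic operator can
    # reach from the other side contribute
    for u in set(_half_states(I)):
        if u == F:
            continue
        c = wf_f.c2(u)
        if c != 0.0:
            raw["term6"] += c * elem(x0, u, I)
    for u in set(_half_states(F)):
        if u == I:
            continue
        c = wf_i.c2(u)
        if c != 0.0:
            raw["term7"] += c * elem(x0, F, u)

    norm = np.sqrt(wf_f.normalization * wf_i.normalization)
    terms = {"term1": raw["term1"]}
    for name in TERM_NAMES[1:10]:
        terms[name] = raw[name] / norm
    terms["term11"] = raw["term1"] * (1.0 / norm - 1.0)
    total = sum(raw[n] for n in TERM_NAMES[:10]) / norm
    return TermDecomposition(terms, total)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def ir_vcd_observables(mu_moment: Optional[np.ndarray],
                       m_moment: Optional[np.ndarray],
                       energy: float) -> Dict[str, Optional[float]]:
    """Dipole strength, rotational strength, g-factor and stick values.

    ``R = Im(sum_a mu_a* m_a)`` under the phase convention in which
    electric-dipole moments are real and magnetic ones imaginary; the IR
    and VCD sticks carry the common nu prefactor of absorption so that
    their ratio is the g-factor 4R/D.
    """
    out: Dict[str, Optional[float]] = {"D": None, "R": None, "g": None,
                                       "ir_stick": None, "vcd_stick": None}
    if mu_moment is not None:
        D = float(np.sum(np.abs(mu_moment) ** 2))
        out["D"] = D
        out["ir_stick"] = energy * D
    if mu_moment is not None and m_moment is not None:
        R = float(np.imag(np.sum(np.conj(mu_moment) * m_moment)))
        out["R"] = R
        out["vcd_stick"] = energy * 4.0 * R
        if out["D"]:
            out["g"] = 4.0 * R / out["D"]
    return out


def raman_roa_observables(alpha_moment: Optional[np.ndarray],
                          gprime_moment: Optional[np.ndarray],
                          aquad_moment: Optional[np.ndarray],
                          energy: float,
                          excitation_nm: float = DEFAULT_EXCITATION_NM,
                          include_nu4: bool = True) -> Dict[str, Optional[float]]:
    """Raman/ROA invariants and SCP(180 deg) backscattering sticks.

    Transition tensors are real in this representation; invariants follow
    the far-from-resonance forms, with the quadrupole invariant carrying
    the excitation angular frequency (atomic units).  The overall intensity
    scale is arbitrary; only ratios (the CID) are contract-bearing.  The
    scattered-photon frequency factor nu0 (nu0-nu)^3 is applied to both
    sticks when ``include_nu4`` (it cancels in the CID).
    """
    out: Dict[str, Optional[float]] = {
        "a2": None, "beta_alpha2": None, "aG": None, "beta_G2": None,
        "beta_A2": None, "raman_stick": None, "roa_stick": None, "cid": None}
    if alpha_moment is None:
        return out
    al = np.real(np.asarray(alpha_moment).reshape(3, 3))
    a_iso = np.trace(al) / 3.0
    out["a2"] = float(a_iso ** 2)
    out["beta_alpha2"] = float(0.5 * (3.0 * np.sum(al * al) - np.trace(al) ** 2))
    nu0 = 1e7 / excitation_nm
    nu_factor = nu0 * (nu0 - energy) ** 3 * 1e-14 if include_nu4 else 1.0
    out["raman_stick"] = nu_factor * 4.0 * (45.0 * out["a2"] + 7.0 * out["beta_alpha2"])
    if gprime_moment is None or aquad_moment is None:
        return out
    G = np.real(np.asarray(gprime_moment).reshape(3, 3))
    A = np.real(np.asarray(aquad_moment).reshape(3, 3, 3))
    out["aG"] = float(np.trace(al) * np.trace(G) / 9.0)
    out["beta_G2"] = float(0.5 * (3.0 * np.sum(al * G) - np.trace(al) * np.trace(G)))
    eps = np.zeros((3, 3, 3))
    for a, b, c in itertools.permutations(range(3), 3):
        eps[a, b, c] = (b - a) * (c - b) * (c - a) / 2.0
    omega_exc_au = nu0 / CM1_PER_HARTREE
    beta_A2 = 0.0
    for a in range(3):
        for b in range(3):
            for g in range(3):
                for d in range(3):
                    beta_A2 += al[a, b] * eps[a, g, d] * A[g, d, b]
    out["beta_A2"] = float(0.5 * omega_exc_au * beta_A2)
    out["roa_stick"] = (nu_factor * (96.0 / SPEED_OF_LIGHT_AU)
                        * (out["beta_G2"] + out["beta_A2"] / 3.0))
    if out["raman_stick"]:
        out["cid"] = out["roa_stick"] / out["raman_stick"]
    return out


# ---------------------------------------------------------------------------
# full transition table
# ---------------------------------------------------------------------------

@dataclass
class TransitionRecord:
    initial: VibState
    final_label: str              # leading zeroth-order configuration (or "mixed")
    leading_state: VibState
    leading_weight: float
    energy: float
    kind_weights: Dict[VibState, float]
    moments: Dict[str, np.ndarray]
    decompositions: Dict[str, TermDecomposition]
    observables: Dict[str, Optional[float]] = field(default_factory=dict)


def compute_transitions(system: ModelSystem,
                        result: Optional[GVPT2Result] = None,
                        derivative_order_cap: int = 3,
                        excitation_nm: float = DEFAULT_EXCITATION_NM,
                        include_nu4: bool = True,
                        assignment_threshold: float = 0.80) -> List[TransitionRecord]:
    """All ground-state transitions to eigenstates with total quanta <= 2.

    Moments toward deperturbed states are mixed by the variational block
    eigenvectors; each eigenstate is assigned to its leading configuration
    when the squared leading weight exceeds ``assignment_threshold``.
    """
    ff = system.force_field
    if result is None:
        result = gvpt2_solve(ff, system.coriolis)
    flags = result.resonances.fermi_flags()
    dd_pairs = frozenset(
        tuple(sorted((
            tuple(1 if m == r.i else 0 for m in range(ff.n_modes)),
            tuple(1 if m == r.j else 0 for m in range(ff.n_modes)))))
        for r in result.resonances.flagged_dd11())
    g = ground(ff.n_modes)
    wf_ground = WavefunctionCoeffs(ff, g, flags, dd_pairs)

    # per deperturbed final state: wavefunction + per-surface decomposition
    dep_moments: Dict[VibState, Dict[str, TermDecomposition]] = {}
    for s in enumerate_final_states(ff.n_modes):
        wf_f = WavefunctionCoeffs(ff, s, flags, dd_pairs)
        dep_moments[s] = {
            name: transition_moment(surf, wf_ground, wf_f, derivative_order_cap)
            for name, surf in system.surfaces.items()}

    records: List[TransitionRecord] = []
    for energy, comps in result.eigenstates():
        moments: Dict[str, np.ndarray] = {}
        decs: Dict[str, TermDecomposition] = {}
        for name in system.surfaces:
            ncomp = int(np.prod(system.surfaces[name].comp_shape))
            terms = {t: np.zeros(ncomp, dtype=complex) for t in TERM_NAMES}
            total = np.zeros(ncomp, dtype=complex)
            for s, c in comps.items():
                dec = dep_moments[s][name]
                total = total + c * dec.total
                for t in TERM_NAMES:
                    terms[t] = terms[t] + c * dec.terms[t]
            moments[name] = total
            decs[name] = TermDecomposition(terms, total)
        leading = max(comps, key=lambda s: abs(comps[s]))
        weight = comps[leading] ** 2 / sum(c * c for c in comps.values())
        label = state_label(leading) if weight >= assignment_threshold else (
            "mixed(" + "+".join(
                state_label(s) for s, c in sorted(
                    comps.items(), key=lambda kv: -kv[1] ** 2)[:2]) + ")")
        obs: Dict[str, Optional[float]] = {}
        obs.update(ir_vcd_observables(moments.get("mu"), moments.get("m"), energy))
        obs.update(raman_roa_observables(moments.get("alpha"), moments.get("Gprime"),
                                         moments.get("Aquad"), energy,
                                         excitation_nm, include_nu4))
        records.append(TransitionRecord(
            initial=g, final_label=label, leading_state=leading,
            leading_weight=float(weight), energy=float(energy),
            kind_weights={s: float(c) for s, c in comps.items()},
            moments=moments, decompositions=decs, observables=obs))
    records.sort(key=lambda r: r.energy)
    return records


def assign_bands(records: List[TransitionRecord], threshold: float = 0.80) -> List[TransitionRecord]:
    """Relabel records by their leading configuration at a given weight threshold."""
    for r in records:
        if r.leading_weight >= threshold:
            r.final_label = state_label(r.leading_state)
        else:
            top = sorted(r.kind_weights.items(), key=lambda kv: -kv[1] ** 2)[:2]
            r.final_label = "mixed(" + "+".join(state_label(s) for s, _ in top) + ")"
    return records


def records_to_frame(records: List[TransitionRecord]) -> "pandas.DataFrame":
    """Flatten transition records into the TSV-ready table."""
    import pandas as pd
    rows = []
    for r in records:
        o = r.observables
        rows.append({
            "energy_cm1": r.energy, "label": r.final_label,
            "leading_weight": r.leading_weight,
            "D": o.get("D"), "R": o.get("R"), "g": o.get("g"),
            "ir": o.get("ir_stick"), "vcd": o.get("vcd_stick"),
            "raman": o.get("raman_stick"), "roa": o.get("roa_stick"),
            "cid": o.get("cid"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# derivative-order contributions (integrated band-intensity split)
# ---------------------------------------------------------------------------

DEFAULT_REGIONS = {
    "fundamental": ((0.0, 2000.0), (2750.0, 3100.0)),
    "anharmonic": ((2000.0, 2750.0), (3100.0, 4000.0)),
}

STICK_KEYS = {"IR": "ir_stick", "VCD": "vcd_stick",
              "Raman": "raman_stick", "ROA": "roa_stick"}


def derivative_order_contributions(system: ModelSystem,
                                   result: Optional[GVPT2Result] = None,
                                   regions: Optional[Dict] = None,
                                   fwhm: float = 8.0,
                                   grid_step: float = 1.0) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Percentage contributions of first/second/third property derivatives.

    Spectra are generated with derivative caps 1, 1+2 and 1+2+3 over
    identical states; for each kind and wavenumber region,
    ``n(third) = (I_123 - I_12)/I_123 * 100``, ``n(second) = (I_12 - I_1)/I_123 * 100``
    and ``n(first) = 100 - n(second) - n(third)`` with ``I = integral |S| d nu``.
    Windows with I_123 = 0 are reported as undefined (NaN).
    """
    from .spectra_io import convolve

    if result is None:
        result = gvpt2_solve(system.force_field, system.coriolis)
    regions = regions or DEFAULT_REGIONS
    caps = {1: None, 2: None, 3: None}
    for cap in caps:
        caps[cap] = compute_transitions(system, result, derivative_order_cap=cap)

    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    for kind, key in STICK_KEYS.items():
        spectra = {}
        for cap, recs in caps.items():
            sticks = [(r.energy, r.observables.get(key) or 0.0) for r in recs]
            spectra[cap] = convolve(sticks, fwhm=fwhm,
                                    grid=(0.0, 4100.0, grid_step), kind=kind)
        out[kind] = {}
        for region, windows in regions.items():
            integrals = {}
            for cap, spec in spectra.items():
                mask = np.zeros_like(spec.grid, dtype=bool)
                for lo, hi in windows:
                    mask |= (spec.grid >= lo) & (spec.grid <= hi)
                integrals[cap] = float(np.trapezoid(np.abs(spec.intensity[mask]),
                                                    spec.grid[mask]))
            i123 = integrals[3]
            if i123 == 0.0:
                out[kind][region] = {"first": float("nan"), "second": float("nan"),
                                     "third": float("nan")}
                continue
            n3 = (integrals[3] - integrals[2]) / i123 * 100.0
            n2 = (integrals[2] - integrals[1]) / i123 * 100.0
            out[kind][region] = {"first": 100.0 - n2 - n3, "second": n2, "third": n3}
    return out
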