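"""VPT2 energies, resonance detection, deperturbation and the variational step.

Second-order vibrational perturbation theory on the quartic potential
``V = 1/2 sum w q^2 + 1/6 sum f3 qqq + 1/24 sum f4 qqqq`` (cm^-1,
reduced coordinates) with the usual ordering: the cubic terms enter at
second order, the (semidiagonal) quartic terms at first order.  The
resulting level shifts take the Dunham form
``E(v) - E(0) = sum w_i v_i + sum_{i<=j} chi_ij [(v_i+1/2)(v_j+1/2) - 1/4]``.

The anharmonicity matrix is assembled in a partial-fraction form in which
every resonance-prone denominator ``omega_i + omega_j - omega_k`` appears
as an isolated term, so deperturbation (removal of flagged Fermi terms)
is a clean per-term skip:

``chi_ii = f_iiii/16
         - sum_k f_iik^2/32 [4/w_k + 1/(2w_i+w_k) - 1/(2w_i-w_k)]``

``chi_ij = f_iijj/4 - sum_k f_iik f_jjk/(4 w_k)
         - sum_k f_ijk^2/8 [1/(w_i+w_j+w_k) - 1/(w_i+w_j-w_k)
                            + 1/(w_k+w_i-w_j) + 1/(w_k+w_j-w_i)]
         + sum_a B_a zeta^a_ij^2 (w_i/w_j + w_j/w_i)``   (optional Coriolis)

These closed forms were checked against an explicit sum-over-states
Rayleigh-Schrodinger second-order calculation in the harmonic-oscillator
basis; see docs/methods.md for the symbol mapping.

Resonance criteria (defaults; numeric values of every criterion are
stored alongside the pass/fail flags):

Fermi (i,j -> k):  |w_i+w_j-w_k| <= 200;  f_ijk^4 >= 64 (1+d)^2 (w_i+w_j-w_k)^2;
                   |f_ijk| >= 0.02 |(w_i+w_j-w_k)^2 (1+d)|
Darling-Dennison:  detuning <= 200;  |<a|H~|b>| >= 10;  (1-1 only)
                   max |c2| >= 0.03 for the second-order wavefunction
                   coefficient linking the two fundamentals.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial, sqrt
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .model_core import (
    CoriolisData,
    InputError,
    QuarticForceField,
    VibState,
    enumerate_final_states,
)

DEFAULT_FERMI_THRESHOLDS = {"window": 200.0, "depth": 64.0, "intensity": 0.02}
DEFAULT_DD_THRESHOLDS = {"window": 200.0, "coupling": 10.0, "c2": 0.03}


class ResonanceError(RuntimeError):
    """An exact zero denominator survived detection: review the thresholds."""


# ---------------------------------------------------------------------------
# harmonic-oscillator ladder algebra on sparse product states
# ---------------------------------------------------------------------------
# One-dimensional states are dicts {level: complex amplitude}; operators act
# right-to-left.  With <0|q|1> = 1/sqrt(2):  q|k> = sqrt(k/2)|k-1> +
# sqrt((k+1)/2)|k+1>,  p|k> = i/sqrt(2) (sqrt(k+1)|k+1> - sqrt(k)|k-1>).


def _apply_q(vec: Dict[int, complex]) -> Dict[int, complex]:
    out: Dict[int, complex] = {}
    for k, c in vec.items():
        if k > 0:
            out[k - 1] = out.get(k - 1, 0.0) + c * sqrt(k / 2.0)
        out[k + 1] = out.get(k + 1, 0.0) + c * sqrt((k + 1) / 2.0)
    return out


def _apply_p(vec: Dict[int, complex]) -> Dict[int, complex]:
    out: Dict[int, complex] = {}
    for k, c in vec.items():
        out[k + 1] = out.get(k + 1, 0.0) + 1j * c * sqrt((k + 1) / 2.0)
        if k > 0:
            out[k - 1] = out.get(k - 1, 0.0) - 1j * c * sqrt(k / 2.0)
    return out


@lru_cache(maxsize=200000)
def elem_1d(bra: int, ops: str, ket: int) -> complex:
    """<bra| ops |ket> for a string of 'q'/'p' factors on one mode (leftmost acts last)."""
    vec: Dict[int, complex] = {ket: 1.0 + 0.0j}
    for ch in reversed(ops):
        vec = _apply_q(vec) if ch == "q" else _apply_p(vec)
    return vec.get(bra, 0.0 + 0.0j)


def q_power_element(bra: int, power: int, ket: int) -> float:
    return elem_1d(bra, "q" * power, ket).real


def _monomials(ff: QuarticForceField, order: int):
    """(coefficient, {mode: power}) for V3 or V4 as stored canonically.

    The potential's full symmetric sum collapses onto canonical keys with a
    multinomial weight: coeff = f * (order! / prod(rep!)) / order!.
    """
    items = ff.cubic_items() if order == 3 else ff.quartic_items()
    out = []
    for key, f in items:
        counts = Counter(key)
        mult = factorial(order)
        for c in counts.values():
            mult //= factorial(c)
        out.append((f * mult / factorial(order), dict(counts)))
    return out


def potential_element(ff: QuarticForceField, bra: VibState, ket: VibState,
                      orders: Tuple[int, ...] = (3, 4)) -> float:
    """<bra|V3(+V4)|ket> between harmonic-oscillator product states (cm^-1)."""
    val = 0.0
    for order in orders:
        for coeff, powers in _monomials(ff, order):
            term = coeff
            for m, p in powers.items():
                term *= q_power_element(bra[m], p, ket[m])
                if term == 0.0:
                    break
            else:
                # modes not touched by the monomial must match
                if all(bra[m] == ket[m] for m in range(len(bra)) if m not in powers):
                    val += term
    return val


def _connected_states(state: VibState, powers: Dict[int, int]):
    """States u with potentially nonzero <u| monomial |state>."""
    deltas = []
    modes = list(powers)
    for m in modes:
        p = powers[m]
        deltas.append([d for d in range(-p, p + 1, 2) if state[m] + d >= 0])
    for combo in itertools.product(*deltas):
        u = list(state)
        for m, d in zip(modes, combo):
            u[m] += d
        yield tuple(u)


def cubic_connected(ff: QuarticForceField, state: VibState) -> Dict[VibState, float]:
    """All <u|V3|state> elements with u != state."""
    out: Dict[VibState, float] = {}
    for coeff, powers in _monomials(ff, 3):
        for u in _connected_states(state, powers):
            if u == state:
                continue
            term = coeff
            for m, p in powers.items():
                term *= q_power_element(u[m], p, state[m])
                if term == 0.0:
                    break
            else:
                out[u] = out.get(u, 0.0) + term
    return {u: v for u, v in out.items() if v != 0.0}


def harmonic_energy(omega: np.ndarray, state: VibState) -> float:
    return float(sum(w * (v + 0.5) for w, v in zip(omega, state)))


# ---------------------------------------------------------------------------
# resonance records
# ---------------------------------------------------------------------------

FermiKey = Tuple[Tuple[int, int], int]  # ((i<=j), k): omega_i+omega_j ~ omega_k


@dataclass
class FermiRecord:
    i: int
    j: int
    k: int
    detuning: float          # omega_i + omega_j - omega_k
    f_ijk: float
    lhs_depth: float         # f^4
    rhs_depth: float         # 64 (1+d)^2 detuning^2
    lhs_intensity: float     # |f|
    rhs_intensity: float     # 0.02 |detuning^2 (1+d)|
    pass_window: bool
    pass_depth: bool
    pass_intensity: bool

    @property
    def flagged(self) -> bool:
        return self.pass_window and self.pass_depth and self.pass_intensity

    @property
    def key(self) -> FermiKey:
        return (tuple(sorted((self.i, self.j))), self.k)


@dataclass
class DD11Record:
    i: int
    j: int
    detuning: float
    coupling: float
    c2_max: float
    pass_window: bool
    pass_coupling: bool
    pass_c2: bool

    @property
    def flagged(self) -> bool:
        return self.pass_window and self.pass_coupling and self.pass_c2


@dataclass
class DD22Record:
    state_a: VibState
    state_b: VibState
    detuning: float
    coupling: float
    pass_window: bool
    pass_coupling: bool

    @property
    def flagged(self) -> bool:
        return self.pass_window and self.pass_coupling


@dataclass
class ResonanceSet:
    fermi: List[FermiRecord] = field(default_factory=list)
    dd11: List[DD11Record] = field(default_factory=list)
    dd22: List[DD22Record] = field(default_factory=list)
    thresholds: Dict = field(default_factory=dict)

    def fermi_flags(self) -> FrozenSet[FermiKey]:
        return frozenset(r.key for r in self.fermi if r.flagged)

    def flagged_fermi(self) -> List[FermiRecord]:
        return [r for r in self.fermi if r.flagged]

    def flagged_dd11(self) -> List[DD11Record]:
        return [r for r in self.dd11 if r.flagged]

    def flagged_dd22(self) -> List[DD22Record]:
        return [r for r in self.dd22 if r.flagged]


def detect_fermi(ff: QuarticForceField,
                 thresholds: Optional[Dict[str, float]] = None,
                 delta_convention: str = "doubled",
                 use_intensity_criterion: bool = True) -> ResonanceSet:
    """Evaluate the three Fermi criteria for every (i<=j -> k) triple.

    ``delta_convention`` places the Kronecker-delta weight either on the
    doubled combination index (``"doubled"``: d=1 when i==j, the overtone
    case; default) or verbatim on j==k (``"verbatim"``).  ``use_intensity_criterion=False``
    drops the third (intensity-singularity) criterion.  The third criterion
    compares |f| (cm^-1) against a squared detuning as printed, i.e. the
    0.02 threshold carries the mixed dimension of the printed form.
    """
    thr = dict(DEFAULT_FERMI_THRESHOLDS)
    thr.update(thresholds or {})
    omega = ff.omega
    res = ResonanceSet(thresholds={"fermi": thr, "delta_convention": delta_convention,
                                   "use_intensity_criterion": use_intensity_criterion})
    n = ff.n_modes
    for i in range(n):
        for j in range(i, n):
            for k in range(n):
                if k == i or k == j:
                    continue
                f = ff.f3(i, j, k)
                det = omega[i] + omega[j] - omega[k]
                if delta_convention == "doubled":
                    d = 1.0 if i == j else 0.0
                else:
                    d = 1.0 if j == k else 0.0
                lhs_depth = f ** 4
                rhs_depth = thr["depth"] * (1.0 + d) ** 2 * det ** 2
                lhs_intensity = abs(f)
                rhs_intensity = thr["intensity"] * abs(det ** 2 * (1.0 + d))
                p_win = abs(det) <= thr["window"]
                p_dep = lhs_depth >= rhs_depth and f != 0.0
                p_int = (lhs_intensity >= rhs_intensity and f != 0.0) if use_intensity_criterion else True
                rec = FermiRecord(i, j, k, float(det), f, lhs_depth, rhs_depth,
                                  lhs_intensity, rhs_intensity, p_win, p_dep, p_int)
                if rec.pass_window or rec.flagged:
                    res.fermi.append(rec)
    return res


# ---------------------------------------------------------------------------
# anharmonicity matrix
# ---------------------------------------------------------------------------

@dataclass
class ChiMatrix:
    values: np.ndarray                 # symmetric (n, n), cm^-1
    deperturbed: List[FermiKey] = field(default_factory=list)

    @property
    def is_deperturbed(self) -> bool:
        return bool(self.deperturbed)


def _safe_inv(den: float, key: FermiKey, flags: FrozenSet[FermiKey],
              removed: set) -> float:
    """1/den for a resonance-prone denominator; 0 with bookkeeping if flagged."""
    if key in flags:
        removed.add(key)
        return 0.0
    if den == 0.0:
        raise ResonanceError(
            f"exact zero denominator for triple {key} not flagged as a resonance; "
            "review the Fermi thresholds")
    return 1.0 / den


def anharmonic_constants(ff: QuarticForceField,
                         coriolis: Optional[CoriolisData] = None,
                         resonances: Optional[ResonanceSet] = None) -> ChiMatrix:
    """Assemble the chi matrix, skipping flagged resonant denominators."""
    flags = resonances.fermi_flags() if resonances is not None else frozenset()
    omega = ff.omega
    n = ff.n_modes
    chi = np.zeros((n, n))
    removed: set = set()
    for i in range(n):
        val = ff.f4(i, i, i, i) / 16.0
        for k in range(n):
            f = ff.f3(i, i, k)
            if f == 0.0:
                continue
            inv_res = _safe_inv(2.0 * omega[i] - omega[k], ((i, i), k), flags, removed)
            val -= (f * f / 32.0) * (4.0 / omega[k]
                                     + 1.0 / (2.0 * omega[i] + omega[k])
                                     - inv_res)
        chi[i, i] = val
    for i in range(n):
        for j in range(i + 1, n):
            val = ff.f4(i, i, j, j) / 4.0
            a, b = omega[i], omega[j]
            for k in range(n):
                val -= ff.f3(i, i, k) * ff.f3(j, j, k) / (4.0 * omega[k])
                f = ff.f3(i, j, k)
                if f != 0.0:
                    c = omega[k]
                    inv_ij_k = _safe_inv(a + b - c, (tuple(sorted((i, j))), k), flags, removed)
                    inv_ik_j = _safe_inv(c + a - b, (tuple(sorted((i, k))), j), flags, removed)
                    inv_jk_i = _safe_inv(c + b - a, (tuple(sorted((j, k))), i), flags, removed)
                    val -= (f * f / 8.0) * (1.0 / (a + b + c) - inv_ij_k
                                            + inv_ik_j + inv_jk_i)
            if coriolis is not None and coriolis.present:
                for ax in range(3):
                    val += (coriolis.rotational_constants[ax]
                            * coriolis.zeta[ax, i, j] ** 2 * (a / b + b / a))
            chi[i, j] = chi[j, i] = val
    return ChiMatrix(chi, sorted(removed))


def state_energy(chi: ChiMatrix, omega: np.ndarray, quanta: VibState) -> float:
    """E(v) - E(0) in cm^-1 from the Dunham-form level expression."""
    if sum(quanta) > 2:
        raise InputError("only states with total quanta <= 2 are enumerated")
    e = float(sum(w * v for w, v in zip(omega, quanta)))
    n = len(quanta)
    for i in range(n):
        for j in range(i, n):
            e += chi.values[i, j] * ((quanta[i] + 0.5) * (quanta[j] + 0.5) - 0.25)
    return e


# ---------------------------------------------------------------------------
# VPT2 wavefunction coefficients
# ---------------------------------------------------------------------------

def _is_fermi_pair(a: VibState, b: VibState, flags: FrozenSet[FermiKey]) -> bool:
    """True if {a, b} is a (fundamental, two-quanta) pair of a flagged triple."""
    for fund, dbl in ((a, b), (b, a)):
        if sum(fund) == 1 and sum(dbl) == 2:
            k = fund.index(1)
            nz = [(m, v) for m, v in enumerate(dbl) if v]
            ij = tuple(sorted(sum(([m] * v for m, v in nz), [])))
            if (ij, k) in flags:
                return True
    return False


class WavefunctionCoeffs:
    """Perturbative coefficients of one VPT2 state over the HO product basis.

    First-order coefficients come from the cubic potential,
    ``c1_u = <u|V3|v> / (E_v - E_u)`` (harmonic energies); second-order
    coefficients add the quartic direct term and the cubic double sum.
    Coefficients whose denominators correspond to flagged Fermi pairs (or,
    optionally, flagged 1-1 Darling-Dennison pairs) are exactly zero: those
    interactions are treated variationally instead.
    """

    def __init__(self, ff: QuarticForceField, state: VibState,
                 fermi_flags: FrozenSet[FermiKey] = frozenset(),
                 dd_pairs: FrozenSet[Tuple[VibState, VibState]] = frozenset()):
        self.ff = ff
        self.state = state
        self.fermi_flags = fermi_flags
        self.dd_pairs = dd_pairs
        self._e0 = harmonic_energy(ff.omega, state)
        self._v3 = cubic_connected(ff, state)
        self.c1: Dict[VibState, float] = {}
        for u, el in self._v3.items():
            if self._zeroed(state, u):
                continue
            den = self._e0 - harmonic_energy(ff.omega, u)
            if den == 0.0:
                raise ResonanceError(
                    f"zero denominator between {state} and {u} not flagged; "
                    "review resonance thresholds")
            self.c1[u] = el / den
        self.norm1_sq = float(sum(c * c for c in self.c1.values()))

    def _zeroed(self, v: VibState, u: VibState) -> bool:
        if _is_fermi_pair(v, u, self.fermi_flags):
            return True
        pair = tuple(sorted((v, u)))
        return pair in self.dd_pairs

    @property
    def normalization(self) -> float:
        """<psi|psi> through second order in the wavefunction (= 1 + <psi1|psi1>)."""
        return 1.0 + self.norm1_sq

    def c2(self, u: VibState) -> float:
        """Second-order coefficient of basis state u (u != state)."""
        if u == self.state:
            return 0.0
        if self._zeroed(self.state, u):
            return 0.0
        den_u = self._e0 - harmonic_energy(self.ff.omega, u)
        if den_u == 0.0:
            raise ResonanceError(f"zero denominator between {self.state} and {u}")
        val = potential_element(self.ff, u, self.state, orders=(4,)) / den_u
        for w, el_wv in self._v3.items():
            if self._zeroed(self.state, w):
                continue
            den_w = self._e0 - harmonic_energy(self.ff.omega, w)
            el_uw = potential_element(self.ff, u, w, orders=(3,))
            if el_uw != 0.0:
                val += el_uw * el_wv / (den_u * den_w)
        return val


# ---------------------------------------------------------------------------
# Darling-Dennison detection
# ---------------------------------------------------------------------------

def contact_coupling(ff: QuarticForceField, state_a: VibState, state_b: VibState,
                     fermi_flags: FrozenSet[FermiKey] = frozenset()) -> float:
    """Off-diagonal element <a|H~|b> of the second-order effective Hamiltonian.

    Van Vleck form: the direct V3+V4 element plus
    ``1/2 sum_w <a|V3|w><w|V3|b> [1/(E_a-E_w) + 1/(E_b-E_w)]`` over
    intermediates outside the {a, b} model space.  Intermediates reached
    through a flagged Fermi denominator are excluded (they belong to the
    variational block, not to the transformation).
    """
    ea = harmonic_energy(ff.omega, state_a)
    eb = harmonic_energy(ff.omega, state_b)
    val = potential_element(ff, state_a, state_b, orders=(3, 4))
    va = cubic_connected(ff, state_a)
    vb = cubic_connected(ff, state_b)
    for w, el_aw in va.items():
        if w == state_b:
            continue
        el_wb = vb.get(w)
        if el_wb is None:
            continue
        if _is_fermi_pair(state_a, w, fermi_flags) or _is_fermi_pair(state_b, w, fermi_flags):
            continue
        da = ea - harmonic_energy(ff.omega, w)
        db = eb - harmonic_energy(ff.omega, w)
        if da == 0.0 or db == 0.0:
            raise ResonanceError(f"degenerate intermediate {w} in contact transformation")
        val += 0.5 * el_aw * el_wb * (1.0 / da + 1.0 / db)
    return val


def dd_coupling(ff: QuarticForceField, state_a: VibState, state_b: VibState,
                fermi_flags: FrozenSet[FermiKey] = frozenset()) -> float:
    """Darling-Dennison coupling constant (cm^-1) between two states.

    For 1-1 resonances the states are two fundamentals; for 2-2 resonances
    two overtone/combination states.
    """
    return contact_coupling(ff, state_a, state_b, fermi_flags)


def detect_dd(ff: QuarticForceField, resonances: ResonanceSet,
              thresholds: Optional[Dict[str, float]] = None) -> ResonanceSet:
    """Append Darling-Dennison records (1-1 and 2-2) to a Fermi resonance set."""
    thr = dict(DEFAULT_DD_THRESHOLDS)
    thr.update(thresholds or {})
    resonances.thresholds["dd"] = thr
    omega = ff.omega
    n = ff.n_modes
    flags = resonances.fermi_flags()
    # 1-1: pairs of fundamentals
    for i in range(n):
        for j in range(i + 1, n):
            det = float(omega[i] - omega[j])
            if abs(det) > thr["window"]:
                continue
            a = tuple(1 if m == i else 0 for m in range(n))
            b = tuple(1 if m == j else 0 for m in range(n))
            k = contact_coupling(ff, a, b, flags)
            wa = WavefunctionCoeffs(ff, a, flags)
            wb = WavefunctionCoeffs(ff, b, flags)
            c2 = max(abs(wa.c2(b)), abs(wb.c2(a)))
            resonances.dd11.append(DD11Record(
                i, j, det, float(k), float(c2),
                pass_window=True, pass_coupling=abs(k) >= thr["coupling"], pass_c2=c2 >= thr["c2"]))
    # 2-2: pairs of two-quanta states
    doubles = [s for s in enumerate_final_states(n) if sum(s) == 2]
    for a, b in itertools.combinations(doubles, 2):
        det = harmonic_energy(omega, a) - harmonic_energy(omega, b)
        if abs(det) > thr["window"]:
            continue
        if _is_fermi_pair(a, b, flags):
            continue
        k = contact_coupling(ff, a, b, flags)
        resonances.dd22.append(DD22Record(
            a, b, float(det), float(k),
            pass_window=True, pass_coupling=abs(k) >= thr["coupling"]))
    return resonances


# ---------------------------------------------------------------------------
# GVPT2: deperturbation + variational step
# ---------------------------------------------------------------------------

@dataclass
class VariationalBlock:
    states: List[VibState]
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are eigenstates over `states`


@dataclass
class GVPT2Result:
    omega: np.ndarray
    chi: ChiMatrix
    resonances: ResonanceSet
    deperturbed_energies: Dict[VibState, float]
    blocks: List[VariationalBlock]
    state_to_block: Dict[VibState, int]

    def eigenstates(self):
        """Yield (energy, {deperturbed state: coefficient}) for all final states.

        Non-resonant states come back unmixed; members of a variational
        block are replaced by the block eigenstates.
        """
        for s, e in self.deperturbed_energies.items():
            if s not in self.state_to_block:
                yield e, {s: 1.0}
        for blk in self.blocks:
            for col in range(len(blk.states)):
                comps = {s: blk.eigenvectors[r, col] for r, s in enumerate(blk.states)}
                yield float(blk.eigenvalues[col]), comps

    def energy(self, state: VibState) -> float:
        """Final energy of the eigenstate dominated by `state`."""
        if state not in self.state_to_block:
            return self.deperturbed_energies[state]
        blk = self.blocks[self.state_to_block[state]]
        r = blk.states.index(state)
        col = int(np.argmax(np.abs(blk.eigenvectors[r, :])))
        return float(blk.eigenvalues[col])


def gvpt2_solve(ff: QuarticForceField,
                coriolis: Optional[CoriolisData] = None,
                fermi_thresholds: Optional[Dict[str, float]] = None,
                dd_thresholds: Optional[Dict[str, float]] = None,
                delta_convention: str = "doubled",
                use_intensity_criterion: bool = True,
                block_cap: int = 30) -> GVPT2Result:
    """Full GVPT2: detect, deperturb, re-diagonalize.

    Resonant states are partitioned into connected blocks (transitive
    closure over flagged interactions).  Each block's matrix carries the
    deperturbed VPT2 energies on the diagonal; off-diagonals are the cubic
    element for flagged Fermi links and the contact-transformed coupling
    for flagged Darling-Dennison links (unflagged pairs inside a chained
    block stay zero - their interaction remains perturbative).
    """
    resonances = detect_fermi(ff, fermi_thresholds, delta_convention,
                              use_intensity_criterion)
    resonances = detect_dd(ff, resonances, dd_thresholds)
    flags = resonances.fermi_flags()
    chi = anharmonic_constants(ff, coriolis, resonances)
    n = ff.n_modes
    energies: Dict[VibState, float] = {}
    for s in enumerate_final_states(n):
        energies[s] = state_energy(chi, ff.omega, s)

    # interaction graph over final states
    edges: Dict[Tuple[VibState, VibState], float] = {}

    def add_edge(a: VibState, b: VibState, coupling: float):
        key = tuple(sorted((a, b)))
        edges[key] = coupling

    for rec in resonances.flagged_fermi():
        dbl = [0] * n
        dbl[rec.i] += 1
        dbl[rec.j] += 1
        a = tuple(dbl)
        b = tuple(1 if m == rec.k else 0 for m in range(n))
        add_edge(a, b, potential_element(ff, a, b, orders=(3,)))
    for rec in resonances.flagged_dd11():
        a = tuple(1 if m == rec.i else 0 for m in range(n))
        b = tuple(1 if m == rec.j else 0 for m in range(n))
        add_edge(a, b, rec.coupling)
    for rec in resonances.flagged_dd22():
        add_edge(rec.state_a, rec.state_b, rec.coupling)

    # connected components
    parent: Dict[VibState, VibState] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    groups: Dict[VibState, List[VibState]] = {}
    for s in parent:
        groups.setdefault(find(s), []).append(s)

    blocks: List[VariationalBlock] = []
    state_to_block: Dict[VibState, int] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        if len(members) > block_cap:
            raise ResonanceError(
                f"variational block of {len(members)} states exceeds the cap of "
                f"{block_cap}; tighten the resonance thresholds")
        members = sorted(members, key=lambda s: energies[s])
        m = len(members)
        mat = np.diag([energies[s] for s in members])
        for (a, b), w in edges.items():
            if a in members and b in members:
                ia, ib = members.index(a), members.index(b)
                mat[ia, ib] = mat[ib, ia] = w
        evals, evecs = np.linalg.eigh(mat)
        blk = VariationalBlock(members, mat, evals, evecs)
        idx = len(blocks)
        blocks.append(blk)
        for s in members:
            state_to_block[s] = idx

    return GVPT2Result(ff.omega, chi, resonances, energies, blocks, state_to_block)


def resonance_report(result: GVPT2Result) -> "pandas.DataFrame":
    """Tabulate every resonance candidate with its criterion values and flags."""
    import pandas as pd
    rows = []
    for r in result.resonances.fermi:
        rows.append({"type": "fermi", "a": f"{r.i + 1}+{r.j + 1}", "b": str(r.k + 1),
                     "detuning": r.detuning, "coupling": r.f_ijk,
                     "crit1": r.pass_window, "crit2": r.pass_depth, "crit3": r.pass_intensity,
                     "lhs2": r.lhs_depth, "rhs2": r.rhs_depth,
                     "lhs3": r.lhs_intensity, "rhs3": r.rhs_intensity, "flagged": r.flagged})
    for r in result.resonances.dd11:
        rows.append({"type": "dd11", "a": str(r.i + 1), "b": str(r.j + 1),
                     "detuning": r.detuning, "coupling": r.coupling,
                     "crit1": r.pass_window, "crit2": r.pass_coupling, "crit3": r.pass_c2,
                     "lhs3": r.c2_max, "flagged": r.flagged})
    for r in result.resonances.dd22:
        rows.append({"type": "dd22", "a": str(r.state_a), "b": str(r.state_b),
                     "detuning": r.detuning, "coupling": r.coupling,
                     "crit1": r.pass_window, "crit2": r.pass_coupling, "flagged": r.flagged})
    return pd.DataFrame(rows)
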