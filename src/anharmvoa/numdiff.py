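"""Two-step finite differencing along normal modes.

Cubic and semidiagonal quartic force constants are built from analytic
Hessians evaluated at +/- one displacement per mode; second and
semidiagonal third property derivatives are built the same way from
analytic first-derivative tensors.  Displacements are specified in
mass-weighted units (default 0.01 amu^1/2 Angstrom) and converted per
mode to reduced coordinates, so the step in q grows with sqrt(omega).

Only semidiagonal higher constants are obtainable from single-mode
double displacements; fully off-diagonal third property derivatives and
quartics are outside this protocol by construction.

Evaluator contract: callables receive a displacement vector in reduced
coordinates and must keep the normal-mode phase convention fixed across
all displaced evaluations.  Polynomial synthetic surfaces are phase-fixed
trivially; ingestion of real quantum-chemistry output has to document its
own phase handling (sign flips between displaced evaluations of near-
degenerate modes are the classic failure mode of this protocol).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

from .model_core import (
    InputError,
    ModelSystem,
    NormalModes,
    PropertySurface,
    QuarticForceField,
    reduced_step_from_massweighted,
)

DEFAULT_STEP_Q = 0.01  # amu^1/2 Angstrom


def _check_finite(arr, what, disp):
    if not np.all(np.isfinite(arr)):
        raise InputError(f"non-finite {what} at displacement {np.asarray(disp)}")


def hessian_evaluator_from_system(system: ModelSystem) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic Hessian (cm^-1, reduced coordinates) of the stored quartic polynomial.

    With the fully symmetric force constants of the potential
    ``V = 1/2 sum w q^2 + 1/6 sum f3 qqq + 1/24 sum f4 qqqq`` the Hessian is
    ``H_xy = w_x d_xy + sum_a f3_axy q_a + 1/2 sum_ab f4_abxy q_a q_b``.
    """
    ff = system.force_field
    n = ff.n_modes

    def hessian(q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if q.shape != (n,):
            raise InputError(f"displacement must have shape ({n},)")
        H = np.diag(ff.omega.astype(float)).copy()
        for x in range(n):
            for y in range(x, n):
                val = 0.0
                for a in range(n):
                    val += ff.f3(a, x, y) * q[a]
                    for b in range(n):
                        val += 0.5 * ff.f4(a, b, x, y) * q[a] * q[b]
                H[x, y] += val
                if x != y:
                    H[y, x] += val
        _check_finite(H, "Hessian", q)
        return H

    return hessian


def property_d1_evaluator_from_system(system: ModelSystem, name: str):
    """Analytic first-derivative tensor dX/dq_i of a stored polynomial surface.

    ``dX/dq_i = d1_i + sum_j d2_ij q_j + 1/2 sum_jk T3_ijk q_j q_k`` with the
    fully symmetric third-derivative tensor read through semidiagonal
    storage (fully off-diagonal entries are zero).
    """
    s = system.surfaces[name]
    n = s.n_modes

    def d1(q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if q.shape != (n,):
            raise InputError(f"displacement must have shape ({n},)")
        out = s.d1 + np.tensordot(q, s.d2, axes=(0, 1))
        for key, val in s.d3_items():
            for perm in sorted(set(itertools.permutations(key))):
                i, j, k = perm
                out[i] += 0.5 * val * q[j] * q[k]
        _check_finite(out, f"{name} first derivatives", q)
        return out

    return d1


def reduced_steps(modes: NormalModes, step_Q: float) -> np.ndarray:
    return np.array([reduced_step_from_massweighted(step_Q, w) for w in modes.omega])


@dataclass
class FiniteDiffResult:
    force_field: QuarticForceField
    max_asymmetry: float  # largest spread among permutation-equivalent estimates, cm^-1


def cubic_quartic_from_hessians(hessian: Callable[[np.ndarray], np.ndarray],
                                modes: NormalModes,
                                step_Q: float = DEFAULT_STEP_Q) -> FiniteDiffResult:
    """Cubic and semidiagonal quartic constants from central differences of Hessians.

    ``f_ijk`` comes from the first central difference of ``H_jk`` along mode
    i, averaged over the permutation-equivalent displacement choices (the
    spread is reported as ``max_asymmetry``); ``f_iijk`` from the symmetric
    second difference of ``H_jk`` along mode i.  Central differences are
    exact through the polynomial order of the stencil, so quartic
    polynomial surfaces are recovered to rounding error.
    """
    if step_Q <= 0:
        raise InputError("step must be positive")
    n = modes.n_modes
    delta = reduced_steps(modes, step_Q)
    zero = np.zeros(n)
    H0 = np.asarray(hessian(zero), dtype=float)
    if not np.allclose(H0, H0.T):
        raise InputError("evaluator must return symmetric Hessians")
    Hp, Hm = [], []
    for i in range(n):
        d = zero.copy(); d[i] = delta[i]
        Hp.append(np.asarray(hessian(d), dtype=float))
        d = zero.copy(); d[i] = -delta[i]
        Hm.append(np.asarray(hessian(d), dtype=float))

    ff = QuarticForceField(modes)
    max_asym = 0.0
    for key in itertools.combinations_with_replacement(range(n), 3):
        ests = []
        for disp in sorted(set(key)):
            rest = list(key)
            rest.remove(disp)
            j, k = rest
            ests.append((Hp[disp][j, k] - Hm[disp][j, k]) / (2.0 * delta[disp]))
        if len(ests) > 1:
            max_asym = max(max_asym, float(np.ptp(ests)))
        ff.set_cubic(key, float(np.mean(ests)))
    for key in itertools.combinations_with_replacement(range(n), 4):
        doubled = [m for m, c in Counter(key).items() if c >= 2]
        if not doubled:
            continue
        ests = []
        for i in doubled:
            rest = list(key)
            rest.remove(i); rest.remove(i)
            j, k = rest
            ests.append((Hp[i][j, k] + Hm[i][j, k] - 2.0 * H0[j, k]) / delta[i] ** 2)
        if len(ests) > 1:
            max_asym = max(max_asym, float(np.ptp(ests)))
        ff.set_quartic(key, float(np.mean(ests)))
    return FiniteDiffResult(ff, max_asym)


@dataclass
class PropertyDiffResult:
    d2: np.ndarray
    d3: Dict[Tuple[int, int, int], np.ndarray]
    max_asymmetry: float


def property_higher_derivatives(d1_evaluator: Callable[[np.ndarray], np.ndarray],
                                modes: NormalModes,
                                step_Q: float = DEFAULT_STEP_Q) -> PropertyDiffResult:
    """Second (full) and semidiagonal third derivatives of one property tensor.

    ``d1_evaluator(q)`` must return the analytic first-derivative array of
    shape ``(n_modes, *components)`` at displacement q.
    """
    if step_Q <= 0:
        raise InputError("step must be positive")
    n = modes.n_modes
    delta = reduced_steps(modes, step_Q)
    zero = np.zeros(n)
    D0 = np.asarray(d1_evaluator(zero), dtype=float)
    _check_finite(D0, "first derivatives", zero)
    Dp, Dm = [], []
    for i in range(n):
        d = zero.copy(); d[i] = delta[i]
        Dp.append(np.asarray(d1_evaluator(d), dtype=float))
        d = zero.copy(); d[i] = -delta[i]
        Dm.append(np.asarray(d1_evaluator(d), dtype=float))

    comp = D0.shape[1:]
    d2 = np.zeros((n, n) + comp)
    max_asym = 0.0
    for i in range(n):
        for j in range(i, n):
            est_ij = (Dp[i][j] - Dm[i][j]) / (2.0 * delta[i])
            est_ji = (Dp[j][i] - Dm[j][i]) / (2.0 * delta[j])
            if i != j:
                max_asym = max(max_asym, float(np.max(np.abs(est_ij - est_ji))))
            avg = 0.5 * (est_ij + est_ji)
            d2[i, j] = avg
            d2[j, i] = avg
    d3: Dict[Tuple[int, int, int], np.ndarray] = {}
    for key in itertools.combinations_with_replacement(range(n), 3):
        doubled = [m for m, c in Counter(key).items() if c >= 2]
        if not doubled:
            continue
        ests = []
        for i in doubled:
            rest = list(key)
            rest.remove(i); rest.remove(i)
            (j,) = rest
            ests.append((Dp[i][j] + Dm[i][j] - 2.0 * D0[j]) / delta[i] ** 2)
        if len(ests) > 1:
            max_asym = max(max_asym, float(np.max(np.ptp(np.asarray(ests), axis=0))))
        d3[key] = np.mean(ests, axis=0)
    return PropertyDiffResult(d2, d3, max_asym)


def refit_system(system: ModelSystem, step_Q: float = DEFAULT_STEP_Q) -> ModelSystem:
    """Round-trip a system through the finite-difference protocol.

    Builds analytic evaluators from the stored polynomial force field and
    surfaces, runs the differencing, and returns the re-fitted system.
    """
    ff_res = cubic_quartic_from_hessians(hessian_evaluator_from_system(system),
                                         system.force_field.modes, step_Q)
    surfaces = {}
    for name, s in system.surfaces.items():
        res = property_higher_derivatives(property_d1_evaluator_from_system(system, name),
                                          system.force_field.modes, step_Q)
        surfaces[name] = PropertySurface(name, s.n_modes, value0=s.value0, d1=s.d1,
                                         d2=res.d2, d3=res.d3, conjugate=s.conjugate)
    meta = dict(system.metadata)
    meta["numdiff_step_Q"] = step_Q
    return ModelSystem(ff_res.force_field, surfaces=surfaces,
                       coriolis=system.coriolis, metadata=meta)
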