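"""Brute-force variational reference solver (<= 3 modes).

The quartic Hamiltonian is assembled in a direct-product harmonic-
oscillator basis truncated by total quanta and diagonalized exactly.  By
the variational principle the eigenvalues decrease monotonically with
basis size; convergence is asserted by re-solving with a larger basis
and requiring the low-lying levels to move by less than a tolerance.

This module deliberately shares no matrix-element code with the
perturbative engine: ladder operators are built as dense numpy matrices
(q = (a + a+)/sqrt(2), p = i (a+ - a)/sqrt(2)), and operator matrices
come from per-mode matrix products, so it is an independent cross-check
of both energies and transition moments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .model_core import InputError, PropertySurface, QuarticForceField, VibState

DEFAULT_MAX_QUANTA = 20     # total quanta in the product basis
CONVERGENCE_INCREMENT = 5
CONVERGENCE_TOL = 0.1       # cm^-1 movement of low-lying levels


class ConvergenceError(RuntimeError):
    """Basis enlargement keeps lowering the levels: the truncated potential
    is probably unbounded at the sampled amplitudes (reduce quartic scales)."""


def _basis(n_modes: int, max_total: int) -> List[VibState]:
    states = [s for s in itertools.product(range(max_total + 1), repeat=n_modes)
              if sum(s) <= max_total]
    states.sort(key=lambda s: (sum(s), s))
    return states


def _ladders(nmax: int):
    a = np.diag(np.sqrt(np.arange(1.0, nmax)), 1)   # annihilation
    q = (a + a.T) / np.sqrt(2.0)
    p = 1j * (a.T - a) / np.sqrt(2.0)
    return q, p


def _mode_matrices(nmax: int, max_power: int = 4) -> Dict[int, np.ndarray]:
    q, _ = _ladders(nmax)
    mats = {0: np.eye(nmax)}
    for k in range(1, max_power + 1):
        mats[k] = mats[k - 1] @ q
    return mats


def _full_monomials(ff: QuarticForceField):
    """(weight, {mode: power}) terms of V3 + V4 from the canonical storage."""
    from collections import Counter
    from math import factorial
    out = []
    for order, items in ((3, ff.cubic_items()), (4, ff.quartic_items())):
        for key, f in items:
            counts = Counter(key)
            mult = factorial(order)
            for c in counts.values():
                mult //= factorial(c)
            out.append((f * mult / factorial(order), dict(counts)))
    return out


@dataclass
class VariationalSolution:
    ff: QuarticForceField
    basis: List[VibState]
    max_quanta: int
    eigenvalues: np.ndarray    # ascending, cm^-1 (absolute, including ZPE)
    eigenvectors: np.ndarray   # columns, phase-fixed (leading HO component > 0)
    index: Dict[VibState, int]

    @property
    def zpe(self) -> float:
        return float(self.eigenvalues[0])

    def level(self, rank: int) -> float:
        """Energy of the rank-th eigenstate relative to the ground state."""
        return float(self.eigenvalues[rank] - self.eigenvalues[0])

    def state_index(self, state: VibState) -> int:
        """Eigenstate dominated by the given harmonic configuration."""
        row = self.index[state]
        return int(np.argmax(np.abs(self.eigenvectors[row, :])))

    def state_energy(self, state: VibState) -> float:
        """E(state) - E(ground) via leading-component assignment."""
        return self.level(self.state_index(state))


def _assemble(ff: QuarticForceField, basis: List[VibState]) -> np.ndarray:
    n = ff.n_modes
    N = len(basis)
    nmax = max(max(s) for s in basis) + 5
    mats = _mode_matrices(nmax)
    levels = np.asarray(basis)  # (N, n)
    H = np.zeros((N, N))
    H[np.diag_indices(N)] = [sum(ff.omega[m] * (s[m] + 0.5) for m in range(n))
                             for s in basis]
    for coeff, powers in _full_monomials(ff):
        term = np.ones((N, N))
        for m in range(n):
            pw = powers.get(m, 0)
            term = term * mats[pw][levels[:, m][:, None], levels[:, m][None, :]]
        H += coeff * term
    return H


def variational_solve(ff: QuarticForceField,
                      max_quanta: int = DEFAULT_MAX_QUANTA,
                      check_convergence: bool = True,
                      convergence_tol: float = CONVERGENCE_TOL,
                      n_check_levels: int = 10) -> VariationalSolution:
    """Diagonalize the quartic Hamiltonian in a total-quanta-truncated HO basis."""
    if ff.n_modes > 3:
        raise InputError("the variational oracle is limited to <= 3 modes")
    diag_quartics = [ff.f4(i, i, i, i) for i in range(ff.n_modes)]
    if any(d < 0 for d in diag_quartics) and not ff.is_harmonic():
        import warnings
        warnings.warn("negative diagonal quartic: truncated potential unbounded; "
                      "variational results may collapse with basis size")

    def solve(mq):
        basis = _basis(ff.n_modes, mq)
        H = _assemble(ff, basis)
        evals, evecs = np.linalg.eigh(H)
        # phase fix: leading HO component of each eigenvector positive
        lead = np.argmax(np.abs(evecs), axis=0)
        signs = np.sign(evecs[lead, np.arange(evecs.shape[1])])
        signs[signs == 0] = 1.0
        return basis, evals, evecs * signs[None, :]

    basis, evals, evecs = solve(max_quanta)
    if check_convergence and not ff.is_harmonic():
        _, evals_big, _ = solve(max_quanta + CONVERGENCE_INCREMENT)
        k = min(n_check_levels, len(evals))
        drop = np.max(np.abs(evals[:k] - evals_big[:k]))
        if drop > convergence_tol:
            raise ConvergenceError(
                f"levels moved by {drop:.3f} cm^-1 on basis enlargement "
                f"(> {convergence_tol}); increase max_quanta or reduce anharmonicity")
    index = {s: i for i, s in enumerate(basis)}
    return VariationalSolution(ff, basis, max_quanta, evals, evecs, index)


def operator_matrix(sol: VariationalSolution, surface: PropertySurface,
                    derivative_order_cap: int = 3) -> np.ndarray:
    """Dense matrix of the property operator over the oracle basis (per component)."""
    n = sol.ff.n_modes
    N = len(sol.basis)
    nmax = max(max(s) for s in sol.basis) + 5
    q, p = _ladders(nmax)
    levels = np.asarray(sol.basis)
    ncomp = int(np.prod(surface.comp_shape))

    from .voa_intensities import operator_terms
    parts = [0] + ([1] if derivative_order_cap >= 2 else []) \
        + ([2] if derivative_order_cap >= 3 else [])
    out = np.zeros((ncomp, N, N), dtype=complex)
    eye = np.eye(nmax, dtype=complex)
    for part in parts:
        for term in operator_terms(surface, part):
            per_mode = []
            for m in range(n):
                ops = term.ops.get(m, "")
                mat = eye
                for ch in reversed(ops):  # leftmost acts last
                    mat = (q if ch == "q" else p) @ mat
                per_mode.append(mat)
            block = np.ones((N, N), dtype=complex)
            for m in range(n):
                block = block * per_mode[m][levels[:, m][:, None], levels[:, m][None, :]]
            out += term.coeff[:, None, None] * block
    return out


def oracle_transition_moment(sol: VariationalSolution, surface: PropertySurface,
                             i_state: VibState, f_state: VibState,
                             derivative_order_cap: int = 3) -> np.ndarray:
    """Exact matrix element of the property operator between oracle eigenstates.

    States are addressed by their leading harmonic configuration; the
    eigenvector phases are fixed so that the result is comparable to the
    perturbative moments.
    """
    mats = operator_matrix(sol, surface, derivative_order_cap)
    vi = sol.eigenvectors[:, sol.state_index(i_state)]
    vf = sol.eigenvectors[:, sol.state_index(f_state)]
    return np.einsum("b,cbk,k->c", vf.conj(), mats, vi)
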