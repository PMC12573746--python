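"""Band convolution, spectral similarity and spectrum file I/O.

Stick spectra are broadened with Lorentzians (default 8 cm^-1 FWHM; each
stick contributes a band of area equal to the stick intensity, so the
peak height is 2 I / (pi FWHM)).  Similarity between two spectra is the
overlap of normalized spectra maximized over a frequency-scaling factor
``a`` close to one:

    s(a) = int S_cal(a w) S_exp(w) dw /
           sqrt( int S_cal^2(a w) dw * int S_exp^2(w) dw )

with s = 1 for identical spectra.  Sign-carrying spectra (VCD, ROA) use
the same formula without absolute values, so wrong signs reduce s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import InputError

logger = logging.getLogger("anharmvoa")

DEFAULT_FWHM = 8.0       # cm^-1
DEFAULT_GRID_STEP = 1.0  # cm^-1


@dataclass
class Spectrum:
    grid: np.ndarray       # cm^-1, ascending, uniform
    intensity: np.ndarray
    kind: str = "IR"       # IR | VCD | Raman | ROA
    units: str = "arb."

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.size < 2 or self.grid.shape != self.intensity.shape:
            raise InputError("spectrum needs matching grids of length >= 2")
        steps = np.diff(self.grid)
        if np.any(steps <= 0):
            raise InputError("grid must be strictly ascending")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
            raise InputError("grid must be uniform")


def convolve(sticks: Sequence[Tuple[float, float]],
             fwhm: float = DEFAULT_FWHM,
             grid: Optional[Tuple[float, float, float]] = None,
             kind: str = "IR") -> Spectrum:
    """Lorentzian broadening of a stick list [(wavenumber, intensity), ...].

    ``grid`` is (min, max, step); when omitted it spans the sticks with a
    margin of 25 FWHM.  Sticks outside the grid still contribute their
    tails but are reported in a warning.
    """
    if fwhm <= 0:
        raise InputError("fwhm must be positive")
    sticks = [(float(e), float(i)) for e, i in sticks]
    if grid is None:
        if not sticks:
            raise InputError("no sticks and no explicit grid")
        lo = min(e for e, _ in sticks) - 25.0 * fwhm
        hi = max(e for e, _ in sticks) + 25.0 * fwhm
        grid = (lo, hi, DEFAULT_GRID_STEP)
    lo, hi, step = grid
    x = np.arange(lo, hi + 0.5 * step, step)
    y = np.zeros_like(x)
    gamma = fwhm / 2.0
    truncated = [e for e, i in sticks if (e < lo or e > hi) and i != 0.0]
    if truncated:
        logger.warning("grid [%g, %g] does not cover %d stick(s): %s",
                       lo, hi, len(truncated), truncated[:5])
    for e, inten in sticks:
        if inten == 0.0:
            continue
        y += inten * (gamma / np.pi) / ((x - e) ** 2 + gamma ** 2)
    return Spectrum(x, y, kind=kind)


@dataclass
class SimilarityResult:
    s: float               # best overlap over the scaling interval
    a: float               # optimal scaling factor
    s_at_1: float          # overlap without frequency scaling
    a_grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    s_grid: np.ndarray = field(default_factory=lambda: np.empty(0))


def _overlap(calc: Spectrum, exp: Spectrum, a: float) -> float:
    # evaluate S_cal(a w) on the experimental grid
    cal = np.interp(a * exp.grid, calc.grid, calc.intensity, left=0.0, right=0.0)
    num = np.trapezoid(cal * exp.intensity, exp.grid)
    n1 = np.trapezoid(cal * cal, exp.grid)
    n2 = np.trapezoid(exp.intensity * exp.intensity, exp.grid)
    if n1 <= 0.0 or n2 <= 0.0:
        raise InputError("zero-norm spectrum: similarity undefined")
    return float(num / np.sqrt(n1 * n2))


def similarity(calc: Spectrum, exp: Spectrum,
               a_bounds: Tuple[float, float] = (0.95, 1.05),
               tol: float = 1e-4) -> SimilarityResult:
    """Best-overlap similarity factor between a computed and a reference spectrum.

    The overlap functional is maximized over the scaling factor on
    ``a_bounds`` by a coarse grid scan refined with bounded scalar
    minimization; the unscaled value s(1) is reported alongside.
    """
    a_grid = np.linspace(a_bounds[0], a_bounds[1], 21)
    s_grid = np.array([_overlap(calc, exp, a) for a in a_grid])
    i = int(np.argmax(s_grid))
    lo = a_grid[max(0, i - 1)]
    hi = a_grid[min(len(a_grid) - 1, i + 1)]
    res = minimize_scalar(lambda a: -_overlap(calc, exp, a),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    a_best = float(res.x)
    s_best = -float(res.fun)
    # the endpoints of the coarse scan can win over the refined interior
    if s_grid[i] > s_best:
        a_best, s_best = float(a_grid[i]), float(s_grid[i])
    s1 = _overlap(calc, exp, 1.0)
    if s1 > s_best:
        a_best, s_best = 1.0, s1
    return SimilarityResult(s_best, a_best, s1, a_grid, s_grid)


def read_spectrum(path, kind: str = "IR") -> Spectrum:
    """Two-column wavenumber/intensity text file ('#' comments allowed).

    Descending grids are normalized to ascending.
    """
    grid: List[float] = []
    inten: List[float] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 2:
                raise InputError(f"{path}:{ln}: expected two columns, got {len(parts)}")
            try:
                w, s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{ln}: {exc}") from None
            grid.append(w)
            inten.append(s)
    g = np.asarray(grid)
    y = np.asarray(inten)
    if g.size >= 2 and np.all(np.diff(g) < 0):
        g, y = g[::-1].copy(), y[::-1].copy()
    return Spectrum(g, y, kind=kind)


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}  units: {spectrum.units}\n")
        for w, s in zip(spectrum.grid, spectrum.intensity):
            fh.write(f"{float(w)!r} {float(s)!r}\n")
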