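"""Synthetic model-system generator.

Produces vibrational problems with controlled anharmonicity, contrived
near-resonances (Fermi and Darling-Dennison) and chiral property
surfaces, so the whole perturbative/variational pipeline can be
exercised and cross-checked without any electronic-structure run.

Property surfaces are exact polynomials of order <= 3 in the reduced
coordinates, which makes finite-difference recovery testable without
truncation-error ambiguity.  Cubic/quartic force constants are drawn
from zero-mean normals scaled so that |f|/omega stays small (the
perturbative regime), except where a resonance plan asks otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    CHIRAL_TENSORS,
    InputError,
    ModelSystem,
    NormalModes,
    PropertySurface,
    QuarticForceField,
    TENSOR_SHAPES,
)

_STREAM = "numpy.random.default_rng/PCG64"


@dataclass
class FermiPlan:
    """Request a near-degeneracy omega_k ~ omega_i + omega_j with cubic coupling f_ijk.

    ``i == j`` plants an overtone-type resonance (2 omega_i ~ omega_k).
    """

    i: int
    j: int
    k: int
    detuning: float = 10.0   # omega_i + omega_j - omega_k, cm^-1
    f: float = 40.0          # |f_ijk|, cm^-1


@dataclass
class DDPlan:
    """Request a 1-1 Darling-Dennison pair: omega_i ~ omega_j with a planted coupling.

    The coupling is realized through the semidiagonal quartic f_iiij,
    whose direct matrix element between the two fundamentals is
    f_iiij / 8 (cm^-1).
    """

    i: int
    j: int
    detuning: float = 20.0
    coupling: float = 20.0   # target |<1_i|H~|1_j>|, cm^-1


@dataclass
class GeneratorSpec:
    n_modes: int = 3
    omega_range: Tuple[float, float] = (700.0, 3100.0)
    cubic_scale: float = 20.0
    quartic_scale: float = 6.0
    resonance_plan: List = field(default_factory=list)
    # property polynomial coefficient scales per derivative order (a.u.);
    # the ~5x fall-off per order mimics the usual hierarchy of electrical
    # anharmonicity (first >> second >> third derivatives)
    d1_scale: float = 0.1
    d2_scale: float = 0.02
    d3_scale: float = 0.004
    tensors: Sequence[str] = tuple(TENSOR_SHAPES)
    chiral: bool = True
    min_fermi_detuning: float = 0.0   # >0 pushes omegas away from any i+j ~ k degeneracy
    seed: int = 0

    def __post_init__(self):
        if self.cubic_scale < 0 or self.quartic_scale < 0:
            raise InputError("scales must be non-negative")
        for plan in self.resonance_plan:
            if plan.detuning < 0:
                raise InputError("requested detunings must be non-negative")


def make_morse_system(omega: float, omega_x: float,
                      mu_d1: float = 0.1, mu_d2: float = 0.02,
                      mu_d3: float = 0.004) -> ModelSystem:
    """One-mode system whose quartic force field is the Taylor expansion of a Morse oscillator.

    For a Morse potential with harmonic wavenumber ``omega`` and
    anharmonicity ``omega_x`` (level formula
    ``E_v = omega (v+1/2) - omega_x (v+1/2)^2``) the quartic truncation in
    reduced coordinates is ``f_111 = -3 sqrt(2 omega omega_x)`` and
    ``f_1111 = 14 omega_x``.  Second-order perturbation theory on this
    truncation reproduces the exact Morse levels (chi = -omega_x).
    """
    if omega <= 0 or omega_x <= 0:
        raise InputError("omega and omega_x must be positive")
    if omega_x >= omega / 4:
        import warnings
        warnings.warn("omega_x >= omega/4: hardly any bound-state structure left")
    modes = NormalModes(np.array([omega]), ["morse"])
    ff = QuarticForceField(modes)
    ff.set_cubic((0, 0, 0), -3.0 * np.sqrt(2.0 * omega * omega_x))
    ff.set_quartic((0, 0, 0, 0), 14.0 * omega_x)
    mu = PropertySurface("mu", 1,
                         d1=np.array([[mu_d1, 0.0, 0.0]]),
                         d2=np.array([[[mu_d2, 0.0, 0.0]]]),
                         d3={(0, 0, 0): np.array([mu_d3, 0.0, 0.0])})
    return ModelSystem(ff, surfaces={"mu": mu}, metadata={
        "generator": "make_morse_system",
        "omega": omega, "omega_x": omega_x,
        "level_formula": "E_v = omega*(v+1/2) - omega_x*(v+1/2)**2",
        "fundamental": omega - 2.0 * omega_x,
        "first_overtone": 2.0 * omega - 6.0 * omega_x,
    })


def _sample_omegas(rng: np.random.Generator, spec: GeneratorSpec) -> np.ndarray:
    lo, hi = spec.omega_range
    for _ in range(5000):
        om = np.sort(rng.uniform(lo, hi, spec.n_modes))
        if spec.min_fermi_detuning <= 0:
            return om
        ok = True
        for i in range(spec.n_modes):
            for j in range(i, spec.n_modes):
                for k in range(spec.n_modes):
                    if abs(om[i] + om[j] - om[k]) < spec.min_fermi_detuning:
                        ok = False
        # keep fundamentals apart as well (1-1 near-degeneracies)
        if spec.n_modes > 1 and np.min(np.diff(om)) < spec.min_fermi_detuning:
            ok = False
        if ok:
            return om
    raise InputError("could not sample omegas satisfying min_fermi_detuning; "
                     "widen omega_range or relax the constraint")


def make_random_system(spec: GeneratorSpec) -> ModelSystem:
    """Reproducible random system realizing the requested resonance plan.

    The same seed yields a bit-identical system.  Planned detunings are
    realized exactly (the relevant omegas are set, not sampled).  Diagonal
    quartics are kept positive so the truncated potential is bounded along
    each single-mode direction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_modes
    omega = _sample_omegas(rng, spec)

    # realize resonance plans by pinning omegas
    for plan in spec.resonance_plan:
        if isinstance(plan, FermiPlan):
            for idx in (plan.i, plan.j, plan.k):
                if not 0 <= idx < n:
                    raise InputError("resonance plan index out of range")
            target = omega[plan.i] + omega[plan.j] - plan.detuning
            if target <= 0:
                raise InputError("infeasible Fermi plan: target frequency not positive")
            omega[plan.k] = target
        elif isinstance(plan, DDPlan):
            omega[plan.j] = omega[plan.i] + plan.detuning
            if omega[plan.j] <= 0:
                raise InputError("infeasible DD plan")
        else:
            raise InputError(f"unknown resonance plan entry {plan!r}")

    modes = NormalModes(omega)
    ff = QuarticForceField(modes)
    for key in itertools.combinations_with_replacement(range(n), 3):
        if spec.cubic_scale > 0:
            ff.set_cubic(key, rng.normal(0.0, spec.cubic_scale))
    for key in itertools.combinations_with_replacement(range(n), 4):
        if len(set(key)) == 4:
            continue  # semidiagonal storage only
        if spec.quartic_scale > 0:
            val = rng.normal(0.0, spec.quartic_scale)
            if len(set(key)) == 1:
                val = abs(val) + 0.5 * spec.quartic_scale  # bounded 1-D directions
            ff.set_quartic(key, val)

    # plant the requested couplings after random draws so they stick
    for plan in spec.resonance_plan:
        if isinstance(plan, FermiPlan):
            ff.set_cubic((plan.i, plan.j, plan.k), plan.f)
        elif isinstance(plan, DDPlan):
            lo, hi2 = sorted((plan.i, plan.j))
            ff.set_quartic((lo, lo, lo, hi2), 8.0 * plan.coupling)

    surfaces = {}
    for name in spec.tensors:
        if name in CHIRAL_TENSORS and not spec.chiral:
            continue
        shape = TENSOR_SHAPES[name]
        value0 = rng.normal(0.0, 1.0, shape)
        d1 = rng.normal(0.0, spec.d1_scale, (n,) + shape)
        d2 = rng.normal(0.0, spec.d2_scale, (n, n) + shape)
        d2 = 0.5 * (d2 + np.swapaxes(d2, 0, 1))
        d3 = {}
        if spec.d3_scale > 0:
            for key in itertools.combinations_with_replacement(range(n), 3):
                if len(set(key)) == 3:
                    continue
                d3[key] = rng.normal(0.0, spec.d3_scale, shape)
        if name == "alpha":
            value0 = 0.5 * (value0 + value0.T)
            d1 = 0.5 * (d1 + np.swapaxes(d1, -1, -2))
            d2 = 0.5 * (d2 + np.swapaxes(d2, -1, -2))
            d3 = {k: 0.5 * (v + v.T) for k, v in d3.items()}
        if name == "Aquad":
            value0 = 0.5 * (value0 + np.swapaxes(value0, 1, 2))
            d1 = 0.5 * (d1 + np.swapaxes(d1, -1, -2))
            d2 = 0.5 * (d2 + np.swapaxes(d2, -1, -2))
            d3 = {k: 0.5 * (v + np.swapaxes(v, 1, 2)) for k, v in d3.items()}
        surfaces[name] = PropertySurface(name, n, value0=value0, d1=d1, d2=d2, d3=d3)

    meta = {
        "generator": "make_random_system",
        "seed": spec.seed,
        "stream": _STREAM,
        "spec": {
            "n_modes": n, "omega_range": list(spec.omega_range),
            "cubic_scale": spec.cubic_scale, "quartic_scale": spec.quartic_scale,
            "d1_scale": spec.d1_scale, "d2_scale": spec.d2_scale, "d3_scale": spec.d3_scale,
        },
    }
    return ModelSystem(ff, surfaces=surfaces, metadata=meta)


def oracle_validation_spec(seed: int, n_modes: int = 2) -> GeneratorSpec:
    """Conditions for cross-checking VPT2 against the variational oracle.

    Frequencies are drawn from a high band (1600-2800 cm^-1) so no
    combination omega_i + omega_j can approach a fundamental (margin
    >= 400 cm^-1 by construction) - non-resonant by design.  Scales are
    gentle (cubic 25, quartic 1.5 cm^-1): the leading VPT2-vs-variational
    differences (second-order quartic energy contributions and
    combined-order-three moment terms, absent from VPT2 by construction)
    grow with the quartic scale, and the comparison is meaningful only in
    the regime where the perturbative treatment converges.
    """
    return GeneratorSpec(n_modes=n_modes, omega_range=(1600.0, 2800.0),
                         cubic_scale=15.0, quartic_scale=1.0,
                         min_fermi_detuning=150.0, seed=seed)


def fermi_dyad_spec(seed: int, detuning: float, f: Optional[float] = None,
                    overtone: bool = True) -> GeneratorSpec:
    """A two- or three-mode system with one planted Fermi dyad.

    The coupling defaults to the larger of 40 cm^-1 and 1.2x the
    third-criterion floor 0.02 detuning^2 (1+d), so planted dyads satisfy
    all three detection criteria across the 5-50 cm^-1 detuning range.
    """
    d = 1.0 if overtone else 0.0
    if f is None:
        f = max(40.0, 1.2 * 0.02 * detuning ** 2 * (1.0 + d))
    if overtone:
        plan = FermiPlan(0, 0, 1, detuning=detuning, f=f)
        n = 2
    else:
        plan = FermiPlan(0, 1, 2, detuning=detuning, f=f)
        n = 3
    return GeneratorSpec(n_modes=n, omega_range=(800.0, 1600.0), cubic_scale=15.0,
                         quartic_scale=3.0, resonance_plan=[plan], seed=seed)


def mirror_image(system: ModelSystem) -> ModelSystem:
    """Enantiomer of a system: pseudo-tensor surfaces (m, G', A) negated at every order.

    The force field, mu and alpha are untouched, so IR and Raman spectra of
    the pair coincide while VCD and ROA are exact negatives.
    """
    surfaces = {name: s.mirror() for name, s in system.surfaces.items()}
    meta = dict(system.metadata)
    meta["mirrored"] = not meta.get("mirrored", False)
    return ModelSystem(system.force_field, surfaces=surfaces,
                       coriolis=system.coriolis, metadata=meta)
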