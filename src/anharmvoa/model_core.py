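"""Core domain types for anharmonic vibrational problems.

All internal math is carried out in reduced (dimensionless) normal
coordinates ``q_i`` with the harmonic potential written as
``(omega_i/2) q_i**2`` and every energy-like quantity in cm^-1.  Property
(electric/magnetic tensor) values and their derivatives with respect to
``q`` are in atomic units.  The single point where mass-weighted
coordinates appear is :func:`reduced_step_from_massweighted`, which
converts a finite-difference displacement given in amu^1/2 Angstrom into
the dimensionless step used internally.

Matrix-element convention: with the reduced coordinates used here,
``<0|q|1> = 1/sqrt(2)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import scipy.constants as _const

logger = logging.getLogger("anharmvoa")

#: Cartesian component shape of each supported property tensor.
TENSOR_SHAPES: Dict[str, Tuple[int, ...]] = {
    "mu": (3,),        # electric dipole
    "m": (3,),         # magnetic dipole (expanded in momenta p_i)
    "alpha": (3, 3),   # electric dipole-dipole polarizability
    "Gprime": (3, 3),  # electric dipole-magnetic dipole polarizability
    "Aquad": (3, 3, 3),  # electric dipole-quadrupole polarizability A_{a,bg}
}

#: Pseudo-tensors that change sign under spatial inversion (mirror image).
CHIRAL_TENSORS = ("m", "Gprime", "Aquad")

SCHEMA_VERSION = 1


class InputError(ValueError):
    """Invalid user input (bad index, malformed file, infeasible request)."""


def canonical_index(indices: Tuple[int, ...], n_modes: Optional[int] = None) -> Tuple[int, ...]:
    """Return the canonical (sorted) form of a force-constant index tuple.

    Force constants and semidiagonal property derivatives are invariant
    under any permutation of their mode indices; they are stored under the
    sorted tuple and retrieved through any permutation.
    """
    idx = tuple(int(i) for i in indices)
    if n_modes is not None:
        for i in idx:
            if not 0 <= i < n_modes:
                raise InputError(f"mode index {i} out of range 0..{n_modes - 1}")
    return tuple(sorted(idx))


def reduced_step_from_massweighted(step_Q: float, omega: float) -> float:
    """Convert a mass-weighted displacement (amu^1/2 Angstrom) to reduced coordinates.

    ``q = Q * sqrt(4 pi^2 c omega / h)`` with omega in cm^-1; the result is
    dimensionless and grows with sqrt(omega).
    """
    if step_Q <= 0:
        raise InputError("step_Q must be positive")
    if omega <= 0:
        raise InputError("omega must be positive")
    q_per_Q = np.sqrt(4.0 * np.pi**2 * _const.c * (omega * 100.0) / _const.h)
    return float(step_Q * np.sqrt(_const.atomic_mass) * 1e-10 * q_per_Q)


@dataclass
class NormalModes:
    """Harmonic normal modes: count, wavenumbers and free-text labels."""

    omega: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if self.omega.ndim != 1 or self.omega.size < 1:
            raise InputError("omega must be a 1-D array with at least one mode")
        if np.any(self.omega <= 0):
            raise InputError("harmonic wavenumbers must be strictly positive")
        if self.labels is None:
            self.labels = [f"mode{i + 1}" for i in range(self.omega.size)]
        if len(self.labels) != self.omega.size:
            raise InputError("labels length must match number of modes")

    @property
    def n_modes(self) -> int:
        return int(self.omega.size)


class QuarticForceField:
    """Quartic force field in reduced normal coordinates (cm^-1).

    Cubic constants ``f_ijk`` are stored for all index triples; quartic
    constants only for semidiagonal patterns (at least two equal indices),
    the set obtainable from single-mode displacement differencing.  Fully
    off-diagonal quartics read as zero (an attempt to store one is ignored
    with a warning).  Storage is canonical (sorted indices); access through
    any permutation returns the same value, and absent entries read as 0.
    """

    def __init__(self, modes: NormalModes,
                 cubic: Optional[Mapping[Tuple[int, int, int], float]] = None,
                 quartic: Optional[Mapping[Tuple[int, int, int, int], float]] = None):
        self.modes = modes
        self._cubic: Dict[Tuple[int, int, int], float] = {}
        self._quartic: Dict[Tuple[int, int, int, int], float] = {}
        for k, v in (cubic or {}).items():
            self.set_cubic(k, v)
        for k, v in (quartic or {}).items():
            self.set_quartic(k, v)

    @property
    def n_modes(self) -> int:
        return self.modes.n_modes

    @property
    def omega(self) -> np.ndarray:
        return self.modes.omega

    def set_cubic(self, indices, value: float) -> None:
        key = canonical_index(indices, self.n_modes)
        if len(key) != 3:
            raise InputError("cubic constant needs exactly three indices")
        if value == 0.0:
            self._cubic.pop(key, None)
        else:
            self._cubic[key] = float(value)

    def set_quartic(self, indices, value: float) -> None:
        key = canonical_index(indices, self.n_modes)
        if len(key) != 4:
            raise InputError("quartic constant needs exactly four indices")
        if len(set(key)) == 4:
            logger.warning(
                "fully off-diagonal quartic f_%s not representable "
                "(semidiagonal storage); ignored", key)
            return
        if value == 0.0:
            self._quartic.pop(key, None)
        else:
            self._quartic[key] = float(value)

    def f3(self, i: int, j: int, k: int) -> float:
        return self._cubic.get(canonical_index((i, j, k), self.n_modes), 0.0)

    def f4(self, i: int, j: int, k: int, l: int) -> float:
        key = canonical_index((i, j, k, l), self.n_modes)
        return self._quartic.get(key, 0.0)

    def cubic_items(self):
        """Canonical (i<=j<=k) -> f_ijk pairs actually stored."""
        return self._cubic.items()

    def quartic_items(self):
        return self._quartic.items()

    def is_harmonic(self) -> bool:
        return not self._cubic and not self._quartic


@dataclass
class CoriolisData:
    """Coriolis coupling constants zeta^a_ij and rotational constants (cm^-1).

    zeta is antisymmetric in the mode pair; it contributes to the
    vibrational second-order energy correction only (not to intensities).
    """

    zeta: np.ndarray                 # (3, n, n), dimensionless
    rotational_constants: np.ndarray  # (3,), cm^-1
    present: bool = True

    def __post_init__(self):
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.rotational_constants = np.asarray(self.rotational_constants, dtype=float)
        if self.zeta.ndim != 3 or self.zeta.shape[0] != 3 or self.zeta.shape[1] != self.zeta.shape[2]:
            raise InputError("zeta must have shape (3, n_modes, n_modes)")
        if not np.allclose(self.zeta, -np.swapaxes(self.zeta, 1, 2)):
            raise InputError("zeta must be antisymmetric in its mode indices")
        if self.rotational_constants.shape != (3,):
            raise InputError("rotational_constants must have three components")


class PropertySurface:
    """One electric/magnetic tensor and its Taylor expansion in reduced coordinates.

    value0 holds the equilibrium components, d1/d2 the first/second
    derivatives and d3 the semidiagonal third derivatives (at least two
    equal mode indices, canonical sorted storage).  The magnetic dipole is
    expanded in the conjugate momenta p_i rather than in q_i
    (``conjugate=True``); its leading derivative is the atomic axial
    tensor, as the polar tensor is for the electric dipole.
    """

    def __init__(self, name: str, n_modes: int,
                 value0=None, d1=None, d2=None,
                 d3: Optional[Mapping[Tuple[int, int, int], np.ndarray]] = None,
                 conjugate: Optional[bool] = None):
        if name not in TENSOR_SHAPES:
            raise InputError(f"unknown tensor name {name!r}; expected one of {sorted(TENSOR_SHAPES)}")
        self.name = name
        self.n_modes = int(n_modes)
        shape = TENSOR_SHAPES[name]
        self.comp_shape = shape
        self.value0 = np.zeros(shape) if value0 is None else np.asarray(value0, dtype=float).reshape(shape)
        self.d1 = (np.zeros((n_modes,) + shape) if d1 is None
                   else np.asarray(d1, dtype=float).reshape((n_modes,) + shape))
        self.d2 = (np.zeros((n_modes, n_modes) + shape) if d2 is None
                   else np.asarray(d2, dtype=float).reshape((n_modes, n_modes) + shape))
        if not np.allclose(self.d2, np.swapaxes(self.d2, 0, 1)):
            raise InputError("d2 must be symmetric in its two mode indices")
        self._d3: Dict[Tuple[int, int, int], np.ndarray] = {}
        for key, val in (d3 or {}).items():
            self.set_d3(key, val)
        self.conjugate = (name == "m") if conjugate is None else bool(conjugate)
        if name == "Aquad" and not np.allclose(self.value0, np.swapaxes(self.value0, 1, 2)):
            raise InputError("A_{a,bg} components must be symmetric under bg swap")

    def set_d3(self, indices, value) -> None:
        key = canonical_index(indices, self.n_modes)
        if len(key) != 3:
            raise InputError("third derivative needs three mode indices")
        if len(set(key)) == 3:
            raise InputError("only semidiagonal third derivatives (>=2 equal indices) are stored")
        self._d3[key] = np.asarray(value, dtype=float).reshape(self.comp_shape)

    def d3(self, i: int, j: int, k: int) -> np.ndarray:
        key = canonical_index((i, j, k), self.n_modes)
        if len(set(key)) == 3:
            return np.zeros(self.comp_shape)
        return self._d3.get(key, np.zeros(self.comp_shape))

    def d3_items(self):
        return self._d3.items()

    def mirror(self) -> "PropertySurface":
        """Spatial-inversion image: pseudo-tensors flip sign at every order."""
        sign = -1.0 if self.name in CHIRAL_TENSORS else 1.0
        return PropertySurface(
            self.name, self.n_modes,
            value0=sign * self.value0, d1=sign * self.d1, d2=sign * self.d2,
            d3={k: sign * v for k, v in self._d3.items()},
            conjugate=self.conjugate)


@dataclass
class ModelSystem:
    """A self-contained vibrational problem: force field, property surfaces, metadata."""

    force_field: QuarticForceField
    surfaces: Dict[str, PropertySurface] = field(default_factory=dict)
    coriolis: Optional[CoriolisData] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.force_field.n_modes
        for name, s in self.surfaces.items():
            if s.n_modes != n:
                raise InputError(f"surface {name!r} has {s.n_modes} modes, force field has {n}")
        if self.coriolis is not None and self.coriolis.zeta.shape[1] != n:
            raise InputError("Coriolis data mode count mismatch")

    @property
    def n_modes(self) -> int:
        return self.force_field.n_modes

    # ---- serialization (JSON document, 1-based indices in the file) ----

    def to_dict(self) -> dict:
        ff = self.force_field
        doc = {
            "schema_version": SCHEMA_VERSION,
            "modes": {"omega": ff.omega.tolist(), "labels": list(ff.modes.labels)},
            "cubic": {" ".join(str(i + 1) for i in k): v for k, v in ff.cubic_items()},
            "quartic": {" ".join(str(i + 1) for i in k): v for k, v in ff.quartic_items()},
            "surfaces": {},
            "metadata": self.metadata,
        }
        for name, s in self.surfaces.items():
            doc["surfaces"][name] = {
                "value0": s.value0.tolist(),
                "d1": s.d1.tolist(),
                "d2": s.d2.tolist(),
                "d3": {" ".join(str(i + 1) for i in k): v.tolist() for k, v in s.d3_items()},
                "conjugate": s.conjugate,
            }
        if self.coriolis is not None:
            doc["coriolis"] = {
                "zeta": self.coriolis.zeta.tolist(),
                "rotational_constants": self.coriolis.rotational_constants.tolist(),
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelSystem":
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise InputError(f"unsupported schema_version {doc.get('schema_version')!r}")
        modes = NormalModes(np.asarray(doc["modes"]["omega"]), doc["modes"].get("labels"))

        def parse_key(s):
            return tuple(int(t) - 1 for t in s.split())

        ff = QuarticForceField(
            modes,
            cubic={parse_key(k): v for k, v in doc.get("cubic", {}).items()},
            quartic={parse_key(k): v for k, v in doc.get("quartic", {}).items()},
        )
        surfaces = {}
        for name, sd in doc.get("surfaces", {}).items():
            surfaces[name] = PropertySurface(
                name, modes.n_modes,
                value0=np.asarray(sd["value0"]), d1=np.asarray(sd["d1"]),
                d2=np.asarray(sd["d2"]),
                d3={parse_key(k): np.asarray(v) for k, v in sd.get("d3", {}).items()},
                conjugate=sd.get("conjugate"),
            )
        coriolis = None
        if "coriolis" in doc:
            coriolis = CoriolisData(np.asarray(doc["coriolis"]["zeta"]),
                                    np.asarray(doc["coriolis"]["rotational_constants"]))
        return cls(ff, surfaces=surfaces, coriolis=coriolis, metadata=doc.get("metadata", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---- vibrational states -------------------------------------------------

VibState = Tuple[int, ...]  # quanta per mode


def ground(n_modes: int) -> VibState:
    return (0,) * n_modes


def fundamental(n_modes: int, i: int) -> VibState:
    s = [0] * n_modes
    s[i] = 1
    return tuple(s)


def overtone(n_modes: int, i: int) -> VibState:
    s = [0] * n_modes
    s[i] = 2
    return tuple(s)


def combination(n_modes: int, i: int, j: int) -> VibState:
    if i == j:
        raise InputError("combination needs two distinct modes")
    s = [0] * n_modes
    s[i] = s[j] = 1
    return tuple(s)


def enumerate_final_states(n_modes: int, max_total: int = 2) -> Iterable[VibState]:
    """Fundamentals, overtones and binary combinations (total quanta 1..2)."""
    for i in range(n_modes):
        yield fundamental(n_modes, i)
    if max_total >= 2:
        for i in range(n_modes):
            yield overtone(n_modes, i)
        for i in range(n_modes):
            for j in range(i + 1, n_modes):
                yield combination(n_modes, i, j)


def state_label(state: VibState) -> str:
    """F_i / O_i / C_ij label (1-based) of a zeroth-order configuration."""
    nz = [(i, v) for i, v in enumerate(state) if v]
    tot = sum(v for _, v in nz)
    if tot == 0:
        return "GS"
    if tot == 1:
        return f"F{nz[0][0] + 1}"
    if len(nz) == 1:
        return f"O{nz[0][0] + 1}"
    return "C" + ",".join(str(i + 1) for i, _ in nz)
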