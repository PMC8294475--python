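"""LJ parameters, combining rules, pair energies, and the physical/mathematical
parameter transform.

Internal units are fixed: epsilon in kcal/mol, distances in Angstrom.
Interfaces that report heats of vaporization use kJ/mol; the conversion
constant lives here and is applied only at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import TypingModel

KCAL_TO_KJ = 4.184
#: Gas constant, kJ/(mol K)
R_KJ = 8.31446261815324e-3
#: Coulomb constant for q in e, r in Angstrom, energy in kcal/mol
COULOMB_KCAL = 332.0637133
AVOGADRO = 6.02214076e23

#: Prior widths t_i converting physical displacements to dimensionless
#: mathematical coordinates.
EPSILON_PRIOR_WIDTH = 0.1  # kcal/mol
RMIN_HALF_PRIOR_WIDTH = 1.0  # Angstrom


@dataclass(frozen=True)
class LJType:
    """One LJ type: well depth (kcal/mol) and half-minimum separation (A)."""

    type_id: str
    epsilon: float
    rmin_half: float

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError(f"{self.type_id}: epsilon must be >= 0")
        if self.rmin_half <= 0:
            raise ValueError(f"{self.type_id}: rmin_half must be > 0")


def combine(a: LJType, b: LJType) -> tuple[float, float]:
    """Lorentz-Berthelot combination: geometric-mean epsilon, additive r_1/2."""
    return math.sqrt(a.epsilon * b.epsilon), a.rmin_half + b.rmin_half


def pair_energy(r, epsilon, r_min):
    """12-6 LJ energy eps * [(rmin/r)^12 - 2 (rmin/r)^6]; r > 0 (kcal/mol).

    Accepts scalars or numpy arrays for ``r``.
    """
    if np.any(np.asarray(r) <= 0):
        raise ValueError("r must be > 0")
    x6 = (r_min / np.asarray(r, dtype=float)) ** 6
    return epsilon * (x6 * x6 - 2.0 * x6)


@dataclass
class LJParameterSet:
    """LJ parameters for every type of a typing model, plus the reference
    values and prior widths used by the mathematical transform."""

    model_name: str
    types: dict[str, LJType]
    reference: dict[str, tuple[float, float]] = field(default_factory=dict)
    prior_widths: tuple[float, float] = (EPSILON_PRIOR_WIDTH, RMIN_HALF_PRIOR_WIDTH)

    def __post_init__(self):
        if not self.reference:
            self.reference = {
                tid: (t.epsilon, t.rmin_half) for tid, t in self.types.items()
            }
        if any(w <= 0 for w in self.prior_widths):
            raise ValueError("prior widths must be positive")

    @classmethod
    def from_model(cls, model: TypingModel) -> "LJParameterSet":
        """Starting parameter set carried by the model's rule list."""
        init = model.initial_parameters()
        types = {tid: LJType(tid, eps, rmin) for tid, (eps, rmin) in init.items()}
        return cls(model_name=model.name, types=types)

    @property
    def type_order(self) -> tuple[str, ...]:
        return tuple(self.types)

    @property
    def n_params(self) -> int:
        return 2 * len(self.types)

    def get(self, type_id: str) -> LJType:
        return self.types[type_id]

    def with_values(self, values: dict[str, tuple[float, float]]) -> "LJParameterSet":
        """Copy with new (epsilon, rmin_half) values, keeping the reference."""
        types = {tid: LJType(tid, eps, rmin) for tid, (eps, rmin) in values.items()}
        if set(types) != set(self.types):
            raise ValueError("type ids do not match")
        return LJParameterSet(
            model_name=self.model_name,
            types=types,
            reference=dict(self.reference),
            prior_widths=self.prior_widths,
        )

    def as_reference(self) -> "LJParameterSet":
        """Copy whose reference point is its own current values (k = 0)."""
        return LJParameterSet(
            model_name=self.model_name,
            types=dict(self.types),
            reference={tid: (t.epsilon, t.rmin_half) for tid, t in self.types.items()},
            prior_widths=self.prior_widths,
        )


def to_math(params: LJParameterSet) -> np.ndarray:
    """Transform to dimensionless coordinates k_i = (K_i - K_i0) / t_i.

    Ordering contract: types in model-definition order, (epsilon, rmin_half)
    interleaved per type. Length = 2 x number of types.
    """
    t_eps, t_r = params.prior_widths
    k = np.empty(params.n_params)
    for i, tid in enumerate(params.type_order):
        lj = params.types[tid]
        eps0, r0 = params.reference[tid]
        k[2 * i] = (lj.epsilon - eps0) / t_eps
        k[2 * i + 1] = (lj.rmin_half - r0) / t_r
    return k


def from_math(k: np.ndarray, ref: LJParameterSet, clamp: bool = False) -> LJParameterSet:
    """Inverse of :func:`to_math` relative to ``ref``'s reference point.

    With ``clamp=True``, epsilon is floored at 0 and rmin_half at a small
    positive value so trial steps from an optimizer always yield a valid set.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (ref.n_params,):
        raise ValueError(f"expected k of length {ref.n_params}, got {k.shape}")
    t_eps, t_r = ref.prior_widths
    values = {}
    for i, tid in enumerate(ref.type_order):
        eps0, r0 = ref.reference[tid]
        eps = eps0 + t_eps * k[2 * i]
        rmin = r0 + t_r * k[2 * i + 1]
        if clamp:
            eps = max(eps, 0.0)
            rmin = max(rmin, 1e-3)
        values[tid] = (eps, rmin)
    return ref.with_values(values)


# --------------------------------------------------------------------------
# Flat CSV I/O (type_id, epsilon_kcal_mol, rmin_half_A)
# --------------------------------------------------------------------------

def params_to_csv(params: LJParameterSet, path) -> None:
    rows = [
        {"type_id": tid, "epsilon_kcal_mol": t.epsilon, "rmin_half_A": t.rmin_half}
        for tid, t in params.types.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def params_from_csv(path, model_name: str = "unnamed") -> LJParameterSet:
    df = pd.read_csv(path)
    types = {
        str(row.type_id): LJType(str(row.type_id), row.epsilon_kcal_mol, row.rmin_half_A)
        for row in df.itertuples()
    }
    return LJParameterSet(model_name=model_name, types=types)
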