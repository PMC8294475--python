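"""Regularized property-matching objective.

Total objective L(k) = sum_m L_m(k) + w_reg |k|^2 with
L_m(k) = sum_p |y_p - y_p,ref|^2 / d_p^2. Default denominators:
95 kg/m^3 for density, 0.95 kJ/mol for heat of vaporization. Training uses
density and HOV; the dielectric constant is evaluation-only by default and
enters with a deliberately large denominator so it contributes very little.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LJParameterSet, to_math

DEFAULT_W_REG = 0.1
DEFAULT_DENOMINATORS = {
    "density": 95.0,  # kg/m^3
    "hov": 0.95,  # kJ/mol
    "dielectric": 10.0,  # evaluation-only, down-weighted
}
#: Properties used for training.
TRAINING_PROPERTIES = ("density", "hov")


@dataclass(frozen=True)
class PropertyRecord:
    """Predicted or reference (density, HOV, dielectric) for one compound.

    Units: density kg/m^3, HOV kJ/mol, dielectric dimensionless. Missing
    properties are ``None``.
    """

    compound_id: str
    density: float | None = None
    hov: float | None = None
    dielectric: float | None = None

    def get(self, prop: str) -> float | None:
        return getattr(self, prop)

    def properties(self) -> dict[str, float]:
        return {
            p: v
            for p in ("density", "hov", "dielectric")
            if (v := getattr(self, p)) is not None
        }


@dataclass(frozen=True)
class PropertyReference(PropertyRecord):
    """Reference values plus per-property denominators d_p."""

    denominators: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENOMINATORS))

    def __post_init__(self):
        if not self.properties():
            raise ValueError(f"{self.compound_id}: no reference properties")
        if any(d <= 0 for d in self.denominators.values()):
            raise ValueError("denominators must be positive")


@dataclass
class ObjectiveBreakdown:
    """Per-compound terms, restraint, and total of the regularized objective."""

    terms: dict[str, float]
    restraint: float
    w_reg: float

    @property
    def data_term(self) -> float:
        return sum(self.terms.values())

    @property
    def total(self) -> float:
        return self.data_term + self.restraint

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": self.terms,
                "restraint": self.restraint,
                "w_reg": self.w_reg,
                "total": self.total,
            },
            indent=2,
        )


def molecule_term(
    predicted: PropertyRecord,
    reference: PropertyReference,
    properties: tuple[str, ...] = TRAINING_PROPERTIES,
) -> float:
    """One compound's objective term: squared errors over squared denominators,
    summed over the properties present in both records."""
    total = 0.0
    shared = set(predicted.properties()) & set(reference.properties()) & set(properties)
    for prop in shared:
        if prop not in reference.denominators:
            raise ValueError(f"no denominator configured for property {prop!r}")
        d = reference.denominators[prop]
        total += (predicted.get(prop) - reference.get(prop)) ** 2 / d**2
    return total


def total_objective(
    terms: dict[str, float], k: np.ndarray, w_reg: float = DEFAULT_W_REG
) -> ObjectiveBreakdown:
    """Assemble the breakdown: sum of compound terms + w_reg |k|^2."""
    if w_reg < 0:
        raise ValueError("w_reg must be >= 0")
    k = np.asarray(k, dtype=float)
    return ObjectiveBreakdown(
        terms=dict(terms), restraint=float(w_reg * k @ k), w_reg=w_reg
    )


def restraint_contribution(
    candidate: LJParameterSet,
    reference: LJParameterSet,
    w_reg: float = DEFAULT_W_REG,
) -> float:
    """Restraint w_reg |k|^2 of ``candidate`` displaced from ``reference``,
    summed over unique adjustable parameters (one term per type x {eps, r})."""
    if candidate.model_name != reference.model_name or set(candidate.types) != set(
        reference.types
    ):
        raise ValueError(
            f"parameter sets belong to different models "
            f"({candidate.model_name} vs {reference.model_name})"
        )
    shifted = candidate.with_values(
        {tid: (t.epsilon, t.rmin_half) for tid, t in candidate.types.items()}
    )
    shifted.reference = {
        tid: (t.epsilon, t.rmin_half) for tid, t in reference.types.items()
    }
    k = to_math(shifted)
    return float(w_reg * k @ k)


def percent_errors(
    predictions: list[PropertyRecord], references: list[PropertyRecord]
) -> dict[str, float]:
    """Mean absolute percent error per property, paired by compound id.

    Compounds with a zero reference value are excluded with a warning.
    """
    ref_by_id = {r.compound_id: r for r in references}
    errors: dict[str, list[float]] = {}
    for pred in predictions:
        ref = ref_by_id.get(pred.compound_id)
        if ref is None:
            continue
        for prop in set(pred.properties()) & set(ref.properties()):
            y_ref = ref.get(prop)
            if y_ref == 0:
                warnings.warn(
                    f"{pred.compound_id}: zero reference {prop}, excluded",
                    stacklevel=2,
                )
                continue
            errors.setdefault(prop, []).append(
                100.0 * abs(pred.get(prop) - y_ref) / abs(y_ref)
            )
    if not errors:
        raise ValueError("no overlapping properties to score")
    return {prop: float(np.mean(vals)) for prop, vals in errors.items()}


# --------------------------------------------------------------------------
# Reference-table I/O
# --------------------------------------------------------------------------

def references_to_csv(refs: list[PropertyReference], path) -> None:
    rows = []
    for r in refs:
        rows.append(
            {
                "compound_id": r.compound_id,
                "density_kg_m3": r.density,
                "hov_kJ_mol": r.hov,
                "dielectric": r.dielectric,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def references_from_csv(path, denominators: dict[str, float] | None = None) -> list[PropertyReference]:
    df = pd.read_csv(path)
    denom = dict(DEFAULT_DENOMINATORS)
    if denominators:
        denom.update(denominators)
    out = []
    for row in df.itertuples():
        out.append(
            PropertyReference(
                compound_id=str(row.compound_id),
                density=None if pd.isna(row.density_kg_m3) else float(row.density_kg_m3),
                hov=None if pd.isna(row.hov_kJ_mol) else float(row.hov_kJ_mol),
                dielectric=None if pd.isna(row.dielectric) else float(row.dielectric),
                denominators=denom,
            )
        )
    return out
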