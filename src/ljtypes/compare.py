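"""Parameter-space geometry of typing models.

Each model becomes a point in 24-dimensional space: 12 display-row r_1/2
values followed by 12 epsilon values scaled by the ratio of the mean r_1/2 to
the mean epsilon (computed over every row of every model, duplicates
included). Pairwise Euclidean distances between these points quantify how
far apart two optimized models landed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .chem import MoleculeGraph, TypingModel, assign_types, parse_compound
from .core import LJParameterSet

#: The 12 display rows of the common parameter table: 4 H, 3 C, 2 N, 3 O.
#: Each row carries a probe molecule + atom chemistry so any typing model can
#: be expanded onto the shared row list.
DISPLAY_ROWS: tuple[tuple[str, str, str], ...] = (
    # (smirks, probe smiles, probe element/selection key)
    ("[#1:1]-[#6X4]", "CC", "H"),
    ("[#1:1]-[#6X3]", "C=C", "H"),
    ("[#1:1]-[#7]", "CN", "H_on_N"),
    ("[#1:1]-[#8]", "CO", "H_on_O"),
    ("[#6:1]", "C=C", "C"),
    ("[#6X4:1]", "CC", "C"),
    ("[#6X2:1]", "CC#N", "C_sp"),
    ("[#7X3:1]", "CN", "N"),
    ("[#7:1]", "CC#N", "N"),
    ("[#8:1]", "CC(C)=O", "O"),
    ("[#8X2H1+0:1]", "CO", "O"),
    ("[#8X2H0+0:1]", "COC", "O"),
)


def _probe_atom_index(mol: MoleculeGraph, key: str) -> int:
    elems = mol.elements
    if key in ("H", "C", "N", "O"):
        if key == "H":
            return elems.index("H")
        if key == "C" and mol.smiles == "C=C":
            return 0
        if key == "C" and mol.smiles == "CC":
            return 0
        return elems.index(key)
    if key == "C_sp":
        # nitrile carbon: the C bonded to N
        for i, j in mol.bonds:
            pair = {elems[i], elems[j]}
            if pair == {"C", "N"}:
                return i if elems[i] == "C" else j
        raise ValueError("no nitrile carbon in probe")
    if key in ("H_on_N", "H_on_O"):
        target = key[-1]
        for i, j in mol.bonds:
            if {elems[i], elems[j]} == {"H", target}:
                return i if elems[i] == "H" else j
        raise ValueError(f"no {key} in probe")
    raise ValueError(f"unknown probe key {key}")


def common_row_expansion(
    model: TypingModel, params: LJParameterSet
) -> np.ndarray:
    """Expand a parameter set onto the 12 display rows -> array (12, 2) of
    (epsilon, rmin_half). Rows sharing a type carry duplicated values."""
    out = np.empty((len(DISPLAY_ROWS), 2))
    for row, (_smirks, probe_smiles, key) in enumerate(DISPLAY_ROWS):
        probe = parse_compound(probe_smiles)
        idx = _probe_atom_index(probe, key)
        tid = assign_types(probe, model)[idx]
        lj = params.get(tid)
        out[row] = (lj.epsilon, lj.rmin_half)
    return out


def epsilon_scale_factor(expansions: dict[str, np.ndarray]) -> float:
    """Mean of all r_1/2 entries over mean of all epsilon entries, across
    every display row of every supplied model (duplicates included)."""
    if not expansions:
        raise ValueError("need at least one model")
    eps = np.concatenate([e[:, 0] for e in expansions.values()])
    r = np.concatenate([e[:, 1] for e in expansions.values()])
    mean_eps = eps.mean()
    if mean_eps == 0:
        raise ValueError("mean epsilon is zero")
    return float(r.mean() / mean_eps)


@dataclass
class DistanceReport:
    models: list[str]
    scale: float
    matrix: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        return float(self.matrix[self.models.index(a), self.models.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.models, columns=self.models)


def distance_matrix(
    expansions: dict[str, np.ndarray], scale: float | None = None
) -> DistanceReport:
    """Pairwise Euclidean distances between 24-vectors (r rows then scaled
    epsilon rows). ``scale`` defaults to the recomputed ratio of means."""
    shapes = {e.shape for e in expansions.values()}
    if shapes != {(len(DISPLAY_ROWS), 2)}:
        raise ValueError("inconsistent common-row expansions")
    if scale is None:
        scale = epsilon_scale_factor(expansions)
    names = list(expansions)
    vectors = {
        name: np.concatenate([exp[:, 1], exp[:, 0] * scale])
        for name, exp in expansions.items()
    }
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(vectors[names[i]] - vectors[names[j]]))
            mat[i, j] = mat[j, i] = d
    return DistanceReport(models=names, scale=float(scale), matrix=mat)


def nearest_neighbor(report: DistanceReport, model: str) -> list[str]:
    """Closest other model(s); all are returned on an exact tie."""
    if len(report.models) < 2:
        raise ValueError("need at least two models")
    i = report.models.index(model)
    row = report.matrix[i].copy()
    row[i] = np.inf
    best = row.min()
    return [m for j, m in enumerate(report.models) if row[j] == best]


# --------------------------------------------------------------------------
# Packaged fixture: the published optimized parameter table (five models,
# 12 display rows each).
# --------------------------------------------------------------------------

def load_reference_table() -> dict[str, np.ndarray]:
    """The packaged five-model optimized parameter table as common-row
    expansions keyed by model name."""
    with resources.files("ljtypes.data").joinpath("optimized_params.csv").open() as fh:
        df = pd.read_csv(fh)
    smirks_order = [s for s, _, _ in DISPLAY_ROWS]
    out: dict[str, np.ndarray] = {}
    for model in df["model"].unique():
        sub = df[df["model"] == model].set_index("smirks")
        arr = np.array(
            [[sub.loc[s, "epsilon_kcal_mol"], sub.loc[s, "rmin_half_A"]] for s in smirks_order]
        )
        out[model] = arr
    return out
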