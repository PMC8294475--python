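"""Synthetic compound libraries, ground-truth typed parameters, and noisy
property tables so the whole pipeline is testable offline.

The property oracle is an invented, smooth, type-separable stand-in for MD:

    density     = c_rho * M / sum_a r_a^3
                  + c_q * n_acceptors * sum_{polar H a} 1/r_a^2
    HOV         = c_h * sum_a sqrt(eps_a) r_a^3
                  + c_p * n_acceptors * sum_{polar H a} sqrt(eps_a)/r_a + R*T
    dielectric  = 1 + c_d * (n_polarH + n_O + n_N)^2 / sum_a r_a^3

where (eps_a, r_a) are the per-atom assigned LJ parameters and "polar H"
means an H bonded to N or O. The hydrogen-bond terms scale as sqrt(eps)/r
(energy) and 1/r^2 (contact densification) of each polar hydrogen: two
independent exponent combinations, so both polar-H parameters carry strong
signal (a pure pair-count term would leave them nearly unidentifiable at the
stated noise). Ground truth uses a typed parameter set
whose H and O types are well separated while C and N types are not, so
splitting H or O is identifiable from data but splitting C or N is
property-neutral by construction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .chem import MoleculeGraph, TypingModel, assign_types, build_model, parse_compound
from .core import LJParameterSet, LJType, R_KJ
from .objective import DEFAULT_DENOMINATORS, PropertyRecord, PropertyReference

#: Default noise scales: 0.001 g/cc = 1 kg/m^3 density, 0.3 kJ/mol HOV,
#: 10% relative on the dielectric constant.
DEFAULT_NOISE = {"density": 1.0, "hov": 0.3, "dielectric_rel": 0.10}

#: Oracle constants tuned so outputs land in realistic liquid ranges
#: (roughly 600-1100 kg/m^3, 20-60 kJ/mol, 1-40).
DEFAULT_ORACLE_CONSTANTS = {
    "c_rho": 600.0,
    "c_h": 3.0,
    "c_p": 85.0,
    "c_q": 30.0,
    "c_d": 50.0,
}

FUNCTIONAL_CLASSES = (
    "alkane",
    "alkene",
    "ether",
    "alcohol",
    "carbonyl",
    "ester",
    "amine",
    "nitrile",
)

# deterministic SMILES templates per class, ordered by size
_TEMPLATES: dict[str, tuple[str, ...]] = {
    "alkane": (
        "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC", "CCCCCC",
        "CC(C)(C)C", "CCC(C)CC", "CCCCCCC", "CC(C)CCC", "CCCCCCCC",
    ),
    "alkene": (
        "C=C", "CC=C", "CC=CC", "CCC=C", "CC(C)=C", "CCC=CC", "C=CC=C",
        "CCCC=C", "CC=C(C)C", "CCC(C)=C", "CCCC=CC", "CC=CCC=C",
    ),
    "ether": (
        "COC", "CCOC", "CCOCC", "COCC", "CCCOC", "COC(C)C", "CCOCCC",
        "COCCOC", "CCCOCC", "CCOC(C)C", "CCCCOC", "COCCCOC",
    ),
    "alcohol": (
        "CO", "CCO", "CCCO", "CC(C)O", "CCCCO", "CC(C)(C)O",
        "CCC(C)O", "CC(C)CO", "CCCCCO", "OCC(C)C", "CCCCCCO", "CCC(C)CO",
    ),
    "carbonyl": (
        "CC=O", "CC(C)=O", "CCC=O", "CCC(C)=O", "CC(=O)CC", "CCCC=O",
        "CCC(=O)CC", "CCCC(C)=O", "CC(C)C=O", "CCCCC=O", "CC(C)C(C)=O", "CCCCC(C)=O",
    ),
    "ester": (
        "COC(C)=O", "CCOC(C)=O", "COC(=O)CC", "CCOC(=O)C", "CCCOC(C)=O",
        "COC(=O)CCC", "CCOC(=O)CC", "CC(C)OC(C)=O", "CCCCOC(C)=O",
        "COC(=O)C(C)C", "CCOC(=O)CCC", "CCCOC(=O)CC",
    ),
    "amine": (
        "CN", "CCN", "CNC", "CCCN", "CCNC", "CN(C)C", "CCCCN", "CC(C)N",
        "CCN(C)C", "CCNCC", "CCCCCN", "CC(C)CN",
    ),
    "nitrile": (
        "CC#N", "CCC#N", "CCCC#N", "CC(C)C#N", "CCCCC#N", "CC(C)CC#N",
        "CCC(C)C#N", "CCCCCC#N", "CC(C)(C)C#N", "CCCCCCC#N", "CCC(C)CC#N", "CC(C)CCC#N",
    ),
}

# crude fixed partial charges per chemical environment (e); residual charge
# is spread over carbons so every molecule is exactly neutral
_CHARGE_RULES = {
    "O_hydroxyl": -0.60,
    "O_ether": -0.40,
    "O_carbonyl": -0.50,
    "H_on_O": 0.42,
    "N": -0.70,
    "H_on_N": 0.35,
    "H_on_C": 0.06,
}


@dataclass(frozen=True)
class Compound:
    compound_id: str
    smiles: str
    functional_class: str
    mol: MoleculeGraph = field(compare=False)

    @property
    def molar_mass(self) -> float:
        return self.mol.molar_mass


def assign_fixed_charges(mol: MoleculeGraph) -> list[float]:
    """Rule-based neutral partial charges (not derived; fixed per group)."""
    elems = mol.elements
    neighbors: dict[int, list[int]] = {i: [] for i in range(mol.n_atoms)}
    for i, j in mol.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    q = [0.0] * mol.n_atoms
    for i, elem in enumerate(elems):
        nbr_elems = [elems[j] for j in neighbors[i]]
        if elem == "O":
            if "H" in nbr_elems:
                q[i] = _CHARGE_RULES["O_hydroxyl"]
            elif len(neighbors[i]) == 1:
                q[i] = _CHARGE_RULES["O_carbonyl"]
            else:
                q[i] = _CHARGE_RULES["O_ether"]
        elif elem == "N":
            q[i] = _CHARGE_RULES["N"]
        elif elem == "H":
            parent = nbr_elems[0]
            q[i] = _CHARGE_RULES.get(f"H_on_{parent}", _CHARGE_RULES["H_on_C"])
    carbons = [i for i, e in enumerate(elems) if e == "C"]
    residual = -sum(q)
    if carbons:
        for i in carbons:
            q[i] += residual / len(carbons)
    elif mol.n_atoms:
        for i in range(mol.n_atoms):
            q[i] += residual / mol.n_atoms
    return q


def make_library(n: int, seed: int = 0) -> list[Compound]:
    """n unique compounds cycling through all functional-group classes."""
    if n < len(FUNCTIONAL_CLASSES):
        raise ValueError(
            f"need n >= {len(FUNCTIONAL_CLASSES)} to cover all classes, got {n}"
        )
    rng = np.random.default_rng(seed)
    order = list(FUNCTIONAL_CLASSES)
    rng.shuffle(order)
    picked: list[Compound] = []
    used: set[str] = set()
    offsets = {cls: int(rng.integers(len(_TEMPLATES[cls]))) for cls in order}
    i = 0
    while len(picked) < n:
        if i > 20 * n + 200:
            raise ValueError(f"cannot build {n} unique compounds from templates")
        cls = order[i % len(order)]
        templates = _TEMPLATES[cls]
        k = (offsets[cls] + i // len(order)) % len(templates)
        smiles = templates[k]
        i += 1
        if smiles in used:
            continue
        base = parse_compound(smiles)
        charges = assign_fixed_charges(base)
        mol = parse_compound(smiles, charges)
        picked.append(
            Compound(
                compound_id=f"cpd{len(picked):03d}",
                smiles=smiles,
                functional_class=cls,
                mol=mol,
            )
        )
        used.add(smiles)
    return picked


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

def ground_truth_parameters(model_name: str = "H2CO3N") -> LJParameterSet:
    """A known typed parameter set with well-separated H and O types.

    Values are deliberately displaced from the packaged starting parameters so
    recovering them is a real test, while C and N stay single-valued.
    """
    truth_by_element = {
        # modest displacements from the packaged starting values, so the
        # restraint center is nearby but recovery is a real test
        "H": [(0.0185, 1.4300), (0.0125, 0.7200), (0.0165, 1.4000), (0.0100, 0.5500)],
        "C": [(0.0950, 1.9500), (0.0950, 1.9500), (0.0950, 1.9500)],
        "O": [(0.2000, 1.6600), (0.1800, 1.7000), (0.2200, 1.7400)],
        "N": [(0.1850, 1.7800), (0.1850, 1.7800)],
    }
    model = build_model(model_name)
    values = {}
    for tid in model.type_ids:
        elem, idx = tid[0], int(tid[1:]) - 1
        eps, rmin = truth_by_element[elem][idx]
        values[tid] = (eps, rmin)
    types = {tid: LJType(tid, eps, rmin) for tid, (eps, rmin) in values.items()}
    return LJParameterSet(model_name=model_name, types=types)


# --------------------------------------------------------------------------
# Property oracle
# --------------------------------------------------------------------------

def _atom_features(compound: Compound) -> dict:
    mol = compound.mol
    elems = mol.elements
    neighbors: dict[int, list[int]] = {i: [] for i in range(mol.n_atoms)}
    for i, j in mol.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    polar_h_idx = [
        i
        for i, e in enumerate(elems)
        if e == "H" and elems[neighbors[i][0]] in ("N", "O")
    ]
    acceptors = sum(1 for e in elems if e in ("N", "O"))
    return {
        "n_polar_h": len(polar_h_idx),
        "n_acceptors": acceptors,
        "polar_h_idx": polar_h_idx,
    }


def oracle_properties(
    compound: Compound,
    params: LJParameterSet,
    model: TypingModel,
    noise: bool = False,
    seed: int = 0,
    constants: dict[str, float] | None = None,
    temperature: float = 298.0,
    noise_scales: dict[str, float] | None = None,
) -> PropertyRecord:
    """Deterministic smooth map from typed parameters to liquid properties,
    optionally with Gaussian noise at the configured scales."""
    c = dict(DEFAULT_ORACLE_CONSTANTS)
    if constants:
        c.update(constants)
    type_ids = assign_types(compound.mol, model)
    eps = np.array([params.get(t).epsilon for t in type_ids])
    rmh = np.array([params.get(t).rmin_half for t in type_ids])
    r3 = rmh**3
    feats = _atom_features(compound)
    sum_r3 = float(r3.sum())
    contact = sum(1.0 / rmh[i] ** 2 for i in feats["polar_h_idx"])
    density = (
        c["c_rho"] * compound.molar_mass / sum_r3
        + c["c_q"] * feats["n_acceptors"] * contact
    )
    hb = sum(np.sqrt(eps[i]) / rmh[i] for i in feats["polar_h_idx"])
    hov = (
        c["c_h"] * float(np.sqrt(eps) @ r3)
        + c["c_p"] * feats["n_acceptors"] * hb
        + R_KJ * temperature
    )
    polarity = feats["n_polar_h"] + feats["n_acceptors"]
    dielectric = 1.0 + c["c_d"] * polarity**2 / sum_r3
    if noise:
        scales = dict(DEFAULT_NOISE)
        if noise_scales:
            scales.update(noise_scales)
        rng = np.random.default_rng((seed, zlib.crc32(compound.compound_id.encode())))
        density += rng.normal(0, scales["density"])
        hov += rng.normal(0, scales["hov"])
        dielectric += rng.normal(0, scales["dielectric_rel"] * dielectric)
    return PropertyRecord(
        compound_id=compound.compound_id,
        density=density,
        hov=hov,
        dielectric=dielectric,
    )


# --------------------------------------------------------------------------
# Train/test splits
# --------------------------------------------------------------------------

def make_split(
    library: list[Compound], design: int, seed: int = 0
) -> tuple[list[Compound], list[Compound]]:
    """Split design 1: smallest class-covering train set (15/75 scaled);
    design 2: uniform random train of 30/75 scaled. Returns (train, test)."""
    n = len(library)
    rng = np.random.default_rng(seed)
    if design == 1:
        n_train = max(len(FUNCTIONAL_CLASSES), round(n * 15 / 75))
        by_class: dict[str, list[Compound]] = {}
        for cpd in library:
            by_class.setdefault(cpd.functional_class, []).append(cpd)
        if len(by_class) > n_train:
            raise ValueError(
                f"cannot cover {len(by_class)} classes with {n_train} training compounds"
            )
        train: list[Compound] = []
        for cls in sorted(by_class):
            members = by_class[cls]
            train.append(members[int(rng.integers(len(members)))])
        rest = [c for c in library if c not in train]
        extra_idx = rng.choice(len(rest), size=n_train - len(train), replace=False)
        train.extend(rest[i] for i in sorted(extra_idx))
    elif design == 2:
        n_train = round(n * 30 / 75)
        idx = rng.choice(n, size=n_train, replace=False)
        train = [library[i] for i in sorted(idx)]
    else:
        raise ValueError(f"unknown split design {design}")
    train_ids = {c.compound_id for c in train}
    test = [c for c in library if c.compound_id not in train_ids]
    return train, test


# --------------------------------------------------------------------------
# Whole-study bundle
# --------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A self-contained study: library, ground truth, and noisy references."""

    library: list[Compound]
    truth_model: TypingModel
    truth_params: LJParameterSet
    references: list[PropertyReference]
    constants: dict[str, float]
    noise_scales: dict[str, float]
    seed: int

    def reference_for(self, compound_id: str) -> PropertyReference:
        for ref in self.references:
            if ref.compound_id == compound_id:
                return ref
        raise KeyError(compound_id)

    def manifest(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_compounds": len(self.library),
                "truth_model": self.truth_model.name,
                "constants": self.constants,
                "noise_scales": self.noise_scales,
                "smiles": [c.smiles for c in self.library],
            },
            indent=2,
        )


def make_study(
    n: int = 75,
    seed: int = 0,
    truth_model_name: str = "H2CO3N",
    noise: bool = True,
    constants: dict[str, float] | None = None,
    noise_scales: dict[str, float] | None = None,
    denominators: dict[str, float] | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic study with noisy 'experimental' tables."""
    library = make_library(n, seed=seed)
    model = build_model(truth_model_name)
    truth = ground_truth_parameters(truth_model_name)
    c = dict(DEFAULT_ORACLE_CONSTANTS)
    if constants:
        c.update(constants)
    scales = dict(DEFAULT_NOISE)
    if noise_scales:
        scales.update(noise_scales)
    denom = dict(DEFAULT_DENOMINATORS)
    if denominators:
        denom.update(denominators)
    refs = []
    for cpd in library:
        rec = oracle_properties(
            cpd, truth, model, noise=noise, seed=seed, constants=c, noise_scales=scales
        )
        refs.append(
            PropertyReference(
                compound_id=rec.compound_id,
                density=rec.density,
                hov=rec.hov,
                dielectric=rec.dielectric,
                denominators=denom,
            )
        )
    return SyntheticStudy(
        library=library,
        truth_model=model,
        truth_params=truth,
        references=refs,
        constants=c,
        noise_scales=scales,
        seed=seed,
    )


class SurrogateObjective:
    """Fast oracle-backed objective over a compound set.

    Precomputes per-compound type-count vectors so each evaluation is pure
    arithmetic; suitable for use inside the optimizer loop.
    """

    def __init__(
        self,
        compounds: list[Compound],
        references: list[PropertyReference],
        model: TypingModel,
        constants: dict[str, float] | None = None,
        w_reg: float = 0.1,
        temperature: float = 298.0,
    ):
        from .objective import molecule_term, total_objective  # local to avoid cycle

        self._molecule_term = molecule_term
        self._total_objective = total_objective
        self.model = model
        self.w_reg = w_reg
        self.temperature = temperature
        self.constants = dict(DEFAULT_ORACLE_CONSTANTS)
        if constants:
            self.constants.update(constants)
        ref_by_id = {r.compound_id: r for r in references}
        self.entries = []
        for cpd in compounds:
            type_ids = assign_types(cpd.mol, model)
            counts: dict[str, int] = {}
            for tid in type_ids:
                counts[tid] = counts.get(tid, 0) + 1
            feats = _atom_features(cpd)
            ph_counts: dict[str, int] = {}
            for i in feats["polar_h_idx"]:
                ph_counts[type_ids[i]] = ph_counts.get(type_ids[i], 0) + 1
            self.entries.append(
                {
                    "compound": cpd,
                    "counts": counts,
                    "polar_h_counts": ph_counts,
                    "features": feats,
                    "reference": ref_by_id[cpd.compound_id],
                }
            )

    def predict(self, params: LJParameterSet, compound_index: int) -> PropertyRecord:
        entry = self.entries[compound_index]
        c = self.constants
        sum_r3 = sum(
            n * params.get(t).rmin_half ** 3 for t, n in entry["counts"].items()
        )
        sum_er3 = sum(
            n * np.sqrt(params.get(t).epsilon) * params.get(t).rmin_half ** 3
            for t, n in entry["counts"].items()
        )
        hb = sum(
            n * np.sqrt(params.get(t).epsilon) / params.get(t).rmin_half
            for t, n in entry["polar_h_counts"].items()
        )
        contact = sum(
            n / params.get(t).rmin_half ** 2
            for t, n in entry["polar_h_counts"].items()
        )
        feats = entry["features"]
        return PropertyRecord(
            compound_id=entry["compound"].compound_id,
            density=c["c_rho"] * entry["compound"].molar_mass / sum_r3
            + c["c_q"] * feats["n_acceptors"] * contact,
            hov=c["c_h"] * sum_er3
            + c["c_p"] * feats["n_acceptors"] * hb
            + R_KJ * self.temperature,
            dielectric=1.0
            + c["c_d"] * (feats["n_polar_h"] + feats["n_acceptors"]) ** 2 / sum_r3,
        )

    def predictions(self, params: LJParameterSet) -> list[PropertyRecord]:
        return [self.predict(params, i) for i in range(len(self.entries))]

    def residual_vector(self, params: LJParameterSet) -> np.ndarray:
        """Signed per-property residuals over denominators, for exact
        Gauss-Newton structure in the optimizer."""
        rows = []
        for i, entry in enumerate(self.entries):
            pred = self.predict(params, i)
            ref = entry["reference"]
            for prop in ("density", "hov"):
                y_ref = ref.get(prop)
                if y_ref is None:
                    continue
                rows.append((pred.get(prop) - y_ref) / ref.denominators[prop])
        return np.array(rows)

    def __call__(self, params: LJParameterSet):
        from .core import to_math

        terms = {}
        for i, entry in enumerate(self.entries):
            terms[entry["compound"].compound_id] = self._molecule_term(
                self.predict(params, i), entry["reference"]
            )
        return self._total_objective(terms, to_math(params), self.w_reg)
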