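"""Molecules and SMIRKS-based Lennard-Jones atom typing.

A typing model is an ordered list of one-atom SMIRKS rules in ascending
priority: the general per-element pattern is applied first and later
(more specific) rules overwrite it, so every atom of a covered element
always ends up with exactly one LJ type.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors


class ParseError(ValueError):
    """Raised for malformed SMILES or inconsistent charge input."""


class TypingError(ValueError):
    """Raised when an atom cannot be assigned a type."""


@dataclass(frozen=True)
class MoleculeGraph:
    """A small molecule with explicit hydrogens and optional partial charges.

    Atom order is stable: heavy atoms in SMILES order, then hydrogens as
    appended by explicit-H expansion.
    """

    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    charges: tuple[float, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a.GetSymbol() for a in self.mol.GetAtoms())

    @property
    def molar_mass(self) -> float:
        """Molar mass in g/mol."""
        return Descriptors.MolWt(self.mol)

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in self.mol.GetBonds()
        )

    def charge(self, idx: int) -> float:
        if self.charges is None:
            return 0.0
        return self.charges[idx]


def parse_compound(smiles: str, charges: list[float] | None = None) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph` with explicit H.

    ``charges`` are per-atom partial charges (units of e) in the final,
    explicit-hydrogen atom order; pass ``None`` for typing-only use.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    if charges is not None:
        if len(charges) != mol.GetNumAtoms():
            raise ParseError(
                f"{smiles!r}: got {len(charges)} charges for "
                f"{mol.GetNumAtoms()} atoms (explicit-H count)"
            )
        charges = tuple(float(q) for q in charges)
    return MoleculeGraph(smiles=smiles, mol=mol, charges=charges)


@dataclass(frozen=True)
class TypingRule:
    """One SMIRKS pattern bound to a type id, at a position in the ordered list.

    Rules later in the list (higher ``rank``) take priority. Several rules may
    share a ``type_id``: the general per-element fallback aliases the type of
    the element's first specific rule.
    """

    smirks: str
    type_id: str
    rank: int
    epsilon: float  # kcal/mol, starting value carried with the rule
    rmin_half: float  # Angstrom

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smirks)
        if patt is None:
            raise ValueError(f"bad SMIRKS {self.smirks!r}")
        tagged = [a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum() == 1]
        if len(tagged) != 1:
            raise ValueError(f"{self.smirks!r} must tag exactly one atom")
        return patt


@dataclass(frozen=True)
class TypingModel:
    """An ordered-SMIRKS LJ typing scheme (e.g. HCON, H2CO3N)."""

    name: str
    rules: tuple[TypingRule, ...]

    @property
    def type_ids(self) -> tuple[str, ...]:
        """Distinct type ids in first-appearance order."""
        out: list[str] = []
        for rule in self.rules:
            if rule.type_id not in out:
                out.append(rule.type_id)
        return tuple(out)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    def elements(self) -> set[str]:
        elems = set()
        for rule in self.rules:
            m = re.match(r"\[#(\d+)", rule.smirks)
            if m:
                elems.add(int(m.group(1)))
        return {Chem.GetPeriodicTable().GetElementSymbol(z) for z in elems}

    def initial_parameters(self) -> dict[str, tuple[float, float]]:
        """Starting (epsilon, rmin_half) per type id.

        Where a general fallback aliases a specific rule's type, the specific
        (higher-rank) rule's values win, matching the overwrite semantics.
        """
        out: dict[str, tuple[float, float]] = {}
        for rule in self.rules:  # ascending rank: later rules overwrite
            out[rule.type_id] = (rule.epsilon, rule.rmin_half)
        return out


def _tagged_query_index(patt: Chem.Mol) -> int:
    for atom in patt.GetAtoms():
        if atom.GetAtomMapNum() == 1:
            return atom.GetIdx()
    raise ValueError("pattern has no :1 tagged atom")


def assign_types(mol: MoleculeGraph, model: TypingModel) -> list[str]:
    """Assign one LJ type id to every atom, last matching rule winning."""
    assigned: list[str | None] = [None] * mol.n_atoms
    for rule in model.rules:  # ascending priority; later rules overwrite
        patt = rule.pattern()
        tag = _tagged_query_index(patt)
        for match in mol.mol.GetSubstructMatches(patt, uniquify=False, maxMatches=10000):
            assigned[match[tag]] = rule.type_id
    for idx, tid in enumerate(assigned):
        if tid is None:
            elem = mol.mol.GetAtomWithIdx(idx).GetSymbol()
            raise TypingError(
                f"atom {idx} ({elem}) of {mol.smiles!r} matched no rule of "
                f"model {model.name}"
            )
    return assigned  # type: ignore[return-value]


def count_types(model: TypingModel, compounds: list[MoleculeGraph] = ()) -> int:
    """Number of distinct types used across ``compounds``.

    With an empty compound list this is the model's defined type count
    (e.g. HC3ON -> 1 + 3 + 1 + 1 = 6).
    """
    if not compounds:
        return model.n_types
    used: set[str] = set()
    for mol in compounds:
        used.update(assign_types(mol, model))
    return len(used)


def refinement_relation(
    coarse: TypingModel, fine: TypingModel, probes: list[MoleculeGraph]
) -> tuple[bool, dict[str, str] | None]:
    """Does ``fine`` refine ``coarse`` over the probe set?

    True iff every fine type maps into exactly one coarse type (the fine atom
    partition subdivides the coarse one); returns the fine->coarse type
    surjection when true, else (False, None).
    """
    mapping: dict[str, set[str]] = {}
    for mol in probes:
        fine_ids = assign_types(mol, fine)
        coarse_ids = assign_types(mol, coarse)
        for f, c in zip(fine_ids, coarse_ids):
            mapping.setdefault(f, set()).add(c)
    if all(len(targets) == 1 for targets in mapping.values()):
        return True, {f: next(iter(c)) for f, c in mapping.items()}
    return False, None


# --------------------------------------------------------------------------
# Packaged typing-rule building blocks.
#
# Ordered ascending in priority within each element. The first (general)
# entry carries the single-type starting parameters; when an element is
# split, the general pattern stays as the lowest-priority fallback aliased
# to the first specific type.
#
# The SMIRKS strings are authoritative over any prose label:
# [#8X2H1+0] = hydroxyl O, [#8X2H0+0] = ether O, [#1:1]-[#7] = amine H,
# [#1:1]-[#8] = hydroxyl H.
# --------------------------------------------------------------------------

# element -> n_types -> list of (smirks, epsilon, rmin_half)
# The sp2-H rule optionally covers sp C hydrogens too (see SP_CARBON_H).
SP_CARBON_H_EXTENSION = True  # include #6X2 in the sp2-H pattern

_H_SP2_PATTERN = "[#1:1]-[#6X3,#6X2]" if SP_CARBON_H_EXTENSION else "[#1:1]-[#6X3]"

_BLOCKS: dict[str, dict[int, list[tuple[str, float, float]]]] = {
    "H": {
        1: [("[#1:1]", 0.0157, 1.4870)],
        2: [
            ("[#1:1]-[#6]", 0.0157, 1.4870),  # apolar
            ("[#1:1]-[#7,#8]", 0.0157, 0.6000),  # polar
        ],
        4: [
            ("[#1:1]-[#6X4]", 0.0157, 1.4870),
            (_H_SP2_PATTERN, 0.0150, 1.4590),
            ("[#1:1]-[#7]", 0.0157, 0.6000),
            ("[#1:1]-[#8]", 5.27e-05, 0.3000),
        ],
    },
    "C": {
        1: [("[#6:1]", 0.0860, 1.9080)],
        3: [
            ("[#6:1]", 0.0860, 1.9080),  # general; effectively sp2
            ("[#6X4:1]", 0.1094, 1.9080),
            ("[#6X2:1]", 0.2100, 1.9080),
        ],
    },
    "O": {
        1: [("[#8:1]", 0.2100, 1.6612)],
        3: [
            ("[#8:1]", 0.2100, 1.6612),  # general; effectively carbonyl
            ("[#8X2H0+0:1]", 0.1700, 1.6837),  # ether
            ("[#8X2H1+0:1]", 0.2104, 1.7210),  # hydroxyl
        ],
    },
    "N": {
        1: [("[#7:1]", 0.1700, 1.8240)],
        2: [
            ("[#7:1]", 0.1700, 1.8240),  # general; effectively X1
            ("[#7X3:1]", 0.1700, 1.8240),
        ],
    },
}

_GENERAL = {"H": "[#1:1]", "C": "[#6:1]", "O": "[#8:1]", "N": "[#7:1]"}

_ELEMENT_ORDER = ("H", "C", "O", "N")

# 15-type SMIRNOFF-style skeleton covering the study's compound chemistry:
# 8 H, 3 C, 3 O, 1 N types.
_EWG = "[#7,#8,#9,#16,#17,#35]"
_SMIRFF15: list[tuple[str, str, float, float]] = [
    ("[#1:1]", "H1", 0.0157, 1.4870),
    ("[#1:1]-[#6X4]", "H1", 0.0157, 1.4870),
    (f"[#1:1]-[#6X4]-{_EWG}", "H2", 0.0157, 1.3870),
    (f"[#1:1]-[#6X4](-{_EWG})-{_EWG}", "H3", 0.0157, 1.2870),
    (f"[#1:1]-[#6X4](-{_EWG})(-{_EWG})-{_EWG}", "H4", 0.0157, 1.1870),
    ("[#1:1]-[#6X3]", "H5", 0.0150, 1.4590),
    (f"[#1:1]-[#6X3]~{_EWG}", "H6", 0.0150, 1.4090),
    ("[#1:1]-[#7]", "H7", 0.0157, 0.6000),
    ("[#1:1]-[#8]", "H8", 5.27e-05, 0.3000),
    ("[#6:1]", "C1", 0.0860, 1.9080),
    ("[#6X4:1]", "C2", 0.1094, 1.9080),
    ("[#6X2:1]", "C3", 0.2100, 1.9080),
    ("[#8:1]", "O1", 0.2100, 1.6612),
    ("[#8X2H0+0:1]", "O2", 0.1700, 1.6837),
    ("[#8X2H1+0:1]", "O3", 0.2104, 1.7210),
    ("[#7:1]", "N1", 0.1700, 1.8240),
]

_NAME_RE = re.compile(r"(H|C|O|N)(\d?)")

#: The eleven typing schemes exercised in the study, plus the 15-type skeleton.
STANDARD_MODELS = (
    "HCON",
    "H4CON",
    "HC3ON",
    "HCO3N",
    "HCON2",
    "H4C3O3N2",
    "H2CON",
    "H2C3ON",
    "H2CO3N",
    "H2CON2",
    "SMIRFF15",
)


def parse_model_name(name: str) -> dict[str, int]:
    """``"H2CO3N" -> {"H": 2, "C": 1, "O": 3, "N": 1}`` (absent digit = 1)."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _NAME_RE.finditer(name):
        if m.start() != pos:
            raise ValueError(f"bad model name {name!r}")
        counts[m.group(1)] = int(m.group(2) or 1)
        pos = m.end()
    if pos != len(name) or not counts:
        raise ValueError(f"bad model name {name!r}")
    for elem, n in counts.items():
        if n not in _BLOCKS[elem]:
            raise ValueError(
                f"no rule block for {n} {elem} types (have {sorted(_BLOCKS[elem])})"
            )
    return counts


def build_model(name: str) -> TypingModel:
    """Construct a typing model from its name (HCON grammar) or SMIRFF15."""
    if name.upper() == "SMIRFF15":
        rules = tuple(
            TypingRule(smirks=s, type_id=t, rank=i, epsilon=e, rmin_half=r)
            for i, (s, t, e, r) in enumerate(_SMIRFF15)
        )
        return TypingModel(name="SMIRFF15", rules=rules)
    counts = parse_model_name(name)
    rules: list[TypingRule] = []
    rank = 0
    for elem in _ELEMENT_ORDER:
        if elem not in counts:
            continue
        block = _BLOCKS[elem][counts[elem]]
        type_ids = [f"{elem}{i + 1}" for i in range(counts[elem])]
        entries = list(block)
        # ensure a general fallback exists, aliased to the first type
        if entries[0][0] != _GENERAL[elem]:
            entries.insert(0, (_GENERAL[elem], entries[0][1], entries[0][2]))
        for i, (smirks, eps, rmin) in enumerate(entries):
            if len(entries) > counts[elem]:  # general fallback present as extra row
                tid = type_ids[0] if i == 0 else type_ids[i - 1]
            else:
                tid = type_ids[i]
            rules.append(
                TypingRule(smirks=smirks, type_id=tid, rank=rank, epsilon=eps, rmin_half=rmin)
            )
            rank += 1
    return TypingModel(name=name, rules=tuple(rules))


# --------------------------------------------------------------------------
# Serialization: a SMIRNOFF-offxml-style vdW block.
# --------------------------------------------------------------------------

def model_to_offxml(model: TypingModel, params: dict[str, tuple[float, float]] | None = None) -> str:
    """Serialize the ordered rule list as an offxml-style ``<vdW>`` block."""
    values = params or model.initial_parameters()
    root = ET.Element("SMIRNOFF")
    vdw = ET.SubElement(root, "vdW", attrib={"model": model.name})
    for rule in model.rules:
        eps, rmin = values[rule.type_id]
        ET.SubElement(
            vdw,
            "Atom",
            attrib={
                "smirks": rule.smirks,
                "type": rule.type_id,
                "epsilon": f"{eps:.6g} * kilocalorie/mole",
                "rmin_half": f"{rmin:.6g} * angstrom",
            },
        )
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def model_from_offxml(text: str) -> TypingModel:
    root = ET.fromstring(text)
    vdw = root.find("vdW")
    if vdw is None:
        raise ValueError("no <vdW> block found")
    rules = []
    for rank, atom in enumerate(vdw.findall("Atom")):
        rules.append(
            TypingRule(
                smirks=atom.get("smirks"),
                type_id=atom.get("type"),
                rank=rank,
                epsilon=float(atom.get("epsilon").split("*")[0]),
                rmin_half=float(atom.get("rmin_half").split("*")[0]),
            )
        )
    return TypingModel(name=vdw.get("model", "unnamed"), rules=tuple(rules))
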