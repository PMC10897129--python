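"""Virtual one-pot, two-step three-component synthesis of DB-lipidoids.

The reaction sequence modeled here:

1. **Ring opening.** An amine nitrogen bearing an N-H attacks the terminal
   (less hindered) carbon of a 1,2-alkyl epoxide, giving
   ``N-CH2-CH(OH)-alkyl`` with a secondary alcohol. Applied twice, this
   yields the *aminoalcohol lipidoid* with two body tails. Atoms are
   conserved (no leaving group).
2. **Acylation.** Each free hydroxyl reacts with an acyl chloride to form an
   ester, formally eliminating HCl, attaching one *branch tail* per ester.

Products are named ``x-m-n``: amine number x, body-tail carbons m, branch
tail carbons n (carbonyl carbon included). ``degrade`` is the inverse
bookkeeping for esterase hydrolysis: each ester consumes one water, yielding
a fatty acid and regenerating a hydroxyl; cleaving both esters returns the
non-degradable aminoalcohol metabolite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

from . import chem
from .building_blocks import BuildingBlock, Registry
from .errors import ReactionError, ValidationError

STAGES = ("aminoalcohol", "one_branch", "two_branch")

PROTON_MASS = 1.007276466  # Da

_MONOISOTOPIC = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Cl": 34.96885271,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.99840320,
    "Br": 78.9183376,
    "I": 126.904468,
}


@dataclass(frozen=True)
class Lipidoid:
    """An enumerated lipidoid (product or intermediate) with provenance."""

    name: str
    structure: str
    amine_id: str
    epoxide_id: str
    acyl_id: str | None
    stage: str
    formula: dict[str, int]
    monoisotopic_mass: float
    average_mass: float

    @classmethod
    def from_mol(
        cls,
        mol: Chem.Mol,
        name: str,
        amine_id: str,
        epoxide_id: str,
        acyl_id: str | None,
        stage: str,
    ) -> "Lipidoid":
        return cls(
            name=name,
            structure=chem.canonical_smiles(mol),
            amine_id=amine_id,
            epoxide_id=epoxide_id,
            acyl_id=acyl_id,
            stage=stage,
            formula=chem.formula_map(mol),
            monoisotopic_mass=chem.monoisotopic_mass_of(mol),
            average_mass=chem.average_mass_of(mol),
        )

    @property
    def mol(self) -> Chem.Mol:
        return chem.mol_from_smiles(self.structure, f"lipidoid {self.name!r}")

    @property
    def xmn(self) -> tuple[int, int, int]:
        return parse_name(self.name)


@dataclass(frozen=True)
class FattyAcid:
    structure: str
    formula: dict[str, int]
    average_mass: float


@dataclass
class MetaboliteSet:
    """Products of esterase degradation of a DB-lipidoid."""

    aminoalcohol: Lipidoid | None = None
    intermediate: Lipidoid | None = None
    fatty_acids: list[FattyAcid] = field(default_factory=list)

    @property
    def remnant(self) -> Lipidoid:
        rem = self.aminoalcohol if self.aminoalcohol is not None else self.intermediate
        assert rem is not None
        return rem


def make_name(x: int, m: int, n: int | None) -> str:
    return f"{x}-{m}" if n is None else f"{x}-{m}-{n}"


def parse_name(name: str) -> tuple[int, int, int]:
    """Recover (x, m, n) from an ``x-m-n`` name."""
    parts = name.split("-")
    if len(parts) != 3:
        raise ValidationError(f"lipidoid name {name!r} is not of the form x-m-n")
    try:
        x, m, n = (int(p) for p in parts)
    except ValueError as exc:
        raise ValidationError(f"lipidoid name {name!r} is not numeric x-m-n") from exc
    return x, m, n


def _determine_stage(mol: Chem.Mol) -> str:
    esters = chem.count_esters(mol)
    if esters >= 2:
        return "two_branch"
    if esters == 1:
        return "one_branch"
    return "aminoalcohol"


def _ring_open_once(mol: Chem.Mol, epoxide: Chem.Mol) -> Chem.Mol:
    """Attach one body tail at the lowest-index substitutable N-H."""
    nh = chem.substitutable_nh(mol)
    if not nh:
        raise ReactionError("no substitutable N-H remaining for ring opening")
    n_idx = min(nh)
    match = epoxide.GetSubstructMatch(chem.TERMINAL_EPOXIDE)
    if not match:
        raise ReactionError("epoxide has no terminal 1,2-epoxide group")
    combo = Chem.RWMol(Chem.CombineMols(mol, epoxide))
    offset = mol.GetNumAtoms()
    ch2, _ch, oxy = (offset + i for i in match)
    combo.RemoveBond(ch2, oxy)  # SN2 at the terminal carbon -> secondary alcohol
    combo.AddBond(n_idx, ch2, Chem.BondType.SINGLE)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return product


def open_epoxide(
    amine: BuildingBlock, epoxide: BuildingBlock, count: int = 2
) -> Lipidoid:
    """Ring-open ``count`` epoxides onto the amine (the first reaction step)."""
    if count not in (0, 1, 2):
        raise ValidationError(f"count must be 0, 1 or 2, got {count}")
    amine_mol = amine.mol
    available = chem.total_substitutable_nh(amine_mol)
    if available < count:
        raise ReactionError(
            f"cannot attach {count} body tails: amine {amine.id!r} has only "
            f"{available} substitutable N-H"
        )
    if not epoxide.mol.GetSubstructMatch(chem.TERMINAL_EPOXIDE):
        raise ReactionError(f"epoxide {epoxide.id!r} is not a terminal 1,2-epoxide")
    mol = amine_mol
    for _ in range(count):
        mol = _ring_open_once(mol, epoxide.mol)
    stage = _determine_stage(mol) if count == 2 else "aminoalcohol"
    return Lipidoid.from_mol(
        mol,
        name=make_name(amine.number, epoxide.carbon_count, None),
        amine_id=amine.id,
        epoxide_id=epoxide.id,
        acyl_id=None,
        stage=stage,
    )


def _acylate_once(mol: Chem.Mol, acyl: Chem.Mol) -> Chem.Mol:
    """Esterify the lowest-index free hydroxyl, eliminating HCl."""
    hydroxyls = mol.GetSubstructMatches(chem.HYDROXYL)
    if not hydroxyls:
        raise ReactionError("no free hydroxyl remaining for acylation")
    o_idx = min(h[0] for h in hydroxyls)
    match = acyl.GetSubstructMatch(chem.ACYL_CHLORIDE)
    if not match:
        raise ReactionError("acylating agent has no -C(=O)Cl group")
    combo = Chem.RWMol(Chem.CombineMols(mol, acyl))
    offset = mol.GetNumAtoms()
    carbonyl, _odbl, chloride = (offset + i for i in match)
    combo.AddBond(o_idx, carbonyl, Chem.BondType.SINGLE)
    combo.RemoveAtom(chloride)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return product


def acylate(aminoalcohol: Lipidoid, acyl: BuildingBlock, count: int = 2) -> Lipidoid:
    """Attach ``count`` branch tails via ester bonds (the second step)."""
    if count not in (0, 1, 2):
        raise ValidationError(f"count must be 0, 1 or 2, got {count}")
    mol = aminoalcohol.mol
    free_oh = chem.count_hydroxyls(mol)
    if free_oh < count:
        raise ReactionError(
            f"cannot attach {count} branch tails: only {free_oh} free hydroxyls"
        )
    for _ in range(count):
        mol = _acylate_once(mol, acyl.mol)
    name = (
        aminoalcohol.name if count == 0 else f"{aminoalcohol.name}-{acyl.carbon_count}"
    )
    return Lipidoid.from_mol(
        mol,
        name=name,
        amine_id=aminoalcohol.amine_id,
        epoxide_id=aminoalcohol.epoxide_id,
        acyl_id=acyl.id if count else aminoalcohol.acyl_id,
        stage=_determine_stage(mol),
    )


def synthesize(
    amine: BuildingBlock, epoxide: BuildingBlock, acyl: BuildingBlock
) -> Lipidoid:
    """Full two-step synthesis: two body tails, then two branch tails."""
    return acylate(open_epoxide(amine, epoxide, 2), acyl, 2)


@dataclass(frozen=True)
class LibraryDesign:
    """Which registry blocks to combine (full cross product)."""

    amine_ids: tuple[str, ...]
    epoxide_ids: tuple[str, ...]
    acyl_ids: tuple[str, ...]

    @classmethod
    def of(
        cls,
        amine_ids: Iterable[str],
        epoxide_ids: Iterable[str],
        acyl_ids: Iterable[str],
    ) -> "LibraryDesign":
        return cls(tuple(amine_ids), tuple(epoxide_ids), tuple(acyl_ids))


def library_1_design(registry: Registry) -> LibraryDesign:
    """Amine 1 crossed with every epoxide and acyl chloride (25 products)."""
    return LibraryDesign.of(
        ["amine-1"],
        [b.id for b in registry.epoxides],
        [b.id for b in registry.acyl_chlorides],
    )


def library_2_design(registry: Registry) -> LibraryDesign:
    """Every amine with the optimal C10 body / C8 branch tails (20 products)."""
    return LibraryDesign.of(
        [b.id for b in registry.amines], ["epoxide-10"], ["acyl-8"]
    )


def enumerate_library(
    registry: Registry, design: LibraryDesign
) -> list[Lipidoid]:
    """Enumerate the design's cross product of two-branch DB-lipidoids.

    Amines that cannot attach exactly two body tails (total substitutable
    N-H != 2) are skipped with a warning, mirroring the design constraint
    that keeps the library structurally homogeneous. Ordering is
    deterministic: amine number, then m, then n, ascending.
    """
    amines = [registry.get(i) for i in design.amine_ids]
    epoxides = [registry.get(i) for i in design.epoxide_ids]
    acyls = [registry.get(i) for i in design.acyl_ids]
    kept = []
    for amine in amines:
        if chem.total_substitutable_nh(amine.mol) == 2:
            kept.append(amine)
        else:
            warnings.warn(
                f"skipping amine {amine.id!r}: cannot attach exactly two body tails",
                stacklevel=2,
            )
    kept.sort(key=lambda b: b.number)
    epoxides.sort(key=lambda b: b.carbon_count)
    acyls.sort(key=lambda b: b.carbon_count)
    out = []
    for amine in kept:
        for epoxide in epoxides:
            aminoalcohol = open_epoxide(amine, epoxide, 2)
            for acyl in acyls:
                out.append(acylate(aminoalcohol, acyl, 2))
    return out


def monoisotopic_mass(target: Lipidoid | dict[str, int] | str) -> float:
    """Monoisotopic mass (Da) of a lipidoid, formula map, or formula string."""
    if isinstance(target, Lipidoid):
        formula = target.formula
    elif isinstance(target, str):
        formula = parse_formula(target)
    else:
        formula = target
    if not formula:
        raise ValidationError("empty molecular formula")
    mass = 0.0
    for element, count in formula.items():
        if element not in _MONOISOTOPIC:
            raise ValidationError(f"unknown element symbol {element!r}")
        mass += _MONOISOTOPIC[element] * count
    return mass


def protonated_mass(target: Lipidoid | dict[str, int] | str) -> float:
    """[M+H]+ m/z for ESI-MS comparison."""
    return monoisotopic_mass(target) + PROTON_MASS


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula like ``C42H82N2O4``."""
    import re

    out: dict[str, int] = {}
    pos = 0
    for match in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = match.end()
        out[match.group(1)] = out.get(match.group(1), 0) + int(match.group(2) or 1)
    if pos != len(formula) or not out:
        raise ValidationError(f"cannot parse formula {formula!r}")
    return out


def degrade(lipidoid: Lipidoid, esters_cleaved: int) -> MetaboliteSet:
    """Hydrolyze ``esters_cleaved`` ester bonds (esterase bookkeeping).

    Each cleavage consumes one water: the acyl fragment leaves as a fatty
    acid and the remnant regains a hydroxyl. Element conservation therefore
    holds as ``lipidoid + k H2O = remnant + k fatty acid``.
    """
    mol = lipidoid.mol
    available = chem.count_esters(mol)
    if esters_cleaved < 0 or esters_cleaved > available:
        raise ReactionError(
            f"cannot cleave {esters_cleaved} esters: {available} available"
        )
    if esters_cleaved == 0:
        out = MetaboliteSet()
        if lipidoid.stage == "aminoalcohol":
            out.aminoalcohol = lipidoid
        else:
            out.intermediate = lipidoid
        return out

    fatty_acids: list[FattyAcid] = []
    for _ in range(esters_cleaved):
        match = mol.GetSubstructMatch(chem.ESTER)
        carbonyl, _odbl, ester_o, _calk = match
        rw = Chem.RWMol(mol)
        rw.RemoveBond(carbonyl, ester_o)
        new_o = rw.AddAtom(Chem.Atom(8))  # the water-derived hydroxyl
        rw.AddBond(carbonyl, new_o, Chem.BondType.SINGLE)
        split = rw.GetMol()
        Chem.SanitizeMol(split)
        frags = Chem.GetMolFrags(split, asMols=True)
        acid = min(frags, key=lambda m: m.GetNumHeavyAtoms())
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        fatty_acids.append(
            FattyAcid(
                structure=chem.canonical_smiles(acid),
                formula=chem.formula_map(acid),
                average_mass=chem.average_mass_of(acid),
            )
        )

    stage = _determine_stage(mol)
    remnant = Lipidoid.from_mol(
        mol,
        name=lipidoid.name,
        amine_id=lipidoid.amine_id,
        epoxide_id=lipidoid.epoxide_id,
        acyl_id=lipidoid.acyl_id if stage != "aminoalcohol" else None,
        stage=stage,
    )
    out = MetaboliteSet(fatty_acids=fatty_acids)
    if stage == "aminoalcohol":
        out.aminoalcohol = remnant
    else:
        out.intermediate = remnant
    return out


# ---------------------------------------------------------------------------
# Tabular / SDF output


def library_to_dataframe(lipidoids: Sequence[Lipidoid]):
    """Flat table: name, x, m, n, formula, masses, SMILES."""
    import pandas as pd

    rows = []
    for lip in lipidoids:
        x, m, n = lip.xmn
        rows.append(
            {
                "name": lip.name,
                "x": x,
                "m": m,
                "n": n,
                "formula": _hill(lip.formula),
                "monoisotopic_mass": round(lip.monoisotopic_mass, 4),
                "average_mass": round(lip.average_mass, 4),
                "smiles": lip.structure,
            }
        )
    return pd.DataFrame(rows)


def _hill(formula: dict[str, int]) -> str:
    order = ["C", "H"] + sorted(e for e in formula if e not in ("C", "H"))
    return "".join(
        f"{el}{formula[el] if formula[el] != 1 else ''}" for el in order if el in formula
    )


def write_library_csv(lipidoids: Sequence[Lipidoid], path: str | Path) -> Path:
    path = Path(path)
    library_to_dataframe(lipidoids).to_csv(path, index=False)
    return path


def write_library_sdf(lipidoids: Sequence[Lipidoid], path: str | Path) -> Path:
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for lip in lipidoids:
            mol = lip.mol
            mol.SetProp("_Name", lip.name)
            mol.SetProp("formula", _hill(lip.formula))
            mol.SetProp("monoisotopic_mass", f"{lip.monoisotopic_mass:.4f}")
            mol.SetProp("average_mass", f"{lip.average_mass:.4f}")
            writer.write(mol)
    finally:
        writer.close()
    return path
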