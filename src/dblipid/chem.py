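"""Low-level RDKit helpers shared across the package.

All structures are handled as canonical, stereochemistry-free SMILES: the
one-pot synthesis this package models produces racemic products and no
stereocenters are tracked, so stripping stereo gives reproducible equality
checks by string comparison.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ValidationError

RDLogger.DisableLog("rdApp.*")

# Substructure patterns used throughout.
TERMINAL_EPOXIDE = Chem.MolFromSmarts("[CH2;r3]1[CH1;r3][OX2;r3]1")
ANY_EPOXIDE = Chem.MolFromSmarts("[C;r3]1[C;r3][OX2;r3]1")
ACYL_CHLORIDE = Chem.MolFromSmarts("[CX3](=[OX1])[Cl]")
ESTER = Chem.MolFromSmarts("[CX3](=[OX1])[OX2][#6]")
HYDROXYL = Chem.MolFromSmarts("[OX2H1][CX4]")
PRIMARY_AMINE = Chem.MolFromSmarts("[NX3;H2;$(N[CX4]);!$(N~[!#6]);!$(NC=[O,S,N])]")
SECONDARY_AMINE = Chem.MolFromSmarts(
    "[NX3;H1;$(N([CX4])[CX4]);!$(N~[!#6]);!$(NC=[O,S,N])]"
)
TERTIARY_AMINE = Chem.MolFromSmarts(
    "[NX3;H0;$(N([CX4])([CX4])[CX4]);!$(N~[!#6]);!$(NC=[O,S,N])]"
)
HYDRAZINE = Chem.MolFromSmarts("[NX3][NX3]")

_uncharger = rdMolStandardize.Uncharger()


def mol_from_smiles(smiles: str, what: str = "structure") -> Chem.Mol:
    """Parse SMILES or raise :class:`ValidationError`."""
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValidationError(f"unparseable {what}: {smiles!r}")
    return mol


def canonical_smiles(mol_or_smiles) -> str:
    """Canonical stereo-free SMILES of the free-base molecule."""
    mol = (
        mol_from_smiles(mol_or_smiles)
        if isinstance(mol_or_smiles, str)
        else Chem.Mol(mol_or_smiles)
    )
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Return the free base: drop counter-ions, then remove formal charges.

    Mirrors the bench practice of neutralizing amine salts with excess base
    before the first reaction step; the registry always stores the free base.
    """
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    mol = _uncharger.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def carbon_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)


def formula_map(mol: Chem.Mol) -> dict[str, int]:
    """Element -> count map, hydrogens included."""
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def formula_string(mol: Chem.Mol) -> str:
    return rdMolDescriptors.CalcMolFormula(mol)


def add_formulas(*formulas: dict[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for f in formulas:
        for el, n in f.items():
            out[el] = out.get(el, 0) + n
    return {el: n for el, n in out.items() if n != 0}


def scale_formula(formula: dict[str, int], k: int) -> dict[str, int]:
    return {el: k * n for el, n in formula.items()}


def monoisotopic_mass_of(mol: Chem.Mol) -> float:
    return Descriptors.ExactMolWt(mol)


def average_mass_of(mol: Chem.Mol) -> float:
    return Descriptors.MolWt(mol)


def substitutable_nh(mol: Chem.Mol) -> dict[int, int]:
    """Map atom index -> N-H count for reactive amine nitrogens.

    A nitrogen is substitutable when it is non-aromatic, carries at least one
    hydrogen, and is not amide-like (no neighbouring carbon double-bonded to
    O/S). Hydrazine nitrogens qualify: they do attach body tails, they are
    simply penalized later at the headgroup-classification stage.
    """
    out: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
            continue
        amide_like = any(
            nb.GetAtomicNum() == 6
            and any(
                b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(nb).GetAtomicNum() in (7, 8, 16)
                for b in nb.GetBonds()
            )
            for nb in atom.GetNeighbors()
        )
        if amide_like:
            continue
        h = atom.GetTotalNumHs()
        if h:
            out[atom.GetIdx()] = h
    return out


def total_substitutable_nh(mol: Chem.Mol) -> int:
    return sum(substitutable_nh(mol).values())


def count_esters(mol: Chem.Mol) -> int:
    return len(mol.GetSubstructMatches(ESTER))


def count_hydroxyls(mol: Chem.Mol) -> int:
    return len(mol.GetSubstructMatches(HYDROXYL))
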