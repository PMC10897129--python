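"""Building-block registries: amines, epoxides, acyl chlorides.

A library design is parameterized by three registries of blocks. Each block
carries a SMILES structure, a declared carbon count, and a kind-specific set
of structural invariants:

* ``epoxide`` — exactly one terminal 1,2-epoxide; declared carbon count must
  equal the carbons in the parsed structure (the body-tail length ``m``).
* ``acyl_chloride`` — exactly one ``-C(=O)Cl``; linear saturated acyl chain;
  declared carbon count (branch-tail length ``n``) includes the carbonyl
  carbon.
* ``amine`` — at least one nitrogen bearing a substitutable hydrogen.

Structures are stored canonicalized, stereo-free, and as the free base
(salt forms are neutralized on load).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem

from . import chem
from .errors import RegistryError, ValidationError

KINDS = ("amine", "epoxide", "acyl_chloride")
REGISTRY_COLUMNS = ("id", "kind", "structure", "carbon_count", "label", "salt_form")


@dataclass(frozen=True)
class BuildingBlock:
    """One amine, epoxide, or acyl chloride.

    ``structure`` is canonical free-base SMILES. ``carbon_count`` is the
    declared total carbon number (``m`` for epoxides, ``n`` for acyl
    chlorides, carbonyl carbon included).
    """

    id: str
    kind: str
    structure: str
    carbon_count: int
    label: str = ""
    salt_form: bool = False

    @classmethod
    def create(
        cls,
        id: str,
        kind: str,
        structure: str,
        carbon_count: int,
        label: str = "",
        salt_form: bool = False,
    ) -> "BuildingBlock":
        """Build a block with the structure neutralized and canonicalized."""
        mol = chem.mol_from_smiles(structure, f"structure for block {id!r}")
        mol = chem.neutralize(mol)
        return cls(
            id=id,
            kind=kind,
            structure=chem.canonical_smiles(mol),
            carbon_count=int(carbon_count),
            label=label,
            salt_form=bool(salt_form),
        )

    @property
    def mol(self) -> Chem.Mol:
        return chem.mol_from_smiles(self.structure, f"block {self.id!r}")

    @property
    def number(self) -> int:
        """Trailing integer of the id (``amine-11`` -> 11)."""
        tail = self.id.rsplit("-", 1)[-1]
        try:
            return int(tail)
        except ValueError as exc:
            raise ValidationError(f"block id {self.id!r} has no numeric suffix") from exc


def validate_block(block: BuildingBlock) -> list[str]:
    """Return the list of violated invariants (empty when valid)."""
    violations: list[str] = []
    try:
        mol = chem.mol_from_smiles(block.structure)
    except ValidationError:
        return [f"unparseable structure {block.structure!r}"]

    if len(Chem.GetMolFrags(mol)) != 1:
        violations.append("structure is not a single connected molecule")

    if block.kind not in KINDS:
        violations.append(f"unknown kind {block.kind!r}")
        return violations

    n_carbons = chem.carbon_count(mol)
    if block.kind == "epoxide":
        n_terminal = len(mol.GetSubstructMatches(chem.TERMINAL_EPOXIDE))
        n_any = len(mol.GetSubstructMatches(chem.ANY_EPOXIDE))
        if n_terminal != 1 or n_any != 1:
            violations.append("epoxide must contain exactly one terminal 1,2-epoxide")
        if block.carbon_count != n_carbons:
            violations.append(
                f"declared carbon_count {block.carbon_count} != "
                f"{n_carbons} carbons in structure"
            )
    elif block.kind == "acyl_chloride":
        if len(mol.GetSubstructMatches(chem.ACYL_CHLORIDE)) != 1:
            violations.append("acyl chloride must contain exactly one -C(=O)Cl group")
        if mol.GetRingInfo().NumRings() > 0:
            violations.append("acyl chain must be linear (no rings)")
        elif any(
            b.GetBondType() != Chem.BondType.SINGLE
            and not (
                b.GetBeginAtom().GetAtomicNum() == 8
                or b.GetEndAtom().GetAtomicNum() == 8
            )
            for b in mol.GetBonds()
        ):
            violations.append("acyl chain must be saturated")
        if _acyl_is_branched(mol):
            violations.append("acyl chain must be linear (no branching)")
        if block.carbon_count != n_carbons:
            violations.append(
                f"declared carbon_count {block.carbon_count} != "
                f"{n_carbons} carbons in structure"
            )
    else:  # amine
        if not chem.substitutable_nh(mol):
            violations.append("amine must bear at least one substitutable N-H")
    return violations


def _acyl_is_branched(mol: Chem.Mol) -> bool:
    # Every carbon except the carbonyl has at most 2 heavy neighbours in a
    # linear acyl chloride; the carbonyl carbon has exactly 3 (O, Cl, chain).
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        is_carbonyl = any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(atom).GetAtomicNum() == 8
            for b in atom.GetBonds()
        )
        if not is_carbonyl and atom.GetDegree() > 2:
            return True
    return False


@dataclass
class Registry:
    """The three block lists a library design draws from."""

    amines: list[BuildingBlock] = field(default_factory=list)
    epoxides: list[BuildingBlock] = field(default_factory=list)
    acyl_chlorides: list[BuildingBlock] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self:
            if block.id in seen:
                raise RegistryError(f"duplicate block id {block.id!r}")
            seen.add(block.id)

    def __iter__(self) -> Iterator[BuildingBlock]:
        yield from self.amines
        yield from self.epoxides
        yield from self.acyl_chlorides

    def __len__(self) -> int:
        return len(self.amines) + len(self.epoxides) + len(self.acyl_chlorides)

    def get(self, block_id: str) -> BuildingBlock:
        for block in self:
            if block.id == block_id:
                return block
        raise RegistryError(f"unknown block id {block_id!r}")

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.amines), len(self.epoxides), len(self.acyl_chlorides))


_KIND_TO_LIST = {"amine": "amines", "epoxide": "epoxides", "acyl_chloride": "acyl_chlorides"}


def load_registry(path: str | Path, validate: bool = True) -> Registry:
    """Read a registry from a CSV/TSV file with the standard header.

    Every row is canonicalized, neutralized, and validated; the error message
    for a bad row names the row number and the violated invariant.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    groups: dict[str, list[BuildingBlock]] = {v: [] for v in _KIND_TO_LIST.values()}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in ("id", "kind", "structure", "carbon_count") if c not in header]
        if missing:
            raise RegistryError(f"registry {path} missing columns: {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                block = BuildingBlock.create(
                    id=row["id"].strip(),
                    kind=row["kind"].strip(),
                    structure=row["structure"].strip(),
                    carbon_count=int(row["carbon_count"]),
                    label=(row.get("label") or "").strip(),
                    salt_form=str(row.get("salt_form", "")).strip().lower()
                    in ("1", "true", "yes"),
                )
            except (ValidationError, ValueError) as exc:
                raise RegistryError(f"{path} row {i}: {exc}") from exc
            if validate:
                violations = validate_block(block)
                if violations:
                    raise RegistryError(
                        f"{path} row {i} (id {block.id!r}): " + "; ".join(violations)
                    )
            if block.kind not in _KIND_TO_LIST:
                raise RegistryError(f"{path} row {i}: unknown kind {block.kind!r}")
            groups[_KIND_TO_LIST[block.kind]].append(block)
    return Registry(provenance=str(path), **groups)


def write_registry(registry: Registry, path: str | Path) -> Path:
    """Write a registry back to CSV/TSV (inverse of :func:`load_registry`)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REGISTRY_COLUMNS)
        for block in registry:
            writer.writerow(
                [
                    block.id,
                    block.kind,
                    block.structure,
                    block.carbon_count,
                    block.label,
                    block.salt_form,
                ]
            )
    return path


def write_smiles(registry: Registry, path: str | Path) -> Path:
    """Export all blocks as a two-column SMILES file."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for block in registry:
            fh.write(f"{block.structure}\t{block.id}\n")
    return path


def write_sdf(registry: Registry, path: str | Path) -> Path:
    """Export all blocks as an SDF with id/kind/carbon_count fields."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for block in registry:
            mol = block.mol
            mol.SetProp("_Name", block.id)
            mol.SetProp("kind", block.kind)
            mol.SetProp("carbon_count", str(block.carbon_count))
            if block.label:
                mol.SetProp("label", block.label)
            writer.write(mol)
    finally:
        writer.close()
    return path


def default_registry() -> Registry:
    """The shipped screening registry: 20 amines, 5 epoxides, 5 acyl chlorides.

    Amine 1 is 3-(dimethylamino)-1-propylamine. The epoxides and acyl
    chlorides are the even-carbon C6-C14 series (body tails m and branch
    tails n). Amines 2-20 are curator-provided fixture structures chosen to
    realize the documented headgroup classes (monoamines, hydrazines,
    diamines with varying spacer and tertiary-amine kind, di-secondary
    diamines); amine 11, 1-(2-aminoethyl)pyrrolidine, is pinned by the lead
    product's molecular formula C42H82N2O4. Each entry that is a synthetic
    stand-in says so in its label.
    """
    with resources.as_file(
        resources.files("dblipid").joinpath("data/default_registry.csv")
    ) as p:
        registry = load_registry(p)
    registry.provenance = "dblipid shipped default registry"
    return registry


def subset(registry: Registry, ids: Iterable[str]) -> Registry:
    """Registry restricted to the given block ids (order preserved)."""
    wanted = list(ids)
    blocks = [registry.get(i) for i in wanted]
    groups: dict[str, list[BuildingBlock]] = {v: [] for v in _KIND_TO_LIST.values()}
    for b in blocks:
        groups[_KIND_TO_LIST[b.kind]].append(b)
    return Registry(provenance=f"subset of {registry.provenance}", **groups)
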