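"""Structural descriptors of DB-lipidoids.

Three families of descriptors drive the potency rules:

* **Tail descriptors** — body-tail carbons m, branch-tail carbons n, total
  carbon number TC = m + n, tail symmetry s = n/(m-2) and its deviation
  d = |s - 1|. A symmetry of 1 means the branch tail is as long as the part
  of the body tail distal to the ester; the lead 10/8 combination has s = 1.
* **Headgroup class** — amine counts by substitution order, the kind of
  tertiary amine, and the carbon spacer between the primary and tertiary
  nitrogen. The efficacious class is a diamine with one primary and one
  tertiary amine (dimethylamino, diethylamino or pyrrolidinyl) spaced by two
  or three carbons, and no hydrazine.
* **Metabolite mass** — average molecular mass of the aminoalcohol left
  after full ester hydrolysis, flagged when below 500 Da (small
  non-degradable metabolites clear faster in vivo).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from rdkit import Chem

from . import chem
from .building_blocks import BuildingBlock, Registry
from .enumerator import Lipidoid, degrade, open_epoxide, parse_name
from .errors import ValidationError

EFFICACIOUS_TERTIARY_KINDS = ("dimethylamino", "diethylamino", "pyrrolidinyl")
METABOLITE_MASS_CUTOFF = 500.0  # Da


@dataclass(frozen=True)
class TailDescriptors:
    m: int
    n: int
    total_carbons: int
    symmetry: float
    deviation: float

    @property
    def symmetry_display(self) -> float:
        """Symmetry rounded to one decimal, as conventionally reported."""
        return round(self.symmetry, 1)


def tail_descriptors(target: Lipidoid | tuple[int, int] | str) -> TailDescriptors:
    """Tail descriptors from a lipidoid, an (m, n) pair, or an x-m-n name.

    Symmetry is undefined for m <= 2 (the divisor m - 2 vanishes or turns
    negative); such inputs raise :class:`ValidationError`.
    """
    if isinstance(target, Lipidoid):
        _, m, n = target.xmn
    elif isinstance(target, str):
        _, m, n = parse_name(target)
    else:
        m, n = target
    if m <= 2:
        raise ValidationError(f"symmetry undefined (division by ≤0) for m={m}")
    s = n / (m - 2)
    return TailDescriptors(
        m=m, n=n, total_carbons=m + n, symmetry=s, deviation=abs(s - 1.0)
    )


@dataclass(frozen=True)
class HeadgroupClass:
    n_primary: int
    n_secondary: int
    n_tertiary: int
    tertiary_kind: str  # dimethylamino | diethylamino | pyrrolidinyl | other | none
    spacer: int | None
    has_hydrazine: bool
    is_efficacious_class: bool


def _tertiary_kind(mol: Chem.Mol, n_idx: int) -> str:
    atom = mol.GetAtomWithIdx(n_idx)
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if n_idx in ring and len(ring) == 5:
            others = [mol.GetAtomWithIdx(i) for i in ring if i != n_idx]
            if all(
                a.GetAtomicNum() == 6 and not a.GetIsAromatic() for a in others
            ) and all(
                mol.GetBondBetweenAtoms(ring[i], ring[(i + 1) % len(ring)]).GetBondType()
                == Chem.BondType.SINGLE
                for i in range(len(ring))
            ):
                return "pyrrolidinyl"
    if atom.IsInRing():
        return "other"
    neighbors = [nb for nb in atom.GetNeighbors()]
    methyls = [
        nb for nb in neighbors if nb.GetAtomicNum() == 6 and nb.GetDegree() == 1
    ]
    ethyls = [
        nb
        for nb in neighbors
        if nb.GetAtomicNum() == 6
        and nb.GetDegree() == 2
        and any(
            o.GetAtomicNum() == 6 and o.GetDegree() == 1
            for o in nb.GetNeighbors()
            if o.GetIdx() != n_idx
        )
    ]
    if len(methyls) == 2:
        return "dimethylamino"
    if len(ethyls) == 2:
        return "diethylamino"
    return "other"


def _spacer(mol: Chem.Mol, primary_idx: int, tertiary_idx: int) -> int | None:
    """Carbons strictly between the two nitrogens on the shortest bond path.

    A heteroatom on the path disqualifies the motif (returns None).
    """
    path = Chem.GetShortestPath(mol, primary_idx, tertiary_idx)
    between = path[1:-1]
    if any(mol.GetAtomWithIdx(i).GetAtomicNum() != 6 for i in between):
        return None
    return len(between)


def classify_headgroup(amine: BuildingBlock | Chem.Mol | str) -> HeadgroupClass:
    """Classify an amine headgroup by substructure matching on the free base."""
    if isinstance(amine, BuildingBlock):
        mol = amine.mol
    elif isinstance(amine, str):
        mol = chem.neutralize(chem.mol_from_smiles(amine, "amine"))
    else:
        mol = amine
    primaries = [m[0] for m in mol.GetSubstructMatches(chem.PRIMARY_AMINE)]
    secondaries = [m[0] for m in mol.GetSubstructMatches(chem.SECONDARY_AMINE)]
    tertiaries = [m[0] for m in mol.GetSubstructMatches(chem.TERTIARY_AMINE)]
    has_hydrazine = mol.HasSubstructMatch(chem.HYDRAZINE)

    kind = "none"
    spacer: int | None = None
    if tertiaries:
        kind = _tertiary_kind(mol, tertiaries[0])
        if primaries:
            spacer = _spacer(mol, primaries[0], tertiaries[0])

    efficacious = (
        len(primaries) == 1
        and len(tertiaries) == 1
        and kind in EFFICACIOUS_TERTIARY_KINDS
        and spacer in (2, 3)
        and not has_hydrazine
    )
    return HeadgroupClass(
        n_primary=len(primaries),
        n_secondary=len(secondaries),
        n_tertiary=len(tertiaries),
        tertiary_kind=kind,
        spacer=spacer,
        has_hydrazine=has_hydrazine,
        is_efficacious_class=efficacious,
    )


def metabolite_mass(
    lipidoid: Lipidoid, registry: Registry | None = None
) -> tuple[float, bool]:
    """Average mass (Da) of the aminoalcohol metabolite and its <500 Da flag.

    The metabolite depends only on the amine and body tail: branch tails
    leave as fatty acids on full hydrolysis.
    """
    n_esters = chem.count_esters(lipidoid.mol)
    if n_esters == 0:
        mass = lipidoid.average_mass
    else:
        metabolites = degrade(lipidoid, n_esters)
        mass = metabolites.remnant.average_mass
    return mass, mass < METABOLITE_MASS_CUTOFF


@dataclass(frozen=True)
class DescriptorSet:
    """All descriptors of one lipidoid, ready for the rule engine."""

    name: str
    tails: TailDescriptors
    headgroup: HeadgroupClass
    metabolite_mass: float
    metabolite_under_500: bool


def describe(lipidoid: Lipidoid, registry: Registry) -> DescriptorSet:
    tails = tail_descriptors(lipidoid)
    headgroup = classify_headgroup(registry.get(lipidoid.amine_id))
    mass, under = metabolite_mass(lipidoid)
    return DescriptorSet(
        name=lipidoid.name,
        tails=tails,
        headgroup=headgroup,
        metabolite_mass=mass,
        metabolite_under_500=under,
    )


def describe_library(lipidoids: Sequence[Lipidoid], registry: Registry):
    """Descriptor table for a whole library (one row per lipidoid)."""
    import pandas as pd

    # Metabolite mass depends only on (amine, epoxide); cache those.
    cache: dict[tuple[str, str], float] = {}
    headgroups: dict[str, HeadgroupClass] = {}
    rows = []
    for lip in lipidoids:
        tails = tail_descriptors(lip)
        if lip.amine_id not in headgroups:
            headgroups[lip.amine_id] = classify_headgroup(registry.get(lip.amine_id))
        hg = headgroups[lip.amine_id]
        key = (lip.amine_id, lip.epoxide_id)
        if key not in cache:
            aminoalcohol = open_epoxide(
                registry.get(lip.amine_id), registry.get(lip.epoxide_id), 2
            )
            cache[key] = aminoalcohol.average_mass
        mass = cache[key]
        rows.append(
            {
                "name": lip.name,
                "m": tails.m,
                "n": tails.n,
                "total_carbons": tails.total_carbons,
                "symmetry": tails.symmetry,
                "symmetry_display": tails.symmetry_display,
                "deviation": tails.deviation,
                **{f"hg_{k}": v for k, v in asdict(hg).items()},
                "metabolite_mass": round(mass, 2),
                "metabolite_under_500": mass < METABOLITE_MASS_CUTOFF,
            }
        )
    return pd.DataFrame(rows)
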