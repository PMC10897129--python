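"""Lipid packing parameter P = V/(A·L) from a single minimized conformer.

The packing parameter summarizes molecular shape: V is the van der Waals
volume of the whole molecule, A the cross-section area of the polar head,
and L the average tail length. P ≈ 1 describes a cylinder (bilayer-forming
lipid), P > 1 a cone (favoring inverted, endosome-disrupting phases), and
P < 1 an inverted cone.

This module computes all three quantities from an ETKDG-embedded,
MMFF-minimized conformer and an explicit head/tail atom convention:

* V — union-of-spheres volume on a cubic grid (default 0.2 Å spacing) with
  elemental van der Waals radii;
* A — cross-section of the head atoms projected onto the plane
  perpendicular to the first principal axis of the tail atoms. The default
  area method is the union of the projected van der Waals disks, which
  stays physical for compact heads; a bare-point convex hull is available
  as an alternative (it underestimates small heads, whose few atoms can
  project almost collinearly);
* L — mean over tails of the through-space distance from the tail's
  attachment atom (first tail atom bonded to the head) to its most distant
  terminal carbon.

The default head set is the ionizable-amine region: every nitrogen plus
all heavy atoms within two bonds of one. Ester oxygens can be added via
``include_esters`` and any explicit atom list can be passed instead.
Values from different force fields or head conventions are not comparable
in absolute terms — only orderings computed under identical settings are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import chem
from .errors import DBLipidError, ValidationError

#: DLin-MC3-DMA, the clinical benchmark ionizable lipid (stereo-free).
MC3_SMILES = (
    "CCCCCC=CCC=CCCCCCCCCC(CCCCCCCCC=CCC=CCCCCC)OC(=O)CCCN(C)C"
)

DEFAULT_GRID_SPACING = 0.2  # Å


@dataclass(frozen=True)
class PackingResult:
    P: float
    V: float  # Å^3
    A: float  # Å^2
    L: float  # Å
    seed: int
    shape_class: str  # cylinder-like / cone / inverted-cone

    @staticmethod
    def classify(P: float) -> str:
        if abs(P - 1.0) <= 0.1:
            return "cylinder-like"
        return "cone" if P > 1.0 else "inverted-cone"


def embed_and_minimize(
    structure: str | Chem.Mol, seed: int = 0, max_iters: int = 4000
) -> Chem.Mol:
    """Generate one low-energy 3-D conformer, deterministic per seed.

    ETKDG embedding with a fixed random seed followed by MMFF94 minimization
    (bounded iteration count). Falls back to UFF when MMFF parameters are
    unavailable. Raises after bounded embedding retries.
    """
    mol = (
        chem.mol_from_smiles(structure)
        if isinstance(structure, str)
        else Chem.Mol(structure)
    )
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        for retry in range(1, 6):
            params.randomSeed = int(seed) + 1_000_003 * retry
            params.useRandomCoords = True
            conf_id = AllChem.EmbedMolecule(mol, params)
            if conf_id >= 0:
                break
        else:
            raise DBLipidError("3-D embedding failed after bounded retries")
    try:
        ok = AllChem.MMFFOptimizeMolecule(mol, maxIters=max_iters)
        if ok == -1:
            raise ValueError
    except ValueError:
        AllChem.UFFOptimizeMolecule(mol, maxIters=max_iters)
    return mol


def default_head_atoms(mol: Chem.Mol, include_esters: bool = False) -> list[int]:
    """Ionizable-amine region: nitrogens plus heavy atoms within 2 bonds.

    With ``include_esters`` the ester carbonyl carbon and both oxygens are
    added; the default keeps the head strictly polar-amine, which is what
    separates a branched four-tail lipidoid from a two-tail benchmark in
    the shape ordering.
    """
    head: set[int] = set()
    nitrogens = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 7]
    dmat = Chem.GetDistanceMatrix(mol)
    for n_idx in nitrogens:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() > 1 and dmat[n_idx][atom.GetIdx()] <= 2:
                head.add(atom.GetIdx())
    if include_esters:
        for match in mol.GetSubstructMatches(chem.ESTER):
            head.add(match[0])  # carbonyl C
            head.add(match[1])  # carbonyl O
            head.add(match[2])  # ester O
    if not head:
        raise ValidationError("no head atoms found (no nitrogen present)")
    return sorted(head)


def _tail_definitions(mol: Chem.Mol, head: set[int]) -> list[tuple[int, int]]:
    """(attachment, terminal) heavy-atom index pairs for every tail.

    Tails are the connected components of heavy atoms outside the head set.
    Each component's attachment is its atom bonded to a head atom (smallest
    index on ties) and its terminal is the carbon at maximal bond distance
    from the attachment.
    """
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    tail_atoms = [i for i in heavy if i not in head]
    if not tail_atoms:
        raise ValidationError("tail atom set is empty under this head convention")
    # connected components by BFS over bonds restricted to tail atoms
    remaining = set(tail_atoms)
    components: list[list[int]] = []
    while remaining:
        seed_atom = min(remaining)
        stack, comp = [seed_atom], {seed_atom}
        remaining.discard(seed_atom)
        while stack:
            cur = stack.pop()
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nb.GetIdx()
                if j in remaining:
                    remaining.discard(j)
                    comp.add(j)
                    stack.append(j)
        components.append(sorted(comp))
    dmat = Chem.GetDistanceMatrix(mol)
    tails = []
    for comp in components:
        attachments = [
            i
            for i in comp
            if any(nb.GetIdx() in head for nb in mol.GetAtomWithIdx(i).GetNeighbors())
        ]
        if not attachments:
            continue  # disconnected decoration, not a tail
        attach = min(attachments)
        carbons = [i for i in comp if mol.GetAtomWithIdx(i).GetAtomicNum() == 6]
        if not carbons:
            continue
        terminal = max(carbons, key=lambda i: (dmat[attach][i], -i))
        tails.append((attach, terminal))
    if not tails:
        raise ValidationError("no tails found under this head convention")
    return tails


def vdw_volume(
    coords: np.ndarray, radii: np.ndarray, spacing: float = DEFAULT_GRID_SPACING
) -> float:
    """Union-of-spheres volume (Å³) by grid voxelization."""
    lo = (coords - radii[:, None]).min(axis=0) - spacing
    hi = (coords + radii[:, None]).max(axis=0) + spacing
    nx, ny, nz = (np.ceil((hi - lo) / spacing).astype(int) + 1)
    occupied = np.zeros((nx, ny, nz), dtype=bool)
    axes = [lo[d] + spacing * np.arange((nx, ny, nz)[d]) for d in range(3)]
    for center, r in zip(coords, radii):
        i0 = np.maximum(((center - r - lo) / spacing).astype(int) - 1, 0)
        i1 = np.minimum(
            ((center + r - lo) / spacing).astype(int) + 2, [nx, ny, nz]
        )
        gx = axes[0][i0[0]:i1[0]]
        gy = axes[1][i0[1]:i1[1]]
        gz = axes[2][i0[2]:i1[2]]
        dx2 = (gx - center[0]) ** 2
        dy2 = (gy - center[1]) ** 2
        dz2 = (gz - center[2]) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        ) <= r * r
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return float(occupied.sum()) * spacing**3


def disk_area(
    points: np.ndarray, radii: np.ndarray, spacing: float = DEFAULT_GRID_SPACING
) -> float:
    """Union-of-disks area (Å²) of 2-D points with per-point radii."""
    lo = (points - radii[:, None]).min(axis=0) - spacing
    hi = (points + radii[:, None]).max(axis=0) + spacing
    nx, ny = (np.ceil((hi - lo) / spacing).astype(int) + 1)
    gx = lo[0] + spacing * np.arange(nx)
    gy = lo[1] + spacing * np.arange(ny)
    occupied = np.zeros((nx, ny), dtype=bool)
    for center, r in zip(points, radii):
        occupied |= (
            (gx[:, None] - center[0]) ** 2 + (gy[None, :] - center[1]) ** 2
        ) <= r * r
    return float(occupied.sum()) * spacing**2


def packing_parameter(
    mol: Chem.Mol,
    head_atoms: list[int] | None = None,
    tail_definitions: list[tuple[int, int]] | None = None,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    area_method: str = "vdw_disks",
    seed: int = 0,
) -> PackingResult:
    """Compute P = V/(A·L) from a molecule with a 3-D conformer.

    ``head_atoms``/``tail_definitions`` default to the documented automatic
    convention. The head and tail atom sets must be disjoint and non-empty.
    ``area_method`` is ``"vdw_disks"`` (default) or ``"convex_hull"``.
    """
    if mol.GetNumConformers() == 0:
        raise ValidationError("molecule has no 3-D conformer; embed it first")
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions())
    pt = Chem.GetPeriodicTable()
    heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]

    head = head_atoms if head_atoms is not None else default_head_atoms(mol)
    head_set = set(head)
    tails = (
        tail_definitions
        if tail_definitions is not None
        else _tail_definitions(mol, head_set)
    )
    tail_atoms = {i for pair in tails for i in pair}
    if head_set & tail_atoms:
        raise ValidationError("head and tail atom sets must be disjoint")

    # V over all atoms (hydrogens included if present)
    radii = np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])
    V = vdw_volume(coords, radii, grid_spacing)

    # principal axis of the tail heavy atoms
    tail_heavy = [i for i in heavy_idx if i not in head_set]
    tail_coords = coords[tail_heavy]
    centered = tail_coords - tail_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]

    # A: head atoms projected onto the plane ⊥ axis
    basis = _plane_basis(axis)
    head_sorted = sorted(head_set)
    head_proj = (coords[head_sorted] - coords[head_sorted].mean(axis=0)) @ basis.T
    if area_method == "vdw_disks":
        head_radii = np.array(
            [pt.GetRvdw(mol.GetAtomWithIdx(i).GetAtomicNum()) for i in head_sorted]
        )
        A = disk_area(head_proj, head_radii, grid_spacing)
    elif area_method == "convex_hull":
        from scipy.spatial import ConvexHull, QhullError

        try:
            hull = ConvexHull(head_proj)
        except QhullError as exc:
            raise ValidationError(
                "degenerate head projection (collinear head atoms); "
                "use a larger head set"
            ) from exc
        A = float(hull.volume)  # 2-D hull: volume is the area
    else:
        raise ValidationError(f"unknown area_method {area_method!r}")

    # L: mean 3-D attachment->terminal distance over tails
    lengths = [
        float(np.linalg.norm(coords[t] - coords[a])) for a, t in tails
    ]
    L = float(np.mean(lengths))
    if V <= 0 or A <= 0 or L <= 0:
        raise DBLipidError("non-positive V, A or L")
    P = V / (A * L)
    return PackingResult(
        P=P, V=V, A=A, L=L, seed=seed, shape_class=PackingResult.classify(P)
    )


def _plane_basis(axis: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane perpendicular to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return np.vstack([u, v])


def packing_of_smiles(
    smiles: str, seed: int = 0, grid_spacing: float = DEFAULT_GRID_SPACING
) -> PackingResult:
    """Embed, minimize and evaluate P for a SMILES in one call."""
    mol = embed_and_minimize(smiles, seed=seed)
    return packing_parameter(mol, grid_spacing=grid_spacing, seed=seed)


def median_packing(
    smiles: str, seeds: list[int], grid_spacing: float = DEFAULT_GRID_SPACING
) -> tuple[float, list[PackingResult]]:
    """Median P over several embedding seeds (conformer-noise robust)."""
    results = [packing_of_smiles(smiles, seed=s, grid_spacing=grid_spacing) for s in seeds]
    return float(np.median([r.P for r in results])), results
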