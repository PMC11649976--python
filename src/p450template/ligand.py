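"""Heavy-atom ligand graphs and the functional-group tags the rules need.

Ligands are loaded from SMILES or MOL/SDF blocks into a hydrogen-free graph
(hydrogens are never placed on the Template).  Three annotation sets drive the
interaction rules:

``lactone_ring_atom``
    Atoms of non-rigid ionizable lactone-like rings: non-aromatic rings of
    size >= 6 carrying a cyclic ester (O-C=O) or cyclic imide (C(=O)-N-C(=O))
    motif (thalidomide's glutarimide is the archetype).  Such rings may not
    touch the Rear-wall or the Trigger-residue.  Small rigid cyclic
    carbamates/lactams (e.g. linezolid's oxazolidinone) are deliberately
    excluded: the restriction targets conformationally loose, ionizable rings.

``heme_ligating_heteroatom``
    Nitrogens and thioether sulfurs able to coordinate the heme iron:
    pyridine-type aromatic N, imine/azole N, basic amines (not amides or
    anilines), thioether S.  An inhibitor parks one of these over the Site of
    oxidation.

``candidate_oxidation_site``
    Atoms that CYP chemistry can attack: carbons bearing at least one
    hydrogen, thioether sulfurs (S-oxidation) and nitrogens (N-oxidation /
    N-dealkylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdmolops

__all__ = [
    "LigandGraph",
    "PlanarConformer",
    "LigandError",
    "load_ligand",
    "tag_functional_groups",
    "flatten_conformer",
]


class LigandError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    aromatic: bool
    in_ring: bool
    rigid_block: int
    n_hydrogens: int


@dataclass
class LigandGraph:
    """Hydrogen-free molecular graph with rule-level annotations."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    annotations: dict[str, frozenset[int]] = field(default_factory=dict)
    smiles: str = ""
    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            object.__setattr__(self, "_mol", Chem.MolFromSmiles(self.smiles))
        return self._mol

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def annotation(self, kind: str) -> frozenset[int]:
        return self.annotations.get(kind, frozenset())

    def match(self, smarts: str) -> list[int]:
        """Atom indices of the first SMARTS match (deterministic), [] if none."""
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LigandError(f"bad SMARTS {smarts!r}")
        hits = self.mol.GetSubstructMatches(patt)
        return sorted(hits[0]) if hits else []

    def match_nth(self, smarts: str, n: int) -> list[int]:
        """Atom indices of the n-th SMARTS match (matches sorted), [] if none."""
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LigandError(f"bad SMARTS {smarts!r}")
        hits = sorted(self.mol.GetSubstructMatches(patt))
        if not hits:
            return []
        return sorted(hits[min(n, len(hits) - 1)])

    def match_all(self, smarts: str) -> set[int]:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise LigandError(f"bad SMARTS {smarts!r}")
        return {i for hit in self.mol.GetSubstructMatches(patt) for i in hit}


@dataclass
class PlanarConformer:
    """Flattened coordinates in Ring-size units plus the strain proxy.

    ``strain_proxy`` is the mean squared out-of-plane deviation after a
    least-squares plane fit of the input conformer (0 for inputs that are
    already planar or generated in 2D).  The accept gate (default < 0.1) is
    the configuration slot standing in for a force-field strain check.
    """

    ligand: LigandGraph
    coords: np.ndarray  # (n, 3); z initialised mid-slab
    strain_proxy: float


def _rigid_blocks(mol: Chem.Mol) -> list[int]:
    """Union of fused ring systems and double/triple-bond constrained pairs."""
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ring in mol.GetRingInfo().AtomRings():
        for a, b in zip(ring, ring[1:] + ring[:1]):
            union(a, b)
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() > 1.0:
            union(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    roots = sorted({find(i) for i in range(n)})
    remap = {r: k for k, r in enumerate(roots)}
    return [remap[find(i)] for i in range(n)]


def load_ligand(source: str, name: str = "", fmt: str = "auto") -> LigandGraph:
    """Load a ligand from a SMILES string or a MOL/SDF V2000 block.

    Multi-fragment inputs are rejected: two-ligand complexes are evaluated by
    the bi-molecule module with each partner loaded separately.
    """
    mol = None
    if fmt in ("auto", "smiles") and "\n" not in source.strip():
        mol = Chem.MolFromSmiles(source)
    if mol is None and fmt in ("auto", "mol", "sdf"):
        mol = Chem.MolFromMolBlock(source, removeHs=True)
    if mol is None:
        raise LigandError(f"unparseable ligand structure for {name or source[:40]!r}")
    mol = Chem.RemoveHs(mol)
    frags = rdmolops.GetMolFrags(mol)
    if len(frags) > 1:
        raise LigandError(
            f"{name or 'input'}: {len(frags)} disconnected fragments; load each"
            " ligand of a bi-molecule complex separately"
        )
    Chem.SanitizeMol(mol)
    blocks = _rigid_blocks(mol)
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            rigid_block=blocks[a.GetIdx()],
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in mol.GetBonds()
    ]
    g = LigandGraph(
        name=name or Chem.MolToSmiles(mol),
        atoms=atoms,
        bonds=bonds,
        smiles=Chem.MolToSmiles(mol, canonical=False),
        _mol=mol,
    )
    return tag_functional_groups(g)


_ESTER_IN_RING = "[C;R;$(C=O)][O;R]"
_IMIDE_IN_RING = "[C;R;$(C=O)][N;R][C;R;$(C=O)]"
_HEME_N_S = (
    "[$([n;X2]),$([N;X2]=[#6]),$([N;X3;!$([N][C,S]=[O,S,N]);!$([N]c)]),$([S;X2]([#6])[#6])]"
)


def tag_functional_groups(g: LigandGraph) -> LigandGraph:
    """Annotate lactone-like rings, heme-ligating heteroatoms and candidate
    oxidation sites (idempotent; returns the same object annotated)."""
    mol = g.mol
    lactone: set[int] = set()
    ester = mol.GetSubstructMatches(Chem.MolFromSmarts(_ESTER_IN_RING))
    imide = mol.GetSubstructMatches(Chem.MolFromSmarts(_IMIDE_IN_RING))
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) < 6:
            continue  # small rigid rings are not the ionizable class
        if any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        ring_set = set(ring)
        # the motif must live inside this ring
        for hit in list(ester) + list(imide):
            if set(hit) <= ring_set:
                lactone |= ring_set
                break

    heme = g.match_all(_HEME_N_S)

    candidates: set[int] = set()
    for i, atom in enumerate(g.atoms):
        if atom.element == "C" and atom.n_hydrogens >= 1:
            candidates.add(i)
        elif atom.element == "S" and i in g.match_all("[S;X2]"):
            candidates.add(i)
        elif atom.element == "N":
            candidates.add(i)

    g.annotations["lactone_ring_atom"] = frozenset(lactone)
    g.annotations["heme_ligating_heteroatom"] = frozenset(heme)
    g.annotations["candidate_oxidation_site"] = frozenset(candidates)
    return g


def flatten_conformer(
    g: LigandGraph,
    coords3d: np.ndarray | None = None,
    mid_depth: float = 0.75,
    seed: int = 2024,
) -> PlanarConformer:
    """Flatten a conformer onto the Template plane.

    With ``coords3d`` given (shape (n, 3)), the conformer is projected onto
    its least-squares plane; the strain proxy is the mean squared
    out-of-plane deviation (Ring-size units).  Without coordinates a
    deterministic 2D depiction is generated (strain 0 by construction).
    Coordinates are rescaled so the mean bond length equals the honeycomb
    edge (Ring-size/sqrt(3)); z starts mid-slab and is owned by the
    placement search thereafter.
    """
    n = len(g)
    if coords3d is not None:
        pts = np.asarray(coords3d, dtype=float)
        if pts.shape != (n, 3):
            raise LigandError(f"coords3d shape {pts.shape} != ({n}, 3)")
        center = pts.mean(axis=0)
        q = pts - center
        # plane normal = least singular vector
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        normal = vt[-1]
        off = q @ normal
        flat = q - np.outer(off, normal)
        strain = float(np.mean(off**2))
        basis = vt[:2]
        xy = flat @ basis.T
    else:
        mol = Chem.Mol(g.mol)
        AllChem.Compute2DCoords(mol)
        conf = mol.GetConformer()
        xy = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y] for i in range(n)])
        strain = 0.0

    if g.bonds:
        lengths = [np.linalg.norm(xy[a] - xy[b]) for a, b, _ in g.bonds]
        mean_len = float(np.mean(lengths))
        if mean_len > 0:
            target = 1.0 / np.sqrt(3.0)
            xy = xy * (target / mean_len)
            strain = strain * (target / mean_len) ** 2 if coords3d is not None else strain
    coords = np.column_stack([xy, np.full(n, mid_depth)])
    return PlanarConformer(ligand=g, coords=coords, strain_proxy=strain)
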