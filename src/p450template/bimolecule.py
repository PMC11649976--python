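"""Bi-molecule binding: a pro-metabolized ligand plus a trigger molecule.

A few CYP2J2 phenomena require two non-identical ligands bound at once.  The
molecule sitting at the Site of oxidation is the pro-metabolized molecule;
the second, never-oxidized partner is the trigger molecule.  The two must
share at least one grid vertex in 2D projection, with the trigger molecule
situated behind (a different depth bucket at every shared vertex): overlap
with depth separation near the pro-molecule's fixation regions stabilizes
the complex, whereas overlap at equal depth is a steric clash that competes
with that placement of the pro-molecule.  A trigger molecule reaching into
the Site of oxidation always invalidates the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import TemplateGrid
from .rules import AtomPlacement

__all__ = ["BiMoleculeResult", "evaluate_bimolecule"]

# regions whose overlap counts as supporting the pro-molecule's fixation:
# the Left-end flank and the upper-part / pillar region
DEFAULT_STABILIZING_RINGS = frozenset({"eL", "eR", "L", "M", "R", "S", "K", "J", "O"})


@dataclass
class BiMoleculeResult:
    valid: bool
    overlap_points: frozenset[str]
    effect: str  # STABILIZING | COMPETING | NONE
    notes: str = ""


def evaluate_bimolecule(
    pro: AtomPlacement,
    trig: AtomPlacement,
    t: TemplateGrid,
    stabilizing_rings: frozenset[str] = DEFAULT_STABILIZING_RINGS,
) -> BiMoleculeResult:
    """Classify a two-ligand co-placement.

    ``pro`` and ``trig`` must be placements of different ligands on the same
    template; the roles are not interchangeable (the trigger molecule is the
    one barred from the Site of oxidation).
    """
    if pro.ligand.name == trig.ligand.name:
        raise ValueError("pro-metabolized and trigger molecule must be different ligands")

    trig_at_site = trig.atoms_at(t.site_of_oxidation)
    if trig_at_site:
        return BiMoleculeResult(
            valid=False,
            overlap_points=frozenset(),
            effect="COMPETING",
            notes="trigger molecule occupies the Site of oxidation",
        )

    pro_by_vertex: dict[str, set] = {}
    for i, (v, d) in pro.assignment.items():
        pro_by_vertex.setdefault(v, set()).add(d)
    shared: set[str] = set()
    clash: set[str] = set()
    for i, (v, d) in trig.assignment.items():
        if v in pro_by_vertex:
            shared.add(v)
            if d in pro_by_vertex[v]:
                clash.add(v)

    if not shared:
        return BiMoleculeResult(
            valid=False,
            overlap_points=frozenset(),
            effect="NONE",
            notes="disjoint footprints: no overlapping point on the Template",
        )
    if clash:
        return BiMoleculeResult(
            valid=False,
            overlap_points=frozenset(shared),
            effect="COMPETING",
            notes=f"equal-depth clash at {sorted(clash)}: competes with this placement",
        )
    stab_vertices = {v for r in stabilizing_rings if r in t.rings for v in t.rings[r]}
    if shared & stab_vertices:
        return BiMoleculeResult(
            valid=True,
            overlap_points=frozenset(shared),
            effect="STABILIZING",
            notes="trigger molecule sits behind the pro-molecule's fixation regions",
        )
    return BiMoleculeResult(
        valid=True,
        overlap_points=frozenset(shared),
        effect="NONE",
        notes="overlap outside the stabilizing regions",
    )
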