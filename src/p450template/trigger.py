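"""Trigger-residue simulation.

After a ligand descends near the Site of oxidation, a mobile residue appears
from behind the Rear-wall in the eB region (the right end of the grid) and
migrates leftward ring by ring along a rear-side path, at most to Ring B and
never into Ring A.  It halts at the first ring where it meets a non-lactone
ligand atom, fastening the ligand there; unfastened ligands are not
metabolized.  The residue is drawn as a pillar of 0.5 x 0.5 x 3 Ring-size
diameters; for long bent ligands it additionally props the upper part that
sits over the Rings K/J (and O) region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import TemplateGrid
from .rules import AtomPlacement

__all__ = ["TriggerState", "simulate_trigger", "pillar_support"]


@dataclass(frozen=True)
class TriggerState:
    final_ring: str | None
    contacted_atoms: frozenset[int]
    fastened: bool
    pillar_support: bool
    path_taken: tuple[str, ...]


def pillar_support(p: AtomPlacement, t: TemplateGrid) -> bool:
    """True iff ligand atoms occupy the support region above the residue's
    approach position (Rings K/J, optionally O, per the template data)."""
    region = {v for r in t.pillar_rings for v in t.rings.get(r, ())}
    return bool(p.atoms_at(region))


def simulate_trigger(p: AtomPlacement, t: TemplateGrid) -> TriggerState:
    """Walk the residue along ``t.trigger_path`` (rightmost ring first) and
    stop at the first ring holding a non-lactone ligand atom.

    Contact is bucket-agnostic: a facial-side atom in Ring B still stops the
    residue.  Lactone-tagged atoms are transparent to it (the rule engine
    separately rejects placements whose lactone rings would be contacted).
    Deterministic: equal placements give equal states.
    """
    lactone = p.ligand.annotation("lactone_ring_atom")
    path_taken: list[str] = []
    final_ring: str | None = None
    contacted: frozenset[int] = frozenset()
    fastened = False
    for ring in t.trigger_path:
        if ring == "A":  # defensive: the residue never enters Ring A
            break
        path_taken.append(ring)
        ring_atoms = p.atoms_at(t.rings.get(ring, ())) - lactone
        final_ring = ring
        if ring_atoms:
            contacted = frozenset(ring_atoms)
            fastened = True
            break
    return TriggerState(
        final_ring=final_ring,
        contacted_atoms=contacted,
        fastened=fastened,
        pillar_support=pillar_support(p, t),
        path_taken=tuple(path_taken),
    )
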