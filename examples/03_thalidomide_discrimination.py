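"""Minimal bottom-region occupancy: why CYP2J2 oxidizes
R-5-hydroxythalidomide but not R-/S-thalidomide.

All three placements satisfy the plural Rear-wall contact, Left-end contact
and Site occupancy -- the discriminating feature is occupancy right of the
Rings A/B junction, where the Trigger-residue can reach and fasten the
ligand.
"""

from p450template import evaluate_placement, load_canonical_template, simulate_trigger
from p450template.fixtures import load_fixture_set

t = load_canonical_template()
records = {(r.ligand, r.reaction): r for r in load_fixture_set()}

for key in [
    ("R-5-Hydroxythalidomide", "aromatic oxidation"),
    ("R-Thalidomide", "ring oxidation"),
    ("S-Thalidomide", "ring oxidation"),
]:
    rec = records[key]
    p = rec.realize(t)
    state = simulate_trigger(p, t)
    v = evaluate_placement(p, t, state)
    failed = sorted(v.failed_rules() & {"R_RING_B", "R_TRIGGER"})
    print(f"{rec.ligand:25s} {rec.notation:22s} -> {v.category.value:15s}"
          f" fastened={state.fastened}  failed={failed or '-'}")

print()
print("The thalidomide placements never touch Ring B, the residue walks its")
print("whole path without contact, and the unfastened ligand is a poor")
print("substrate despite sitting over the Site of oxidation.")
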