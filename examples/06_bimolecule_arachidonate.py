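"""Bi-molecule binding: 7-deaDox modulates arachidonate epoxidation.

7-deaDox (de-glycosylated doxorubicin derivative) raises the rate of
arachidonate 5,6-epoxidation and lowers the 14,15-epoxidation.  On the
Template this is a depth story: for the 5,6 placement the two footprints
overlap with 7-deaDox situated behind (rear of) the arachidonate upper part
(stabilizing); for the 14,15 placement both want the same rear-side space
(steric competition).
"""

from p450template import evaluate_bimolecule, load_canonical_template
from p450template.fixtures import load_fixture_set

t = load_canonical_template()
records = {(r.ligand, r.reaction): r for r in load_fixture_set()}
dea = records[("7-deaDox", "trigger molecule")].realize(t)

for reaction in ["5,6-epoxidation", "14,15-epoxidation"]:
    ara = records[("Arachidonic acid", reaction)].realize(t)
    r = evaluate_bimolecule(ara, dea, t)
    print(f"arachidonate {reaction:18s} + 7-deaDox -> valid={r.valid!s:5s}"
          f" effect={r.effect:11s} overlap={sorted(r.overlap_points)}")

print()
print("STABILIZING = shared grid vertices with depth separation near the")
print("fixation regions; COMPETING = an equal-depth clash at a shared vertex.")
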