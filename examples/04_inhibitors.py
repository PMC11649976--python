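"""Inhibitor recognition: a heme-ligating nitrogen parked over the Site of
oxidation blocks catalysis instead of feeding it.
"""

from p450template import evaluate_placement, load_canonical_template, simulate_trigger
from p450template.fixtures import load_fixture_set

t = load_canonical_template()
records = {(r.ligand, r.reaction): r for r in load_fixture_set()}

for key, what in [
    (("Danazol", "oxazole oxidation"), "isoxazole N"),
    (("Norfloxacin", "inhibition"), "piperazine terminal N"),
    (("Doxorubicin", "inhibition"), "sugar amino N"),
]:
    rec = records[key]
    g = rec.load()
    p = rec.realize(t)
    v = evaluate_placement(p, t, simulate_trigger(p, t))
    heme = sorted(g.annotation("heme_ligating_heteroatom"))
    at_site = [i for i in heme if p.assignment[i][0] in t.site_of_oxidation]
    print(f"{rec.ligand:12s} -> {v.category.value:10s}  {what}"
          f" (atom {at_site}) at position {[p.assignment[i][0] for i in at_site]}")

print()
print("Each verdict is INHIBITOR because the nitrogen occupying positions")
print("2-4 coordinates the heme iron and nothing oxidizable shares the site.")
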