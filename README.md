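# p450template

Rule-based prediction of human **CYP2J2** ligand metabolism on a fused
hexagonal-grid **Template** of the enzyme's active site.

CYP2J2 is the dominant cytochrome P450 of the human heart and intestine; it
epoxidizes arachidonic acid and clears drugs as diverse as astemizole,
terfenadine and albendazole.  Instead of 3D docking, the Template approach
abstracts the ligand-accessible space into a 2D honeycomb assembled from
known substrates: hexagon cells (Rings A–U plus edge extensions), numbered
corner Positions where heavy atoms sit, and named regions — the Site of
oxidation (Positions 2–4), the Shelf, the Left-end border, the Entrance,
and a slab of allowable depth (the Width-gauge, 1.5 Ring-size) between the
Facial- and Rear-walls.  A mobile **Trigger-residue** emerges near Ring eB,
migrates leftward at most to Ring B (never Ring A) and must fasten the
ligand for catalysis to start — which is why CYP2J2 substrates need Ring-B
occupancy, and why thalidomide, which cannot reach it, is not turned over.

This package makes that model executable:

* a frozen canonical CYP2J2 grid (`data/cyp2j2.yaml`) with loader,
  validator and round-trip serialization;
* a parser for the hyphen-linked placement notation (`A(B)-E(G)-eE-F-L`);
* an RDKit-backed ligand model tagging lactone-like rings, heme-ligating
  heteroatoms and candidate oxidation sites;
* a rule engine producing a `Verdict` (GOOD_SUBSTRATE / POOR_SUBSTRATE /
  INHIBITOR / NON_LIGAND) with per-rule evidence and predicted sites of
  oxidation;
* the Trigger-residue simulation and pillar-support test;
* an exhaustive graph-to-lattice placement search with a brute-force
  oracle used to cross-check it;
* a bi-molecule evaluator for pro-metabolized + trigger-molecule
  co-placements;
* the published worked placements as machine-readable fixtures, with a
  concordance suite.

See `docs/methods.md` for the model, transcription conventions and
limitations.

## A worked example

```python
from p450template import (
    evaluate_placement, load_canonical_template, simulate_trigger,
)
from p450template.fixtures import load_fixture_set

t = load_canonical_template()
records = {(r.ligand, r.reaction): r for r in load_fixture_set()}

for key in [("R-5-Hydroxythalidomide", "aromatic oxidation"),
            ("S-Thalidomide", "ring oxidation")]:
    p = records[key].realize(t)
    state = simulate_trigger(p, t)
    v = evaluate_placement(p, t, state)
    print(key[0], "->", v.category.value, "fastened:", state.fastened)
```

prints

```
R-5-Hydroxythalidomide -> GOOD_SUBSTRATE fastened: True
S-Thalidomide -> POOR_SUBSTRATE fastened: False
```

R-5-hydroxythalidomide occupies the right side of the Rings A/B junction,
so the Trigger-residue fastens it and every mandatory rule passes; the
thalidomide placement never reaches Ring B, the residue walks its whole
path without contact, and the molecule is classified a poor substrate even
though it sits over the Site of oxidation.  The `examples/` directory has
one short script per capability (geometry tour, notation, inhibitor
recognition, magnolin regioselectivity scores, the arachidonate/7-deaDox
bi-molecule effects, and the enumeration/oracle cross-check), each printing
what it computes and what the numbers mean.

A thin CLI wraps the same library:

```bash
p450template fixtures                 # run the packaged concordance suite
p450template predict --ligand "CCO" --max-placements 1000
p450template validate --ligand <SMILES> --placement "A(B)-E-F-eL-M"
```

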