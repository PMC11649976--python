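# Methods

`p450template` implements the fused hexagonal-grid Template model of the
human CYP2J2 active site as executable code: a frozen canonical geometry, a
parser for the field's placement notation, a discrete rule engine for ligand
interaction criteria, a Trigger-residue simulation, a constrained
graph-to-lattice placement search with a brute-force oracle, and a
two-ligand (bi-molecule) evaluator.  This note records the model, the
transcription conventions, the numerical choices, and what the packaged
tests do and do not establish.

## The model

A Template is a 2D abstraction of a CYP isoform's ligand-accessible space,
assembled in the original work by overlaying the flattened structures of
known substrates so that their experimentally observed sites of metabolism
coincide.  The result for CYP2J2 is a fused honeycomb of hexagonal cells
("Rings" A–U plus edge extensions eB…eU) whose corners ("Positions" 1–54,
plus primed border anchors) carry all the model's semantics:

* **Width-gauge** — ligands must fit in a slab of 1.5 Ring-size between two
  parallel walls (Facial, Rear).  Depth is modelled as three discrete
  buckets (facial / mid / rear); "wall contact" means occupying the facial
  or rear bucket.  One Ring-size is the distance across a hexagon's flats;
  the lattice edge is therefore `1/sqrt(3)` Ring-size.
* **Site of oxidation** — positions 2–4 at the bottom of the grid, where
  the heme-bound oxygen attacks from the rear side.
* **Shelf** — a plateau between position 10 (the Rings A/E junction) and
  the Left-end; nothing may sit beneath it, and contacts on its top edge
  stabilize a placement.
* **Left-end** — the left border polyline (up to the left side of Ring S,
  anchor 54'); good substrates are fixed against it.
* **Entrance** — the line between anchors 49' and 54' at the top; ligands
  descend from it without changing conformation.
* **Trigger-residue** — a mobile element that appears from behind the
  Rear-wall in the eB region, migrates leftward ring-by-ring (path
  eB → C → B, never into Ring A) and halts at the first ring holding a
  non-lactone ligand atom, fastening the ligand.  It is drawn as a pillar
  of 0.5 × 0.5 × 3 Ring-size and additionally props the upper parts of long
  bent ligands over the Rings K/J (and O) region.

A ligand placement assigns every heavy atom (hydrogens are never placed) a
grid vertex and a depth bucket.  Classification is rule-based:

| rule | content | role |
|---|---|---|
| R_WIDTH | every atom inside the slab | gate; failure ⇒ NON_LIGAND |
| R_PLURAL_REAR | ≥ 2 non-lactone atoms in the rear bucket | gate |
| R_RING_B | ring occupancy includes Ring B | gate |
| R_TRIGGER | the residue fastened the ligand | gate |
| R_SITE | ≥ 1 oxidizable atom on positions 2–4 | gate |
| R_LACTONE | no lactone-like ring atom rear or trigger-contacted | gate |
| R_LEFT_END | ≥ 1 atom on the Left-end polyline | gate (relaxable) |
| R_DESCENT | vertical descent not blocked by the Shelf pocket | gate (relaxable) |
| R_SHELF | no atom under the Shelf | gate; edge contact stabilizes |
| R_FACIAL | facial contact | stabilizing only |

A placement passing every gate with a non-empty predicted site is a
GOOD_SUBSTRATE; an admissible placement failing a gate is a POOR_SUBSTRATE.
A heme-ligating **nitrogen** occupying the site region, with no other
oxidizable atom sharing it, yields INHIBITOR.  Sulfur is deliberately
excluded from this precedence even though thioethers are tagged as
potential ligators: a thioether parked over the site undergoes S-oxidation
(albendazole, thioridazine) rather than blocking the enzyme, whereas the
corpus inhibitors (danazol, norfloxacin, doxorubicin) all act through a
nitrogen.  For N-dealkylation reactions the attacked atom is the α-carbon,
so the amine nitrogen itself stays outside the site region.

Ring-B occupancy and Trigger fastening are two facets of one mechanism (the
residue reaches at most Ring B); the ablation switch used as a negative
control in the test suite therefore disables both together.

The placement score is a weighted contact count (defaults: rear 2, facial
1, shelf edge 1, left-end 2, site 3, pillar bonus 1).  The weights are
model constants chosen once, not fitted: the source material ranks
placements only qualitatively, and the packaged check is ordinal (the
magnolin M-2 sitting must outscore M-1).

## Transcription of the canonical grid

No coordinate list for the grid exists in print; only a drawing does.  The
packaged `data/cyp2j2.yaml` is a transcription frozen as canonical data and
regenerable by `scripts/build_canonical_grid.py`, which encodes the layout
convention:

* pointy-top hexagons in six rows (A–C / eE,E,D,H,I,eC / eL,F,G,K,J,eJ /
  M,L,N,O,eO / eR,R,Q,P,eP / S,T,U,eU), each cell a full 6-cycle;
* positions numbered 1–54 in a bottom-up, left-to-right zigzag sweep that
  skips six primed border anchors.  The textual anchors all hold: the site
  spans positions 2–4 with 3 on the A/B junction, position 10 is the A/E
  junction and the Shelf's right boundary, 49' lies directly above 49, 54'
  on the left side of Ring S, and 11' is the Shelf/Left-end corner;
* extension cells' outer corners are labelled `eX1`, `eX2`, …

Two details could not be made simultaneously consistent with every textual
aside and are recorded as transcription artifacts: the vertex pair right of
the A/B junction is numbered (3, 11) here where the original drawing
apparently reads (3, 8); and a handful of ring adjacencies implied by
hyphen-linked paths (e.g. L–K, O–Q) are one lattice step apart rather than
edge-sharing.  Neither affects any rule, because rules read regions and
ring membership, not adjacency of consecutive notation labels — and the
placement realizer bridges one-step gaps within the off-corner tolerance.
The eB and eC cells carry real, occupiable vertices (a published placement
occupies eB), with eB doubling as the Trigger origin region.

## Ligand model

Ligands load from SMILES or MOL/SDF through RDKit into a hydrogen-free
graph.  Three annotation sets drive the rules:

* **lactone-like rings**: non-aromatic rings of size ≥ 6 containing a
  cyclic ester or cyclic imide motif.  This operationalizes "non-rigid
  ionizable lactone rings": thalidomide's glutarimide is tagged, while
  small rigid cyclic carbamates (linezolid's oxazolidinone,
  chlorzoxazone's benzoxazolone) are not — they demonstrably sit against
  the Rear-wall in the worked placements.
* **heme-ligating heteroatoms**: pyridine-type and imine nitrogens, basic
  amines (excluding amides and aniline-type N), thioether sulfur.
* **candidate oxidation sites**: carbons bearing H, thioether S, nitrogens.

Conformer flattening projects 3D coordinates onto their least-squares
plane; the strain proxy is the mean squared out-of-plane deviation in
Ring-size units, with the acceptance gate (default < 0.1) occupying the
configuration slot of the original force-field strain criterion.  The
proxy is a planarity measure, not an energy; it gates obviously
non-flattenable conformers and nothing more.

## Realizing published placements (fixtures)

The worked placements exist as drawings plus prose.  Each fixture record
stores the printed ring path, a transcribed SMILES, and a small set of
atom-level anchors ("pins") encoding the described contacts (the oxidized
atom at position 3 rear; the described Left-end / Shelf contacts; rear and
facial depth tags).  `realize_placement` deterministically extends the
pins to all atoms: the ligand's backbone (longest bond path from the
anchor pin) is mapped monotonically onto the ring sequence, every other
atom inherits an expected ring from its nearest backbone atom, and a
greedy breadth-first assignment places each atom within the off-corner
bond tolerance (≤ 2 lattice steps per bond, shared vertices allowed) while
marching toward its expected ring, spreading occupancy, respecting the
reachability of every pin, and keeping filler atoms off scoring-sensitive
vertices and off junction corners of rings the path does not name.  A
repair pass then removes any residual bond stretch.  The procedure is
deterministic, and the suite asserts that every realized fixture satisfies
the placement invariants.

Fixture SMILES are transcribed from the ligand names; two probe substrates
(the luciferin-type probe and BnXP) have undisclosed structures, carry
best-effort stand-ins flagged `structure_approx`, and are excluded from
site-level assertions.

## Placement search

The embedding model is discrete: atoms → vertices (injective), bonds →
lattice edges, depth buckets free per atom.  `enumerate_embeddings` is a
depth-first search over a canonical atom order (largest rigid block first,
then breadth-first); `brute_force_oracle` is a deliberately naive
enumeration in plain atom-index order.  Both filter through the same
admissibility predicate but share no traversal logic, so their set
equality on small graphs is a meaningful cross-check; it is exercised over
a generated family of ≥ 50 chains, rings and ring-plus-tail graphs of ≤ 6
atoms on a trimmed 4-ring template (counts are exact: one atom gives
|V|·3 placements, two atoms 2·|E|·3², benzene exactly the hexagon cells).
With `allow_off_corner` the bond constraint relaxes to ≤ `tolerance`
lattice steps or a shared vertex, which is how 5-rings and fused systems
that do not tile the honeycomb are accommodated.  `predict` enumerates,
simulates the Trigger, evaluates and ranks by score plus a category bonus
so functional placements always lead; all top-tier predicted sites are
reported together rather than forcing a single one.

## Bi-molecule binding

The model requires the two partners to share at least one 2D vertex while
the trigger molecule is "situated behind".  These two statements are
reconciled as: overlap with a different depth bucket at every shared
vertex.  Depth-separated overlap near the fixation regions (Left-end
flank eL/eR/L/M/R/S and the pillar region K/J/O, configurable) is
STABILIZING; an equal-depth clash at any shared vertex means the trigger
molecule competes with that placement of the pro-metabolized molecule; a
trigger molecule reaching positions 2–4 always invalidates the complex.
This reading reproduces both arachidonate outcomes (7-deaDox stabilizes
the 5,6-epoxidation sitting and competes with the 14,15 one).

## Problem sizes and determinism

The packaged suite evaluates 35 worked placements with expectations (28
with site-level pins), runs the Ring-B ablation control, and checks oracle
equivalence over 60 generated graphs; everything completes in about a
minute on one CPU.  All procedures are deterministic given the seed:
generated toy ligands, search order, realization, and rule evaluation have
no hidden randomness, and hypothesis-based property tests run
derandomized.

## Limitations

* The grid coordinates and position numbering are transcription-by-
  convention; any check that depended on exact figure coordinates rather
  than the textual anchors would not be meaningful here.
* Fixture realizations are anchored by a few pins per ligand; atom-level
  detail away from the pins is a deterministic reconstruction, not figure
  data.  Category and pinned-site outcomes are therefore the meaningful
  test currency, and passing them shows the rule engine reproduces the
  published reasoning — not that it predicts metabolism of arbitrary new
  chemicals.
* Exhaustive search is practical for small ligands and trimmed templates;
  drug-sized molecules need the off-corner tolerance and placement caps,
  and `predict` on them is a screening heuristic, not an exhaustive
  verdict.
* Kinetics (rates, Km/kcat, inhibition constants) and electronic
  reactivity are out of scope; the score is an ordinal stability measure.
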