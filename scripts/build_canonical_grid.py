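"""Regenerate the packaged canonical CYP2J2 grid (src/p450template/data/cyp2j2.yaml).

The CYP2J2 Template is published as a drawing; no coordinate list exists in print.
This script encodes the documented transcription convention (see docs/methods.md)
and freezes it as YAML.  The emitted file is the canonical datum: the package never
regenerates it at run time.

Layout convention
-----------------
Pointy-top hexagon cells, Ring-size (distance across flats) = 1.0, edge length
a = 1/sqrt(3).  Cell rows bottom-up; row r centres sit at y = 1.5*a*r; within a
row, centres are 1.0 apart in x.  Vertex keys are (2x, L) with L the height in
units of a/2.  Numbered positions 1..54 sweep zigzag vertex rows bottom-up,
left-to-right, skipping six primed border anchors (11', 27', 36', 44', 49', 51',
54' -- 11' belongs to the eE cell and is not part of the 54-count sweep).
"""

from __future__ import annotations

import math
import sys
from pathlib import Path

import yaml

A = 1.0 / math.sqrt(3.0)

# cell label -> (centre x, cell row)
CELLS = {
    # bottom row: site of oxidation sits under A/B; eB is the trigger origin space
    "A": (0.0, 0), "B": (1.0, 0), "C": (2.0, 0), "eB": (3.0, 0),
    "eE": (-1.5, 1), "E": (-0.5, 1), "D": (0.5, 1), "H": (1.5, 1), "I": (2.5, 1), "eC": (3.5, 1),
    "eL": (-2.0, 2), "F": (-1.0, 2), "G": (0.0, 2), "K": (1.0, 2), "J": (2.0, 2), "eJ": (3.0, 2),
    "M": (-1.5, 3), "L": (-0.5, 3), "N": (0.5, 3), "O": (1.5, 3), "eO": (2.5, 3),
    "eR": (-2.0, 4), "R": (-1.0, 4), "Q": (0.0, 4), "P": (1.0, 4), "eP": (2.0, 4),
    "S": (-1.5, 5), "T": (-0.5, 5), "U": (0.5, 5), "eU": (1.5, 5),
}

CORE = [c for c in CELLS if not c.startswith("e")]
EXT = [c for c in CELLS if c.startswith("e")]

PRIMED = {  # key -> label; border anchors excluded from the 1..54 sweep
    (-4, 8): "27'",
    (-4, 10): "36'",
    (-4, 14): "44'",
    (-3, 17): "51'",
    (-4, 16): "54'",
    (2, 16): "49'",
}
EE_PRIME = ((-4, 2), "11'")  # Left-end/Shelf anchor on the eE cell


def corners(label):
    """Six corner keys, clockwise from the upper-left shoulder."""
    cx, r = CELLS[label]
    x2 = int(round(2 * cx))
    lb = 3 * r  # centre height in a/2 units is 3r
    return [
        (x2 - 1, lb + 1),  # upper-left shoulder
        (x2, lb + 2),      # top tip
        (x2 + 1, lb + 1),  # upper-right shoulder
        (x2 + 1, lb - 1),  # lower-right shoulder
        (x2, lb - 2),      # bottom tip
        (x2 - 1, lb - 1),  # lower-left shoulder
    ]


def xy(key):
    return key[0] / 2.0, key[1] * A / 2.0


def main(out_path: Path) -> None:
    core_keys = sorted({k for c in CORE for k in corners(c)})
    assert len(core_keys) == 60, len(core_keys)

    # zigzag vertex rows: pairs of adjacent height levels
    row_levels = [(-2, -1), (1, 2), (4, 5), (7, 8), (10, 11), (13, 14), (16, 17)]
    labels: dict[tuple, str] = dict(PRIMED)
    labels[EE_PRIME[0]] = EE_PRIME[1]
    n = 0
    for levels in row_levels:
        row = sorted([k for k in core_keys if k[1] in levels])
        for key in row:
            if key in PRIMED:
                continue
            n += 1
            labels[key] = str(n)
    assert n == 54, n
    # textual anchors of the published description
    assert labels[(0, -2)] == "2" and labels[(1, -1)] == "3" and labels[(2, -2)] == "4"
    assert labels[(0, 2)] == "10"       # junction of Rings A and E, Shelf right boundary
    assert labels[(2, 14)] == "49"      # 49' sits directly above 49

    # extension-cell outer corners
    for ext in sorted(EXT):
        i = 0
        for key in corners(ext):
            if key not in labels:
                i += 1
                labels[key] = f"{ext}{i}"

    rings = {c: [labels[k] for k in corners(c)] for c in CELLS}

    site = ["2", "3", "4"]
    shelf_edge = ["11'", "8", "10"]
    under_shelf = [labels[(-3, 1)]]  # eE bottom tip, beneath the plateau
    # Left-end border polyline, bottom-up: the outer left column of the grid
    left_end = [labels[k] for k in [
        (-4, 2), (-4, 4), (-5, 5), (-5, 7), (-4, 8), (-4, 10),
        (-5, 11), (-5, 13), (-4, 14), (-4, 16),
    ]]
    entrance = ["49'", "54'"]

    features: dict[str, list] = {}

    def add(lbl, feat):
        features.setdefault(lbl, []).append(feat)

    for s in site:
        add(s, "in_site_of_oxidation")
    for s in shelf_edge:
        add(s, "on_shelf_edge")
    for s in under_shelf:
        add(s, "under_shelf")
    for s in left_end:
        add(s, "on_left_end")
    for s in entrance:
        add(s, "entrance_anchor")

    vertices = []
    for key, lbl in sorted(labels.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        x, y = xy(key)
        vertices.append({
            "label": lbl,
            "x": round(x, 9),
            "y": round(y, 9),
            "features": sorted(features.get(lbl, [])),
        })

    doc = {
        "name": "CYP2J2",
        "width_gauge": 1.5,
        "facial_depth": 0.0,
        "rear_depth": 1.5,
        "vertices": vertices,
        "rings": {c: rings[c] for c in sorted(rings)},
        "site_of_oxidation": site,
        "shelf": {"edge": shelf_edge, "forbidden": under_shelf},
        "left_end": left_end,
        "entrance": entrance,
        "trigger_path": ["eB", "C", "B"],
        "trigger_pillar": [0.5, 0.5, 3.0],
        "pillar_rings": ["K", "J", "O"],
        "heme_access": "rear",
    }
    out_path.write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))
    print(f"wrote {out_path} ({len(vertices)} vertices, {len(rings)} rings)")


if __name__ == "__main__":
    out = Path(sys.argv[1]) if len(sys.argv) > 1 else (
        Path(__file__).resolve().parents[1] / "src" / "p450template" / "data" / "cyp2j2.yaml"
    )
    main(out)
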