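"""Parsing the hyphen-linked ring-path notation.

Placements are written as hyphen-linked ring labels with bracketed branches
and slash alternatives; this shows parsing, canonical serialization and the
derived ring occupancy.
"""

from p450template import parse_placement, rings_occupied, serialize_placement

for text in [
    "A(B)-E(G)-eE-F-L",              # a small good substrate
    "B-A-E-F(G-H-K-J-O)-eL-L",       # a long branch sweeping the upper rings
    "A-E(D/eE)-F(eL)-L",             # slash = either ring is acceptable
]:
    p = parse_placement(text)
    print(f"raw:        {text}")
    print(f"canonical:  {serialize_placement(p)}")
    print(f"main path:  {p.main_labels()}")
    print(f"occupied:   {sorted(rings_occupied(p))}")
    print(f"weak alts:  {sorted(p.alternative_labels())}")
    print()

print("`occupied` is the union of main and branch labels; slash alternatives")
print("count as occupied but are flagged weak for rule evaluation.")
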