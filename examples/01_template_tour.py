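"""Tour of the canonical CYP2J2 Template grid.

Loads the packaged geometry and prints its headline constants: the
Width-gauge (allowable slab depth), the numbered Positions, and the named
regions every placement rule refers to.
"""

from p450template import load_canonical_template, region_membership, ring_vertices

t = load_canonical_template()

print(f"Template:            {t.name}")
print(f"Width-gauge:         {t.width_gauge} Ring-size  (Facial-wall z={t.facial_depth}, Rear-wall z={t.rear_depth})")
print(f"Rings:               {len(t.rings)} ({sum(1 for r in t.rings if not r.startswith('e'))} core + extensions)")
print(f"Numbered positions:  {len(t.numbered_positions())}")
print(f"Site of oxidation:   positions {sorted(t.site_of_oxidation, key=int)}")
print(f"Shelf top edge:      {t.shelf_edge}  (right boundary = position 10, the A/E junction)")
print(f"Left-end polyline:   {t.left_end}")
print(f"Entrance anchors:    {t.entrance}")
print(f"Trigger path:        {' -> '.join(t.trigger_path)}  (right to left, never Ring A)")
print(f"Trigger pillar:      {t.trigger_pillar} Ring-size (w, d, height)")
print()
print(f"Ring A cycle:        {ring_vertices(t, 'A')}")
print(f"Ring B cycle:        {ring_vertices(t, 'B')}")
print(f"Features of '3':     {sorted(region_membership(t, '3'))}")
print()
print("Vertex 3 sits on the A/B junction inside the Site of oxidation: an")
print("oxidizable atom there simultaneously satisfies the Site rule and the")
print("Ring-B occupancy that lets the Trigger-residue fasten the ligand.")
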