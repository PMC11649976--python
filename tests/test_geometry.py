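"""Canonical grid geometry: invariants, queries, round-trip."""

import math

import pytest
import yaml

from p450template.geometry import (
    EDGE_LENGTH,
    TemplateError,
    load_template,
    region_membership,
    ring_vertices,
    serialize_template,
    trim_template,
    validate_template,
)


def test_canonical_constants(template):
    assert template.name == "CYP2J2"
    assert template.width_gauge == 1.5
    assert template.rear_depth - template.facial_depth == template.width_gauge
    assert len(template.numbered_positions()) == 54
    assert template.site_of_oxidation == {"2", "3", "4"}
    assert template.trigger_pillar == (0.5, 0.5, 3.0)
    assert template.heme_access == "rear"
    # 21 core rings A..U plus 9 edge extensions
    assert sum(1 for r in template.rings if not r.startswith("e")) == 21
    assert sorted(r for r in template.rings if r.startswith("e")) == [
        "eB", "eC", "eE", "eJ", "eL", "eO", "eP", "eR", "eU",
    ]


def test_canonical_is_valid(template):
    assert validate_template(template) == []


def test_every_ring_is_a_hexagon(template):
    for ring in template.rings:
        cycle = ring_vertices(template, ring)
        assert len(cycle) == 6
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            va, vb = template.vertices[a], template.vertices[b]
            assert math.hypot(va.x - vb.x, va.y - vb.y) == pytest.approx(
                EDGE_LENGTH, abs=1e-9
            )


def test_ring_lookup_errors(template):
    with pytest.raises(KeyError):
        ring_vertices(template, "Z")
    with pytest.raises(KeyError):
        region_membership(template, "999")


def test_named_regions(template):
    assert "in_site_of_oxidation" in region_membership(template, "3")
    assert "on_shelf_edge" in region_membership(template, "10")
    assert "entrance_anchor" in region_membership(template, "54'")
    assert "entrance_anchor" in region_membership(template, "49'")
    # A/B junction: vertex 3 belongs to both bottom rings
    assert template.vertices["3"].member_rings >= {"A", "B"}
    # position 10 sits at the junction of Rings A and E
    assert template.vertices["10"].member_rings >= {"A", "E"}


def test_site_of_oxidation_on_bottom_row(template):
    ys = [v.y for v in template.vertices.values()]
    site_ys = [template.vertices[s].y for s in template.site_of_oxidation]
    assert max(site_ys) < min(ys) + 2 * EDGE_LENGTH


def test_trigger_path_strictly_right_to_left(template):
    xs = [template.ring_center_x(r) for r in template.trigger_path]
    assert all(a > b for a, b in zip(xs, xs[1:]))
    assert "A" not in template.trigger_path


def test_serialize_roundtrip(template):
    t2 = load_template(serialize_template(template))
    assert t2.rings == template.rings
    assert set(t2.vertices) == set(template.vertices)
    for lbl, v in template.vertices.items():
        w = t2.vertices[lbl]
        assert (w.x, w.y) == (v.x, v.y)
        assert w.features == v.features
        assert w.member_rings == v.member_rings
    assert t2.left_end == template.left_end
    assert t2.trigger_path == template.trigger_path


def test_validation_catches_injected_defects(template):
    doc = yaml.safe_load(serialize_template(template))

    broken = yaml.safe_load(serialize_template(template))
    broken["rings"]["A"] = broken["rings"]["A"][:5]
    with pytest.raises(TemplateError, match="5 vertices"):
        load_template(broken)

    broken = yaml.safe_load(serialize_template(template))
    broken["trigger_path"] = ["eB", "B", "A"]
    with pytest.raises(TemplateError, match="Ring A"):
        load_template(broken)

    broken = yaml.safe_load(serialize_template(template))
    broken["width_gauge"] = 1.7
    with pytest.raises(TemplateError, match="width_gauge"):
        load_template(broken)

    broken = yaml.safe_load(serialize_template(template))
    broken["rings"]["A"] = ["1", "2", "3", "4", "5", "ghost"]
    with pytest.raises(TemplateError, match="ghost"):
        load_template(broken)

    assert load_template(doc).name == template.name  # untouched copy loads


def test_trim_template_keeps_metadata_consistent(template):
    tt = trim_template(template, ["A", "B", "C", "D"])
    assert set(tt.rings) == {"A", "B", "C", "D"}
    assert validate_template(tt) == []
    assert tt.site_of_oxidation <= template.site_of_oxidation
    kept = set(tt.vertices)
    for ring in tt.rings.values():
        assert set(ring) <= kept
    with pytest.raises(KeyError):
        trim_template(template, ["A", "Z"])
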