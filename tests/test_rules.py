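"""Interaction rules and Verdict classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from p450template.ligand import load_ligand
from p450template.rules import (
    AtomPlacement,
    Category,
    Depth,
    RuleConfig,
    check_descent,
    check_lactone,
    check_left_end,
    check_plural_rear_contact,
    check_ring_b,
    check_shelf,
    check_site_occupancy,
    check_width,
    evaluate_placement,
)
from p450template.trigger import simulate_trigger


def place(g, spec, **kw):
    """Helper: spec maps atom index -> (vertex, Depth)."""
    return AtomPlacement(ligand=g, assignment=dict(spec), **kw)


@pytest.fixture(scope="module")
def propane():
    return load_ligand("CCC", "propane")


def test_width_gate(template, propane):
    p = place(propane, {0: ("2", Depth.REAR), 1: ("3", Depth.REAR), 2: ("11", Depth.MID)})
    assert check_width(p, template).passed
    bad = place(
        propane,
        {0: ("2", Depth.REAR), 1: ("3", Depth.REAR), 2: ("11", Depth.MID)},
        out_of_slab=frozenset({2}),
    )
    r = check_width(bad, template)
    assert not r.passed
    assert 2 in {i for i, _ in r.evidence}


def test_plural_rear_needs_two_non_lactone_atoms(template, propane):
    two = place(propane, {0: ("2", Depth.REAR), 1: ("3", Depth.REAR), 2: ("11", Depth.MID)})
    assert check_plural_rear_contact(two, template).passed
    one = place(propane, {0: ("2", Depth.REAR), 1: ("3", Depth.MID), 2: ("11", Depth.MID)})
    assert not check_plural_rear_contact(one, template).passed

    thal = load_ligand("O=C1CC[C@H](N2C(=O)c3ccccc3C2=O)C(=O)N1", "thalidomide")
    lact = sorted(thal.annotation("lactone_ring_atom"))[:2]
    only_lactone_rear = place(thal, {lact[0]: ("2", Depth.REAR), lact[1]: ("3", Depth.REAR)})
    assert not check_plural_rear_contact(only_lactone_rear, template).passed


def test_ring_b_occupancy(template, propane):
    on_junction = place(propane, {0: ("3", Depth.MID), 1: ("11", Depth.MID), 2: ("10", Depth.MID)})
    assert check_ring_b(on_junction, template).passed
    off = place(propane, {0: ("2", Depth.MID), 1: ("9", Depth.MID), 2: ("10", Depth.MID)})
    assert not check_ring_b(off, template).passed
    empty = place(propane, {})
    assert not check_ring_b(empty, template).passed


def test_site_occupancy_requires_oxidizable_atom(template):
    propane = load_ligand("CCC", "propane")
    hit = place(propane, {0: ("3", Depth.REAR), 1: ("11", Depth.MID), 2: ("12", Depth.MID)})
    r = check_site_occupancy(hit, template)
    assert r.passed and (0, "3") in r.evidence

    # a fluorine in the site region cannot be oxidized
    cf4like = load_ligand("FC(F)(F)F", "tetrafluoromethane")
    f_idx = next(i for i, a in enumerate(cf4like.atoms) if a.element == "F")
    c_idx = next(i for i, a in enumerate(cf4like.atoms) if a.element == "C")
    p = place(cf4like, {f_idx: ("3", Depth.REAR), c_idx: ("11", Depth.MID)})
    assert not check_site_occupancy(p, template).passed


def test_left_end_shelf_descent(template, propane):
    at_border = place(propane, {0: ("27'", Depth.MID), 1: ("27", Depth.MID), 2: ("28", Depth.MID)})
    assert check_left_end(at_border, template).passed
    inner = place(propane, {0: ("3", Depth.MID), 1: ("11", Depth.MID), 2: ("12", Depth.MID)})
    assert not check_left_end(inner, template).passed

    under = place(propane, {0: ("eE2", Depth.MID), 1: ("8", Depth.MID), 2: ("9", Depth.MID)})
    assert not check_shelf(under, template).passed
    assert not check_descent(under, template).passed
    assert check_shelf(inner, template).passed
    assert check_descent(inner, template).passed


def test_lactone_rule_rejects_rear_and_trigger_contact(template):
    thal = load_ligand("O=C1CC[C@H](N2C(=O)c3ccccc3C2=O)C(=O)N1", "thalidomide")
    lact = sorted(thal.annotation("lactone_ring_atom"))
    rear_lactone = place(thal, {lact[0]: ("9", Depth.REAR)})
    assert not check_lactone(rear_lactone, template).passed
    facial_lactone = place(thal, {lact[0]: ("9", Depth.FACIAL)})
    assert check_lactone(facial_lactone, template).passed
    assert not check_lactone(
        facial_lactone, template, trigger_contacts=frozenset({lact[0]})
    ).passed


def _verdict(rec, template, cfg=None):
    p = rec.realize(template)
    return evaluate_placement(p, template, simulate_trigger(p, template), cfg)


def test_good_poor_inhibitor_examples(record_map, template):
    good = _verdict(record_map[("R-5-Hydroxythalidomide", "aromatic oxidation")], template)
    assert good.category is Category.GOOD_SUBSTRATE
    assert good.predicted_sites

    poor = _verdict(record_map[("S-Thalidomide", "ring oxidation")], template)
    assert poor.category is Category.POOR_SUBSTRATE
    assert "R_RING_B" in poor.failed_rules()

    danazol = _verdict(record_map[("Danazol", "oxazole oxidation")], template)
    assert danazol.category is Category.INHIBITOR


def test_verdict_invariants(record_map, template):
    v = _verdict(record_map[("Linezolid", "morpholine oxidation")], template)
    assert v.category is Category.GOOD_SUBSTRATE
    for rid in ("R_RING_B", "R_SITE", "R_PLURAL_REAR", "R_WIDTH"):
        assert v.result(rid).passed
    assert v.predicted_sites


def test_rule_order_independence(record_map, template):
    """Rules read only placement + template, so evaluation is a pure function:
    repeated evaluation gives identical verdicts."""
    rec = record_map[("Benzphetamine", "N-demethylation")]
    p = rec.realize(template)
    state = simulate_trigger(p, template)
    verdicts = [evaluate_placement(p, template, state) for _ in range(3)]
    for v in verdicts[1:]:
        assert v.category == verdicts[0].category
        assert v.score == verdicts[0].score
        assert {r.rule_id: r.passed for r in v.rule_results} == {
            r.rule_id: r.passed for r in verdicts[0].rule_results
        }


def test_monotonicity_rear_contact_never_downgrades(record_map, template):
    """Adding a non-lactone rear contact never flips GOOD to POOR, and
    removing Ring-B occupancy always does."""
    rec = record_map[("Chlorzoxazone", "6-oxidation")]
    p = rec.realize(template)
    base = evaluate_placement(p, template, simulate_trigger(p, template))
    assert base.category is Category.GOOD_SUBSTRATE

    lact = rec.load().annotation("lactone_ring_atom")
    for i, (v, d) in p.assignment.items():
        if d is Depth.REAR or i in lact:
            continue
        boosted = AtomPlacement(
            ligand=p.ligand,
            assignment={**p.assignment, i: (v, Depth.REAR)},
            bond_tolerance=p.bond_tolerance,
        )
        vb = evaluate_placement(boosted, template, simulate_trigger(boosted, template))
        assert vb.category is Category.GOOD_SUBSTRATE
        assert vb.score >= base.score

    ring_b = set(template.rings["B"])
    moved = {
        i: (("9", d) if v in ring_b else (v, d)) for i, (v, d) in p.assignment.items()
    }
    stripped = AtomPlacement(ligand=p.ligand, assignment=moved, bond_tolerance=6)
    vs = evaluate_placement(stripped, template, simulate_trigger(stripped, template))
    assert vs.category is not Category.GOOD_SUBSTRATE


@given(st.integers(0, 2), st.sampled_from([Depth.FACIAL, Depth.MID, Depth.REAR]))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_score_linear_in_rear_weight(atom, depth):
    from p450template.geometry import load_canonical_template

    t = load_canonical_template()
    g = load_ligand("CCC", "propane")
    base_spec = {0: ("12", Depth.MID), 1: ("11", Depth.MID), 2: ("13", Depth.MID)}
    p0 = place(g, base_spec)
    p1 = place(g, {**base_spec, atom: (base_spec[atom][0], depth)})
    cfg = RuleConfig()
    v0 = evaluate_placement(p0, t, simulate_trigger(p0, t), cfg)
    v1 = evaluate_placement(p1, t, simulate_trigger(p1, t), cfg)
    if depth is Depth.REAR:
        assert v1.score == v0.score + cfg.weights["rear"]
    elif depth is Depth.FACIAL:
        assert v1.score == v0.score + cfg.weights["facial"]
    else:
        assert v1.score == v0.score
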