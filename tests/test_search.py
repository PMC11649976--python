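"""Lattice embedding search, oracle equivalence, scoring, prediction."""

import pytest

from p450template.fixtures import generate_toy_ligands
from p450template.ligand import load_ligand
from p450template.rules import Category
from p450template.search import (
    SearchConfig,
    SizeError,
    brute_force_oracle,
    enumerate_embeddings,
    predict,
    score_placement,
)

BIG = SearchConfig(max_placements=10**7)


def _key(p):
    return tuple((p.assignment[i][0], p.assignment[i][1]) for i in sorted(p.assignment))


def test_single_atom_count_is_vertices_times_buckets(trimmed):
    g = load_ligand("C", "one")
    out = enumerate_embeddings(g, trimmed, BIG)
    assert len(out) == len(trimmed.vertices) * 3


def test_two_atom_count_is_directed_edges_times_depths(trimmed):
    g = load_ligand("CC", "two")
    out = enumerate_embeddings(g, trimmed, BIG)
    assert len(out) == 2 * trimmed.graph.number_of_edges() * 9


def test_benzene_embeds_only_on_ring_cells(trimmed):
    g = load_ligand("c1ccccc1", "benzene")
    out = enumerate_embeddings(g, trimmed, BIG)
    cells = {frozenset(c) for c in trimmed.rings.values()}
    for p in out:
        assert frozenset(v for v, _ in p.assignment.values()) in cells
    # every ring cell is hit in both orientations and all rotations
    vertex_sets = {frozenset(v for v, _ in p.assignment.values()) for p in out}
    assert vertex_sets == cells


def test_five_ring_has_no_on_corner_embedding(trimmed):
    g = load_ligand("C1CCCC1", "cyclopentane")
    assert enumerate_embeddings(g, trimmed, BIG) == []
    assert brute_force_oracle(g, trimmed, BIG) == []


def test_search_deterministic(trimmed):
    g = load_ligand("CCC", "propane")
    a = [_key(p) for p in enumerate_embeddings(g, trimmed, BIG)]
    b = [_key(p) for p in enumerate_embeddings(g, trimmed, BIG)]
    assert a == b


def test_max_placements_cap(trimmed):
    g = load_ligand("CC", "two")
    out = enumerate_embeddings(g, trimmed, SearchConfig(max_placements=17))
    assert len(out) == 17


def test_size_limits(trimmed):
    big = load_ligand("C" * 20, "icosane")
    with pytest.raises(SizeError):
        brute_force_oracle(big, trimmed)
    with pytest.raises(SizeError):
        enumerate_embeddings(big, trimmed, SearchConfig(max_atoms=10))


@pytest.mark.parametrize("smiles", ["C", "CC", "CCC", "CCO", "C1CCCCC1", "C1OCCC1"])
def test_oracle_equivalence_examples(trimmed, smiles):
    g = load_ligand(smiles, smiles)
    a = {_key(p) for p in enumerate_embeddings(g, trimmed, BIG)}
    b = {_key(p) for p in brute_force_oracle(g, trimmed, BIG)}
    assert a == b


def test_oracle_equivalence_off_corner_mode(template):
    from p450template.geometry import trim_template

    tiny = trim_template(template, ["A", "B"])
    cfg = SearchConfig(max_placements=10**7, allow_off_corner=True, tolerance=2)
    g = load_ligand("C1CC1", "cyclopropane")
    a = {_key(p) for p in enumerate_embeddings(g, tiny, cfg)}
    b = {_key(p) for p in brute_force_oracle(g, tiny, cfg)}
    assert a == b
    assert a  # the 3-ring fits once bonds may sit off-corner


def test_generated_toys_load_and_tag():
    toys = generate_toy_ligands(12, seed=3)
    assert len(toys) == 12
    again = generate_toy_ligands(12, seed=3)
    assert [g.smiles for g in toys] == [g.smiles for g in again]
    assert len(toys[0]) == 2  # first family member is the two-atom chain
    for g in toys:
        assert g.annotations.keys() == {
            "lactone_ring_atom",
            "heme_ligating_heteroatom",
            "candidate_oxidation_site",
        }


def test_predict_small_ligand(trimmed):
    g = load_ligand("CC", "ethane")
    pred = predict(g, trimmed, SearchConfig(max_placements=2000))
    assert pred.ranked
    # trimmed template keeps the site, so some placement may metabolise;
    # ranking must put the highest-ranked first
    scores = [score_placement(p, v) for p, v in pred.ranked]
    assert scores == sorted(scores, reverse=True)
    assert pred.best_category == pred.ranked[0][1].category


def test_predict_reports_nonligand_when_nothing_fits(trimmed):
    g = load_ligand("C1CCCC1", "cyclopentane")
    pred = predict(g, trimmed, SearchConfig(max_placements=100))
    assert pred.best_category is Category.NON_LIGAND
    assert pred.ranked == []


def test_good_outranks_poor_for_same_ligand(template, record_map):
    """A functional placement of magnolin outranks the trace-level one."""
    from p450template.rules import evaluate_placement
    from p450template.trigger import simulate_trigger

    m2 = record_map[("Magnolin", "O-demethylation")].realize(template)
    m1 = record_map[("Magnolin", "O-demethylation (M-1)")].realize(template)
    v2 = evaluate_placement(m2, template, simulate_trigger(m2, template))
    v1 = evaluate_placement(m1, template, simulate_trigger(m1, template))
    assert v2.score > v1.score
    assert score_placement(m2, v2) > score_placement(m1, v1)
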