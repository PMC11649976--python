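"""Ligand graphs, functional-group tags, conformer flattening."""

import numpy as np
import pytest

from p450template.ligand import LigandError, flatten_conformer, load_ligand

THALIDOMIDE = "O=C1CC[C@H](N2C(=O)c3ccccc3C2=O)C(=O)N1"
DANAZOL = "C#C[C@]1(O)CC[C@H]2[C@@H]3CCC4=Cc5cnoc5C[C@]4(C)[C@H]3CC[C@]12C"


def test_benzene_graph():
    g = load_ligand("c1ccccc1", "benzene")
    assert len(g) == 6
    assert len(g.bonds) == 6
    assert all(a.aromatic and a.in_ring for a in g.atoms)
    assert len({a.rigid_block for a in g.atoms}) == 1


def test_ethane_and_single_atom():
    g = load_ligand("CC", "ethane")
    assert len(g) == 2 and len(g.bonds) == 1
    c = load_ligand("C", "methane-like")
    assert c.annotation("candidate_oxidation_site") == {0}
    assert not c.annotation("lactone_ring_atom")
    assert not c.annotation("heme_ligating_heteroatom")


def test_chlorzoxazone_features():
    g = load_ligand("O=c1oc2cc(Cl)ccc2[nH]1", "chlorzoxazone")
    assert any(a.element == "Cl" for a in g.atoms)
    ring_blocks = {a.rigid_block for a in g.atoms if a.in_ring}
    assert len(ring_blocks) == 1  # fused bicyclic = one rigid block


def test_hydrogens_never_appear():
    g = load_ligand("CCO", "ethanol")
    assert all(a.element != "H" for a in g.atoms)


def test_multi_fragment_rejected():
    with pytest.raises(LigandError, match="fragments"):
        load_ligand("CC.O", "salt")
    with pytest.raises(LigandError, match="unparseable"):
        load_ligand("not-a-molecule", "junk")


def test_thalidomide_glutarimide_tagged_lactone_like():
    g = load_ligand(THALIDOMIDE, "thalidomide")
    lact = g.annotation("lactone_ring_atom")
    assert lact, "ionizable glutarimide ring must be tagged"
    elements = {g.atoms[i].element for i in lact}
    assert elements == {"C", "N"}
    # the tag is the non-aromatic 6-ring; benzo carbons stay untagged
    assert all(not g.atoms[i].aromatic for i in lact)


def test_rigid_small_cyclic_carbamates_not_tagged():
    linezolid = load_ligand(
        "CC(=O)NC[C@H]1CN(c2ccc(N3CCOCC3)c(F)c2)C(=O)O1", "linezolid"
    )
    assert not linezolid.annotation("lactone_ring_atom")


def test_heme_ligating_tags():
    dan = load_ligand(DANAZOL, "danazol")
    (n_idx,) = dan.annotation("heme_ligating_heteroatom")
    assert dan.atoms[n_idx].element == "N"  # isoxazole nitrogen

    nor = load_ligand("CCn1cc(C(=O)O)c(=O)c2cc(N3CCNCC3)c(F)cc21", "norfloxacin")
    hits = nor.annotation("heme_ligating_heteroatom")
    assert len(hits) == 1  # terminal piperazine NH; aniline-type N excluded
    assert nor.atoms[next(iter(hits))].n_hydrogens == 1

    thio = load_ligand("CSc1ccc2Sc3ccccc3N(CCC4CCCCN4C)c2c1", "thioridazine")
    assert any(thio.atoms[i].element == "S" for i in thio.annotation("heme_ligating_heteroatom"))


def test_candidate_oxidation_sites():
    g = load_ligand("CC(=O)c1ccccc1", "acetophenone")
    cand = g.annotation("candidate_oxidation_site")
    assert 0 in cand  # methyl
    assert all(g.atoms[i].element != "O" for i in cand)


def test_flatten_benzene_is_strain_free():
    g = load_ligand("c1ccccc1", "benzene")
    pc = flatten_conformer(g)
    assert pc.strain_proxy == 0.0
    assert pc.coords.shape == (6, 3)
    # z initialised mid-slab
    assert np.allclose(pc.coords[:, 2], 0.75)
    lengths = [
        np.linalg.norm(pc.coords[a, :2] - pc.coords[b, :2]) for a, b, _ in g.bonds
    ]
    assert np.allclose(lengths, 1 / np.sqrt(3), atol=1e-6)


def test_flatten_projects_3d_and_scores_strain():
    g = load_ligand("CC", "ethane")
    flat = flatten_conformer(g, coords3d=np.array([[0.0, 0, 0], [1.0, 0, 0]]))
    assert flat.strain_proxy == pytest.approx(0.0)

    g4 = load_ligand("CCCC", "butane")
    twisted = np.array([[0.0, 0, 0], [1, 0.2, 0.4], [2, 1.0, -0.4], [2.5, 1.8, 0.5]])
    pc = flatten_conformer(g4, coords3d=twisted)
    assert pc.strain_proxy > 0


def test_load_tag_flatten_deterministic():
    a = flatten_conformer(load_ligand(DANAZOL, "danazol"))
    b = flatten_conformer(load_ligand(DANAZOL, "danazol"))
    assert np.array_equal(a.coords, b.coords)
    assert a.ligand.annotations == b.ligand.annotations
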