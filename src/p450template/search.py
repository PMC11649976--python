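"""Constrained embedding of ligand graphs onto the Template lattice.

The embedding model is discrete: heavy atoms sit on honeycomb vertices, bonds
follow lattice edges, and each atom carries one of three depth buckets
(facial / mid / rear) inside the Width-gauge slab.  With ``allow_off_corner``
enabled, bonded atoms may instead share a vertex or sit up to ``tolerance``
lattice steps apart (atoms accepted "not exactly at the corner"), which is
how non-hexagonal rings (5-rings, fused systems that do not tile the
honeycomb) are accommodated.

``enumerate_embeddings`` is a depth-first search over a canonical atom order;
``brute_force_oracle`` is a deliberately naive enumeration in plain atom
index order used to cross-check it on small graphs.  Both filter through the
same admissibility predicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .geometry import TemplateGrid
from .ligand import LigandGraph
from .notation import RingPath, parse_placement
from .rules import AtomPlacement, Category, Depth, RuleConfig, Verdict, evaluate_placement
from .trigger import simulate_trigger

__all__ = [
    "SearchConfig",
    "Prediction",
    "SizeError",
    "enumerate_embeddings",
    "brute_force_oracle",
    "score_placement",
    "predict",
]

DEPTH_ORDER = (Depth.FACIAL, Depth.MID, Depth.REAR)


class SizeError(ValueError):
    pass


@dataclass
class SearchConfig:
    """Search knobs.

    ``strain_threshold`` is the accept gate standing in the slot of the
    force-field strain criterion (< 0.1); ``max_placements`` caps the search;
    ``allow_off_corner``/``tolerance`` relax bond adjacency as described in
    the module docstring.
    """

    strain_threshold: float = 0.1
    max_placements: int = 10_000
    seed: int = 0
    allow_off_corner: bool = False
    tolerance: int = 2
    max_atoms: int = 60
    score_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.strain_threshold < 0 or self.tolerance < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_placements < 1:
            raise ValueError("max_placements must be >= 1")

    def rule_config(self) -> RuleConfig:
        cfg = RuleConfig()
        if self.score_weights is not None:
            cfg.weights = dict(self.score_weights)
        return cfg


@dataclass
class Prediction:
    ligand: str
    ranked: list[tuple[AtomPlacement, Verdict]]
    best_category: Category
    best_sites: frozenset[int] = frozenset()

    def as_dict(self) -> dict:
        return {
            "ligand": self.ligand,
            "best_category": self.best_category.value,
            "best_sites": sorted(self.best_sites),
            "n_placements": len(self.ranked),
            "top": [
                {
                    "notation": _notation_key(p, v),
                    "category": v.category.value,
                    "score": v.score,
                    "sites": sorted(v.predicted_sites),
                }
                for p, v in self.ranked[:5]
            ],
        }


def _vertex_sort_key(label: str):
    return (0, int(label), "") if label.isdigit() else (1, 0, label)


def _ordered_vertices(t: TemplateGrid) -> list[str]:
    return sorted(t.vertices, key=_vertex_sort_key)


def _bond_ok(t: TemplateGrid, cfg: SearchConfig, va: str, vb: str) -> bool:
    if cfg.allow_off_corner:
        return va == vb or t.lattice_distance(va, vb) <= cfg.tolerance
    return t.graph.has_edge(va, vb)


def admissible_vertices(
    g: LigandGraph, t: TemplateGrid, cfg: SearchConfig, assign: Sequence[str]
) -> bool:
    """Shared admissibility predicate on a full vertex assignment."""
    forbidden = set(t.shelf_forbidden)
    if any(v in forbidden for v in assign):
        return False
    if not cfg.allow_off_corner and len(set(assign)) != len(assign):
        return False
    for a, b, _ in g.bonds:
        if not _bond_ok(t, cfg, assign[a], assign[b]):
            return False
    return True


def _canonical_atom_order(g: LigandGraph) -> list[int]:
    """Largest rigid block first, then BFS over the bond graph."""
    n = len(g)
    blocks: dict[int, list[int]] = {}
    for i, a in enumerate(g.atoms):
        blocks.setdefault(a.rigid_block, []).append(i)
    anchor_block = max(blocks.values(), key=lambda idxs: (len(idxs), -min(idxs)))
    start = min(anchor_block)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b, _ in g.bonds:
        adj[a].append(b)
        adj[b].append(a)
    order, seen, queue = [], {start}, [start]
    while queue:
        cur = queue.pop(0)
        order.append(cur)
        for nb in sorted(adj[cur]):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    order.extend(i for i in range(n) if i not in seen)  # disconnected safety
    return order


def _vertex_assignments(
    g: LigandGraph, t: TemplateGrid, cfg: SearchConfig
) -> Iterator[list[str]]:
    """DFS over the canonical atom order; yields full vertex assignments."""
    n = len(g)
    order = _canonical_atom_order(g)
    pos_in_order = {atom: k for k, atom in enumerate(order)}
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b, _ in g.bonds:
        adj[a].append(b)
        adj[b].append(a)
    vertices = [v for v in _ordered_vertices(t) if v not in set(t.shelf_forbidden)]
    assign: dict[int, str] = {}

    def candidates(atom: int) -> list[str]:
        placed_nb = [nb for nb in adj[atom] if nb in assign]
        if not placed_nb:
            return vertices
        if cfg.allow_off_corner:
            cands = [
                v
                for v in vertices
                if all(_bond_ok(t, cfg, v, assign[nb]) for nb in placed_nb)
            ]
        else:
            first = placed_nb[0]
            cands = [
                v
                for v in sorted(t.graph.neighbors(assign[first]), key=_vertex_sort_key)
                if all(t.graph.has_edge(v, assign[nb]) for nb in placed_nb[1:])
                and v not in set(t.shelf_forbidden)
            ]
        if not cfg.allow_off_corner:
            used = set(assign.values())
            cands = [v for v in cands if v not in used]
        return cands

    def rec(k: int) -> Iterator[list[str]]:
        if k == n:
            full = [assign[i] for i in range(n)]
            if admissible_vertices(g, t, cfg, full):
                yield list(full)
            return
        atom = order[k]
        for v in candidates(atom):
            assign[atom] = v
            yield from rec(k + 1)
            del assign[atom]

    yield from rec(0)


def _with_depths(
    g: LigandGraph, vertex_assignments: Iterator[list[str]], cfg: SearchConfig
) -> Iterator[AtomPlacement]:
    n = len(g)
    count = 0
    for vs in vertex_assignments:
        for depths in itertools.product(DEPTH_ORDER, repeat=n):
            count += 1
            if count > cfg.max_placements:
                return
            yield AtomPlacement(
                ligand=g,
                assignment={i: (vs[i], depths[i]) for i in range(n)},
                bond_tolerance=cfg.tolerance if cfg.allow_off_corner else 1,
            )


def enumerate_embeddings(
    g: LigandGraph, t: TemplateGrid, cfg: SearchConfig | None = None
) -> list[AtomPlacement]:
    """All admissible embeddings (atoms -> vertices, bonds -> lattice edges,
    depth buckets free), in deterministic order, up to ``max_placements``."""
    cfg = cfg or SearchConfig()
    if len(g) > cfg.max_atoms:
        raise SizeError(f"{g.name}: {len(g)} atoms exceeds cap {cfg.max_atoms}")
    return list(_with_depths(g, _vertex_assignments(g, t, cfg), cfg))


def brute_force_oracle(
    g: LigandGraph, t: TemplateGrid, cfg: SearchConfig | None = None
) -> list[AtomPlacement]:
    """Naive exhaustive enumeration for graphs of <= 6 atoms, used as the
    independent cross-check of :func:`enumerate_embeddings` in tests."""
    cfg = cfg or SearchConfig()
    if len(g) > 6:
        raise SizeError(f"brute_force_oracle is limited to 6 atoms, got {len(g)}")
    n = len(g)
    vertices = _ordered_vertices(t)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b, _ in g.bonds:
        adj[a].append(b)
        adj[b].append(a)

    out_vertices: list[list[str]] = []

    def rec(i: int, assign: list[str]) -> None:
        if i == n:
            if admissible_vertices(g, t, cfg, assign):
                out_vertices.append(list(assign))
            return
        for v in vertices:
            # progressive pruning keeps this tractable but stays a plain
            # index-order enumeration, unlike the DFS above
            ok = True
            if not cfg.allow_off_corner and v in assign:
                ok = False
            if ok:
                for nb in adj[i]:
                    if nb < i and not _bond_ok(t, cfg, v, assign[nb]):
                        ok = False
                        break
            if ok:
                assign.append(v)
                rec(i + 1, assign)
                assign.pop()

    rec(0, [])
    placements: list[AtomPlacement] = []
    for vs in out_vertices:
        for depths in itertools.product(DEPTH_ORDER, repeat=n):
            placements.append(
                AtomPlacement(
                    ligand=g,
                    assignment={i: (vs[i], depths[i]) for i in range(n)},
                    bond_tolerance=cfg.tolerance if cfg.allow_off_corner else 1,
                )
            )
    return placements


_CATEGORY_BONUS = {
    Category.GOOD_SUBSTRATE: 1000.0,
    Category.INHIBITOR: 500.0,
    Category.POOR_SUBSTRATE: 0.0,
    Category.NON_LIGAND: -1000.0,
}


def score_placement(p: AtomPlacement, verdict: Verdict) -> float:
    """Ranking score: weighted contact score plus a category bonus, so a
    functional (GOOD) placement of a ligand always outranks a poor one."""
    return verdict.score + _CATEGORY_BONUS[verdict.category]


def _notation_key(p: AtomPlacement, v: Verdict | None = None) -> str:
    t_rings = sorted(p.notation.all_labels()) if p.notation else []
    if t_rings:
        return "-".join(t_rings)
    return "-".join(f"{p.assignment[i][0]}:{p.assignment[i][1].value[0]}" for i in sorted(p.assignment))


def predict(g: LigandGraph, t: TemplateGrid, cfg: SearchConfig | None = None) -> Prediction:
    """Enumerate, simulate the Trigger-residue, evaluate and rank.

    The best category is that of the top-ranked placement; ``best_sites``
    pools predicted sites over all top-score GOOD placements (regioselective
    alternatives are reported together rather than forced to one).  A ligand
    with no admissible embedding at all is a NON_LIGAND.
    """
    cfg = cfg or SearchConfig()
    rcfg = cfg.rule_config()
    scored: list[tuple[AtomPlacement, Verdict]] = []
    for p in enumerate_embeddings(g, t, cfg):
        state = simulate_trigger(p, t)
        v = evaluate_placement(p, t, state, rcfg)
        scored.append((p, v))
    if not scored:
        return Prediction(ligand=g.name, ranked=[], best_category=Category.NON_LIGAND)
    scored.sort(key=lambda pv: (-score_placement(pv[0], pv[1]), _notation_key(pv[0])))
    best_p, best_v = scored[0]
    best_sites = frozenset()
    if best_v.category is Category.GOOD_SUBSTRATE:
        top = [
            v.predicted_sites
            for p_, v in scored
            if v.category is Category.GOOD_SUBSTRATE and v.score == best_v.score
        ]
        best_sites = frozenset().union(*top) if top else frozenset()
    return Prediction(
        ligand=g.name,
        ranked=scored,
        best_category=best_v.category,
        best_sites=best_sites,
    )
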