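"""Deterministic realization of a ring-path placement at atom level.

The published placements are drawings; machine-readable fixtures store the
ring path plus a handful of atom-level anchors ("pins": this atom at that
Position, at that depth) transcribed from the described contacts.  This
module turns (ligand, ring path, pins) into a full :class:`AtomPlacement`:

* pinned atoms go exactly where the transcription says;
* the ligand's backbone (the longest bond path from the anchor pin) is
  mapped monotonically onto the ring sequence of the path, giving every
  atom an expected ring; remaining atoms inherit the expected ring of the
  nearest backbone atom;
* atoms are then assigned breadth-first along the bond graph, greedily
  choosing vertices that stay within the off-corner bond tolerance of
  already-placed neighbours, respect the reachability of every pinned atom,
  march toward their expected ring, spread occupancy, and keep filler atoms
  off scoring-sensitive vertices (Site of oxidation, Shelf edge, Left-end)
  and off junction corners of rings the path does not name;
* a short repair pass then resolves any bond still stretched beyond the
  tolerance (pinned atoms never move);
* depths: pinned > rear/facial tag lists > lactone-like rings facial >
  mid-slab default.

The procedure is deterministic for a fixed template, ligand and record.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import TemplateGrid
from .ligand import LigandGraph
from .notation import RingPath, parse_placement
from .rules import AtomPlacement, Depth

__all__ = ["Pin", "realize_placement"]


@dataclass(frozen=True)
class Pin:
    vertex: str
    depth: Depth | None = None
    smarts: str | None = None
    atom: int | None = None
    select: int = 0  # which SMARTS match (not which atom within a match)

    def resolve(self, g: LigandGraph) -> int:
        if self.atom is not None:
            return self.atom
        if self.smarts is None:
            raise ValueError("pin needs 'atom' or 'smarts'")
        hit = g.match_nth(self.smarts, self.select)
        if not hit:
            raise ValueError(f"{g.name}: pin SMARTS {self.smarts!r} has no match")
        return hit[0]


def _ring_sequence(path: RingPath) -> list[str]:
    """Rings in transcription order: main steps first, then branches."""
    seq: list[str] = []
    branch_map = path.branch_map()
    for step in path.main:
        for lbl in step:
            if lbl not in seq:
                seq.append(lbl)
    for idx in sorted(branch_map):
        for token in branch_map[idx]:
            for bstep in token:
                for lbl in bstep:
                    if lbl not in seq:
                        seq.append(lbl)
    return seq


def _main_rings(path: RingPath) -> list[str]:
    return [step[0] for step in path.main]


def _adjacency(g: LigandGraph) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {i: [] for i in range(len(g))}
    for a, b, _ in g.bonds:
        adj[a].append(b)
        adj[b].append(a)
    return {i: sorted(nbs) for i, nbs in adj.items()}


def _graph_distances(adj: dict[int, list[int]], start: int) -> dict[int, int]:
    dist = {start: 0}
    queue = [start]
    while queue:
        cur = queue.pop(0)
        for nb in adj[cur]:
            if nb not in dist:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist


def _backbone(adj: dict[int, list[int]], anchor: int) -> list[int]:
    """Longest shortest-path from the anchor atom, as an atom list."""
    dist = _graph_distances(adj, anchor)
    far = max(sorted(dist), key=lambda i: dist[i])
    # walk back from far to anchor
    path = [far]
    cur = far
    while cur != anchor:
        cur = min((nb for nb in adj[cur] if dist.get(nb, 10**9) == dist[cur] - 1))
        path.append(cur)
    return list(reversed(path))


def realize_placement(
    g: LigandGraph,
    path: RingPath | str,
    t: TemplateGrid,
    pins: list[Pin] | None = None,
    rear: list[str] | None = None,
    facial: list[str] | None = None,
    tolerance: int = 2,
) -> AtomPlacement:
    """Build an atom-level placement realizing ``path`` with the given pins."""
    if isinstance(path, str):
        path = parse_placement(path, known_rings=set(t.rings))
    ring_seq = _ring_sequence(path)
    missing = [r for r in ring_seq if r not in t.rings]
    if missing:
        raise KeyError(f"path names unknown rings {missing}")
    forbidden = set(t.shelf_forbidden)
    pool: list[str] = []
    for r in ring_seq:
        for v in t.rings[r]:
            if v not in pool and v not in forbidden:
                pool.append(v)
    if not pool:
        raise ValueError("empty vertex pool for path")
    pool_set = set(pool)
    universe = [v for v in t.vertices if v not in forbidden]
    ring_vertices = {r: [v for v in t.rings[r] if v not in forbidden] for r in ring_seq}

    special = set(t.site_of_oxidation) | set(t.shelf_edge) | set(t.left_end)

    # depth buckets
    depth_of: dict[int, Depth] = {}
    for smarts_list, bucket in ((rear or [], Depth.REAR), (facial or [], Depth.FACIAL)):
        for smarts in smarts_list:
            for i in g.match_all(smarts):
                depth_of[i] = bucket
    for i in g.annotation("lactone_ring_atom"):
        depth_of.setdefault(i, Depth.FACIAL)

    # pins
    pinned: dict[int, Pin] = {}
    for pin in pins or []:
        if pin.vertex not in t.vertices:
            raise KeyError(f"pin vertex {pin.vertex!r} not on template")
        pinned[pin.resolve(g)] = pin

    adj = _adjacency(g)
    n = len(g)

    # expected ring per atom: backbone resampled along the ring sequence
    anchor = next(iter(pinned)) if pinned else 0
    spine = _backbone(adj, anchor)
    main_seq = [r for r in _main_rings(path) if r in ring_seq] or ring_seq
    anchor_vertex = pinned[anchor].vertex if anchor in pinned else None
    start_idx = 0
    if anchor_vertex is not None:
        member = t.vertices[anchor_vertex].member_rings
        hits = [k for k, r in enumerate(main_seq) if r in member]
        start_idx = hits[0] if hits else 0
    expected: dict[int, str] = {}
    m = len(spine)
    span = len(main_seq) - 1 - start_idx
    for k, atom in enumerate(spine):
        idx = start_idx + (round(k * span / (m - 1)) if m > 1 else 0)
        expected[atom] = main_seq[max(0, min(idx, len(main_seq) - 1))]
    for atom, d in sorted(_graph_distances(adj, anchor).items()):
        if atom not in expected:
            near = min(
                (nb for nb in adj[atom] if nb in expected),
                default=None,
            )
            expected[atom] = expected[near] if near is not None else main_seq[0]
    for atom in range(n):  # disconnected safety
        expected.setdefault(atom, main_seq[0])

    dist = t.lattice_distance
    assignment: dict[int, tuple[str, Depth]] = {}
    usage: dict[str, int] = {}
    covered: set[str] = set()

    def put(atom: int, vertex: str, depth: Depth | None) -> None:
        d = depth if depth is not None else depth_of.get(atom, Depth.MID)
        assignment[atom] = (vertex, d)
        usage[vertex] = usage.get(vertex, 0) + 1
        covered.update(t.vertices[vertex].member_rings)

    for atom, pin in sorted(pinned.items()):
        put(atom, pin.vertex, pin.depth)

    if not assignment:
        put(0, pool[0], None)

    # breadth-first over the bond graph from all pinned seeds
    order: list[int] = []
    seen = set(assignment)
    queue = sorted(assignment)
    while queue:
        cur = queue.pop(0)
        order.append(cur)
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    for i in range(n):
        if i not in seen:
            order.append(i)

    # distance (in bonds) from each atom to each pinned atom, for feasibility
    pin_dists = {p: _graph_distances(adj, p) for p in pinned}

    def cost_of(atom: int, v: str, placed_nb: list[int]) -> float | None:
        c = 0.0
        for nb in placed_nb:
            d = 0 if v == assignment[nb][0] else dist(v, assignment[nb][0])
            if d > tolerance:
                return None
            c += 2.0 * abs(d - 1)
        for p, pin in pinned.items():
            if atom == p:
                continue
            ligd = pin_dists[p].get(atom)
            if ligd is not None and dist(v, pin.vertex) > ligd * tolerance:
                return None
        c += 1.5 * usage.get(v, 0)
        if v in special:
            c += 25.0
        if v not in pool_set:
            c += 4.0
        c += 8.0 * len(t.vertices[v].member_rings - set(ring_seq))
        exp_ring = expected[atom]
        exp_vs = ring_vertices.get(exp_ring) or pool
        c += 2.5 * min(dist(v, ev) for ev in exp_vs)
        uncovered = t.vertices[v].member_rings & (set(ring_seq) - covered)
        c -= 3.0 * len(uncovered)
        return c

    for atom in order:
        if atom in assignment:
            continue
        placed_nb = [nb for nb in adj[atom] if nb in assignment]
        best_v, best_cost = None, None
        for k, v in enumerate(universe):
            c = cost_of(atom, v, placed_nb)
            if c is None:
                continue
            c += 0.01 * (pool.index(v) if v in pool_set else len(pool) + k)
            if best_cost is None or c < best_cost - 1e-12:
                best_v, best_cost = v, c
        if best_v is None:
            # infeasible under the pin constraints: minimise total stretch
            def excess(v: str) -> float:
                e = sum(
                    max(0, (0 if v == assignment[nb][0] else dist(v, assignment[nb][0])) - tolerance)
                    for nb in placed_nb
                )
                return e
            best_v = min(universe, key=lambda v: (excess(v), universe.index(v)))
        put(atom, best_v, None)

    # repair pass: greedy single-atom moves that strictly reduce the total
    # bond stretch beyond the tolerance (pinned atoms never move)
    def bond_stretch(a: int, b: int) -> int:
        va, vb = assignment[a][0], assignment[b][0]
        return 0 if va == vb else max(0, dist(va, vb) - tolerance)

    def atom_stretch(atom: int, v: str) -> int:
        s = 0
        for nb in adj[atom]:
            if nb not in assignment:
                continue
            w = assignment[nb][0]
            s += 0 if v == w else max(0, dist(v, w) - tolerance)
        return s

    for _ in range(6 * n):
        bad = [(a, b) for a, b, _ in g.bonds if bond_stretch(a, b) > 0]
        if not bad:
            break
        best_move: tuple[int, str, int, float] | None = None
        candidates_atoms = sorted({i for ab in bad for i in ab if i not in pinned})
        for atom in candidates_atoms:
            cur = atom_stretch(atom, assignment[atom][0])
            for v in universe:
                s = atom_stretch(atom, v)
                if s >= cur:
                    continue
                c = 1.5 * usage.get(v, 0) + (25.0 if v in special else 0.0)
                c += 8.0 * len(t.vertices[v].member_rings - set(ring_seq))
                c += 0.01 * (pool.index(v) if v in pool_set else len(pool))
                gain = cur - s
                if best_move is None or (-gain, c) < (-best_move[2], best_move[3]):
                    best_move = (atom, v, gain, c)
        if best_move is None:
            break
        atom, v, _, _ = best_move
        usage[assignment[atom][0]] -= 1
        put(atom, v, assignment[atom][1])

    return AtomPlacement(
        ligand=g,
        assignment=assignment,
        bond_tolerance=tolerance,
        notation=path,
    )
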