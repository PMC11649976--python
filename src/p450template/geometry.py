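"""Canonical Template geometry: the fused hexagonal grid of the CYP2J2 model.

A Template is a 2D fused honeycomb describing the ligand-accessible space of a
CYP active site.  Hexagon cells ("Rings", labelled A-U plus edge extensions
eB..eU) share corners ("Positions", numbered 1-54 plus primed border anchors
such as 11', 49', 54').  Ligand heavy atoms sit on Positions; named regions
(Site of oxidation, Shelf, Left-end, Entrance) and a slab of allowable depth
between the Facial- and Rear-walls (the Width-gauge, 1.5 Ring-size for CYP2J2)
constrain and score placements.

The canonical CYP2J2 grid ships as ``data/cyp2j2.yaml``; the loader is
bit-exact on labels and validates the geometric invariants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

__all__ = [
    "GridVertex",
    "TemplateGrid",
    "TemplateError",
    "load_template",
    "load_canonical_template",
    "validate_template",
    "ring_vertices",
    "region_membership",
    "serialize_template",
    "trim_template",
]

EDGE_LENGTH = 1.0 / math.sqrt(3.0)  # honeycomb edge for Ring-size = 1.0

FEATURES = frozenset({
    "on_shelf_edge",
    "on_left_end",
    "in_site_of_oxidation",
    "entrance_anchor",
    "under_shelf",
})


class TemplateError(ValueError):
    """Malformed template document or dangling cross-reference."""


@dataclass(frozen=True)
class GridVertex:
    label: str
    x: float
    y: float
    member_rings: frozenset[str] = frozenset()
    features: frozenset[str] = frozenset()


@dataclass
class TemplateGrid:
    """The canonical grid plus every named structural feature.

    ``rings`` maps each ring label to its 6-cycle of vertex labels, clockwise
    from the upper-left shoulder.  Depths are in Ring-size units with the
    Facial-wall at ``facial_depth`` and the Rear-wall at ``rear_depth``;
    their difference is the Width-gauge.
    """

    name: str
    vertices: dict[str, GridVertex]
    rings: dict[str, list[str]]
    width_gauge: float
    facial_depth: float
    rear_depth: float
    shelf_edge: list[str]
    shelf_forbidden: list[str]
    left_end: list[str]
    entrance: tuple[str, str]
    site_of_oxidation: frozenset[str]
    trigger_path: list[str]
    trigger_pillar: tuple[float, float, float]
    pillar_rings: list[str]
    heme_access: str = "rear"
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)
    _dist: dict | None = field(default=None, repr=False, compare=False)

    # -- derived structure -------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """Lattice graph: vertices, with ring-cycle edges."""
        if self._graph is None:
            g = nx.Graph()
            for v in self.vertices.values():
                g.add_node(v.label, x=v.x, y=v.y)
            for cycle in self.rings.values():
                for a, b in zip(cycle, cycle[1:] + cycle[:1]):
                    g.add_edge(a, b)
            self._graph = g
        return self._graph

    def lattice_distance(self, a: str, b: str) -> int:
        if self._dist is None:
            self._dist = {}
        key = (a, b) if a <= b else (b, a)
        hit = self._dist.get(key)
        if hit is None:
            try:
                hit = nx.shortest_path_length(self.graph, a, b)
            except nx.NetworkXNoPath:
                hit = 10**6
            self._dist[key] = hit
        return hit

    def rings_of(self, vertex: str) -> frozenset[str]:
        return self.vertices[vertex].member_rings

    def rings_occupied_by(self, vertex_labels: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for v in vertex_labels:
            out |= self.vertices[v].member_rings
        return out

    def ring_center_x(self, ring: str) -> float:
        vs = self.rings[ring]
        return sum(self.vertices[v].x for v in vs) / len(vs)

    def numbered_positions(self) -> list[str]:
        return sorted((v for v in self.vertices if v.isdigit()), key=int)

    def depth_bucket_bounds(self) -> tuple[float, float]:
        """(facial/mid, mid/rear) z boundaries splitting the slab in thirds."""
        third = (self.rear_depth - self.facial_depth) / 3.0
        return self.facial_depth + third, self.rear_depth - third


# -- loading ---------------------------------------------------------------


def _require(doc: Mapping, key: str):
    if key not in doc:
        raise TemplateError(f"template document missing field {key!r}")
    return doc[key]


def load_template(source: str | Path | Mapping) -> TemplateGrid:
    """Load a TemplateGrid from YAML text, a file path, or a parsed mapping.

    Raises :class:`TemplateError` naming the offending field on malformed
    documents or dangling labels, and validates all grid invariants.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        try:
            path = Path(source)
            text = path.read_text() if path.exists() else str(source)
        except OSError:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise TemplateError("template document is not a mapping")

    raw_vertices = _require(doc, "vertices")
    raw_rings = _require(doc, "rings")

    seen: set[str] = set()
    verts: dict[str, GridVertex] = {}
    for rec in raw_vertices:
        try:
            label = str(rec["label"])
            x = float(rec["x"])
            y = float(rec["y"])
        except (KeyError, TypeError, ValueError) as exc:
            raise TemplateError(f"malformed vertex record {rec!r}") from exc
        if label in seen:
            raise TemplateError(f"duplicate vertex label {label!r}")
        seen.add(label)
        feats = frozenset(rec.get("features") or ())
        unknown = feats - FEATURES
        if unknown:
            raise TemplateError(f"vertex {label!r}: unknown features {sorted(unknown)}")
        verts[label] = GridVertex(label=label, x=x, y=y, features=feats)

    rings: dict[str, list[str]] = {}
    member: dict[str, set[str]] = {v: set() for v in verts}
    for ring, cycle in raw_rings.items():
        cycle = [str(v) for v in cycle]
        if len(cycle) != 6:
            raise TemplateError(f"ring {ring!r} references {len(cycle)} vertices, expected 6")
        for v in cycle:
            if v not in verts:
                raise TemplateError(f"ring {ring!r} references unknown vertex {v!r}")
            member[v].add(ring)
        rings[str(ring)] = cycle

    verts = {
        lbl: GridVertex(lbl, v.x, v.y, frozenset(member[lbl]), v.features)
        for lbl, v in verts.items()
    }

    shelf = doc.get("shelf") or {}
    entrance = [str(v) for v in _require(doc, "entrance")]
    if len(entrance) != 2:
        raise TemplateError("entrance must name exactly two anchor vertices")

    grid = TemplateGrid(
        name=str(_require(doc, "name")),
        vertices=verts,
        rings=rings,
        width_gauge=float(_require(doc, "width_gauge")),
        facial_depth=float(_require(doc, "facial_depth")),
        rear_depth=float(_require(doc, "rear_depth")),
        shelf_edge=[str(v) for v in shelf.get("edge", ())],
        shelf_forbidden=[str(v) for v in shelf.get("forbidden", ())],
        left_end=[str(v) for v in doc.get("left_end", ())],
        entrance=(entrance[0], entrance[1]),
        site_of_oxidation=frozenset(str(v) for v in _require(doc, "site_of_oxidation")),
        trigger_path=[str(r) for r in _require(doc, "trigger_path")],
        trigger_pillar=tuple(float(v) for v in _require(doc, "trigger_pillar")),
        pillar_rings=[str(r) for r in doc.get("pillar_rings", ("K", "J"))],
        heme_access=str(doc.get("heme_access", "rear")),
    )
    for lst, what in [
        (grid.shelf_edge, "shelf.edge"),
        (grid.shelf_forbidden, "shelf.forbidden"),
        (grid.left_end, "left_end"),
        (list(grid.entrance), "entrance"),
        (sorted(grid.site_of_oxidation), "site_of_oxidation"),
    ]:
        for v in lst:
            if v not in verts:
                raise TemplateError(f"{what} references unknown vertex {v!r}")
    problems = validate_template(grid)
    if problems:
        raise TemplateError("invalid template: " + "; ".join(problems))
    return grid


def load_canonical_template() -> TemplateGrid:
    """The packaged canonical CYP2J2 Template."""
    ref = resources.files("p450template").joinpath("data/cyp2j2.yaml")
    return load_template(yaml.safe_load(ref.read_text()))


# -- validation ------------------------------------------------------------


def validate_template(t: TemplateGrid, tol: float = 1e-9) -> list[str]:
    """Return violation descriptors (empty list means all invariants hold)."""
    out: list[str] = []
    if abs((t.rear_depth - t.facial_depth) - t.width_gauge) > tol:
        out.append(
            f"width_gauge: rear_depth-facial_depth = {t.rear_depth - t.facial_depth}"
            f" != width_gauge {t.width_gauge}"
        )
    for ring in t.trigger_path:
        if ring not in t.rings:
            out.append(f"trigger_path: unknown ring {ring!r}")
    if "A" in t.trigger_path:
        out.append("trigger_path: the Trigger-residue may never enter Ring A")
    xs = [t.ring_center_x(r) for r in t.trigger_path if r in t.rings]
    if any(b >= a for a, b in zip(xs, xs[1:])):
        out.append("trigger_path: ring order is not strictly right-to-left in x")
    for v in t.site_of_oxidation:
        if v not in t.vertices:
            out.append(f"site_of_oxidation: unknown vertex {v!r}")
    for name, lst in [("shelf_edge", t.shelf_edge), ("left_end", t.left_end)]:
        for v in lst:
            if v not in t.vertices:
                out.append(f"{name}: unknown vertex {v!r}")
    for ring, cycle in t.rings.items():
        if len(set(cycle)) != 6:
            out.append(f"ring {ring!r}: not six distinct vertices")
            continue
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            va, vb = t.vertices.get(a), t.vertices.get(b)
            if va is None or vb is None:
                out.append(f"ring {ring!r}: dangling vertex")
                break
            d = math.hypot(va.x - vb.x, va.y - vb.y)
            if abs(d - EDGE_LENGTH) > 1e-9:
                out.append(
                    f"ring {ring!r}: edge {a}-{b} has length {d:.9f},"
                    f" expected {EDGE_LENGTH:.9f}"
                )
                break
    if len(t.trigger_pillar) != 3:
        out.append("trigger_pillar: expected three diameters")
    return out


# -- queries ---------------------------------------------------------------


def ring_vertices(t: TemplateGrid, ring: str) -> list[str]:
    """The 6-cycle of a ring, clockwise from the upper-left shoulder."""
    if ring not in t.rings:
        raise KeyError(f"unknown ring label {ring!r}")
    return list(t.rings[ring])


def region_membership(t: TemplateGrid, vertex: str) -> frozenset[str]:
    if vertex not in t.vertices:
        raise KeyError(f"unknown vertex label {vertex!r}")
    return t.vertices[vertex].features


# -- serialization / derivation -------------------------------------------


def serialize_template(t: TemplateGrid) -> str:
    """YAML round-trip form; ``load_template(serialize_template(t))`` == t."""
    doc = {
        "name": t.name,
        "width_gauge": t.width_gauge,
        "facial_depth": t.facial_depth,
        "rear_depth": t.rear_depth,
        "vertices": [
            {
                "label": v.label,
                "x": v.x,
                "y": v.y,
                "features": sorted(v.features),
            }
            for v in sorted(t.vertices.values(), key=lambda v: (v.y, v.x))
        ],
        "rings": {r: list(c) for r, c in sorted(t.rings.items())},
        "site_of_oxidation": sorted(t.site_of_oxidation),
        "shelf": {"edge": list(t.shelf_edge), "forbidden": list(t.shelf_forbidden)},
        "left_end": list(t.left_end),
        "entrance": list(t.entrance),
        "trigger_path": list(t.trigger_path),
        "trigger_pillar": list(t.trigger_pillar),
        "pillar_rings": list(t.pillar_rings),
        "heme_access": t.heme_access,
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def trim_template(t: TemplateGrid, rings: Iterable[str], name: str | None = None) -> TemplateGrid:
    """Sub-template restricted to the given rings (used for small exhaustive
    searches and tests).  Region metadata is intersected with the kept rings."""
    keep = [r for r in t.rings if r in set(rings)]
    missing = set(rings) - set(keep)
    if missing:
        raise KeyError(f"unknown ring labels {sorted(missing)}")
    kept_vertices = {v for r in keep for v in t.rings[r]}
    verts = {}
    for lbl in kept_vertices:
        v = t.vertices[lbl]
        member = frozenset(m for m in v.member_rings if m in keep)
        verts[lbl] = GridVertex(lbl, v.x, v.y, member, v.features)
    path = [r for r in t.trigger_path if r in keep]
    return TemplateGrid(
        name=name or f"{t.name}-trimmed",
        vertices=verts,
        rings={r: list(t.rings[r]) for r in keep},
        width_gauge=t.width_gauge,
        facial_depth=t.facial_depth,
        rear_depth=t.rear_depth,
        shelf_edge=[v for v in t.shelf_edge if v in kept_vertices],
        shelf_forbidden=[v for v in t.shelf_forbidden if v in kept_vertices],
        left_end=[v for v in t.left_end if v in kept_vertices],
        entrance=t.entrance if all(v in kept_vertices for v in t.entrance) else ("", ""),
        site_of_oxidation=frozenset(v for v in t.site_of_oxidation if v in kept_vertices),
        trigger_path=path,
        trigger_pillar=t.trigger_pillar,
        pillar_rings=[r for r in t.pillar_rings if r in keep],
        heme_access=t.heme_access,
    )
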