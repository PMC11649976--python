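"""Interaction rules: evaluate an atom-level placement into a Verdict.

A placement assigns each heavy atom a grid vertex and a depth bucket within
the Width-gauge slab (facial / mid / rear).  Wall "contact" is discrete: an
atom contacts the Rear-wall iff its bucket is ``rear`` and the Facial-wall
iff ``facial``.  The rules:

R_WIDTH        every atom inside the slab (no out-of-slab atoms)      [gate]
R_PLURAL_REAR  >= 2 non-lactone atoms contact the Rear-wall           [gate]
R_RING_B       ring occupancy includes Ring B                         [gate]
R_SITE         >= 1 oxidizable atom on a Site-of-oxidation vertex     [gate]
R_TRIGGER      the Trigger-residue fastened the ligand                [gate]
R_LACTONE      no lactone-like ring atom rear-bucketed / trigger-hit  [gate]
R_LEFT_END     >= 1 atom on the Left-end polyline              [gate, relaxable]
R_DESCENT      the placement can descend from the Entrance     [gate, relaxable]
R_FACIAL       Facial-wall contact                              [stabilizing]
R_SHELF        no atom under the Shelf; edge contact is stabilizing   [gate]

A placement failing R_WIDTH is no ligand of the template at all
(NON_LIGAND); one failing another mandatory gate is a POOR_SUBSTRATE.  A
heme-ligating heteroatom parked on the Site of oxidation, with no oxidizable
atom sharing the site, marks an INHIBITOR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Callable, Iterable, Mapping

from .geometry import TemplateGrid
from .ligand import LigandGraph
from .notation import RingPath

if TYPE_CHECKING:  # pragma: no cover
    from .trigger import TriggerState

__all__ = [
    "Depth",
    "Category",
    "AtomPlacement",
    "RuleResult",
    "Verdict",
    "RuleConfig",
    "check_width",
    "check_plural_rear_contact",
    "check_ring_b",
    "check_site_occupancy",
    "check_left_end",
    "check_shelf",
    "check_facial",
    "check_lactone",
    "check_descent",
    "evaluate_placement",
]


class Depth(str, Enum):
    FACIAL = "facial"
    MID = "mid"
    REAR = "rear"


class Category(str, Enum):
    GOOD_SUBSTRATE = "GOOD_SUBSTRATE"
    POOR_SUBSTRATE = "POOR_SUBSTRATE"
    INHIBITOR = "INHIBITOR"
    NON_LIGAND = "NON_LIGAND"


@dataclass
class AtomPlacement:
    """Atom -> (vertex, depth bucket) assignment bound to a template.

    ``out_of_slab`` lists atoms that could not be kept inside the
    Width-gauge (an oversized ligand); a placement with such atoms fails
    R_WIDTH.  Bonded atoms must sit on the same vertex or within
    ``bond_tolerance`` lattice steps (atoms "not exactly at the corner" are
    accepted).
    """

    ligand: LigandGraph
    assignment: dict[int, tuple[str, Depth]]
    out_of_slab: frozenset[int] = frozenset()
    bond_tolerance: int = 2
    notation: RingPath | None = None

    def vertices(self) -> set[str]:
        return {v for v, _ in self.assignment.values()}

    def atoms_at(self, vertex_labels: Iterable[str]) -> set[int]:
        want = set(vertex_labels)
        return {i for i, (v, _) in self.assignment.items() if v in want}

    def atoms_with_depth(self, depth: Depth) -> set[int]:
        return {i for i, (_, d) in self.assignment.items() if d == depth}

    def rings_occupied(self, t: TemplateGrid) -> set[str]:
        return t.rings_occupied_by(self.vertices())

    def validate(self, t: TemplateGrid) -> list[str]:
        """Structural violations: unknown vertices, under-Shelf sitting,
        bond adjacency beyond tolerance."""
        out: list[str] = []
        forbidden = set(t.shelf_forbidden)
        for i, (v, d) in self.assignment.items():
            if v not in t.vertices:
                out.append(f"atom {i}: unknown vertex {v!r}")
            elif v in forbidden:
                out.append(f"atom {i}: vertex {v} is under the Shelf")
            if not isinstance(d, Depth):
                out.append(f"atom {i}: bad depth bucket {d!r}")
        for a, b, _ in self.ligand.bonds:
            if a not in self.assignment or b not in self.assignment:
                continue
            va, vb = self.assignment[a][0], self.assignment[b][0]
            if va == vb:
                continue
            if t.lattice_distance(va, vb) > self.bond_tolerance:
                out.append(
                    f"bond {a}-{b}: vertices {va},{vb} farther than"
                    f" tolerance {self.bond_tolerance}"
                )
        return out


@dataclass(frozen=True)
class RuleResult:
    rule_id: str
    passed: bool
    evidence: frozenset[tuple[int, str]] = frozenset()
    note: str = ""
    mandatory: bool = True


@dataclass
class Verdict:
    category: Category
    rule_results: list[RuleResult]
    predicted_sites: frozenset[int]
    score: float
    trigger_state: "TriggerState | None" = None

    def result(self, rule_id: str) -> RuleResult:
        for r in self.rule_results:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def failed_rules(self) -> set[str]:
        return {r.rule_id for r in self.rule_results if not r.passed}

    def as_dict(self) -> dict:
        return {
            "category": self.category.value,
            "score": self.score,
            "predicted_sites": sorted(self.predicted_sites),
            "rules": [
                {
                    "rule": r.rule_id,
                    "passed": r.passed,
                    "mandatory": r.mandatory,
                    "evidence": sorted(r.evidence),
                    "note": r.note,
                }
                for r in self.rule_results
            ],
            "trigger": None
            if self.trigger_state is None
            else {
                "fastened": self.trigger_state.fastened,
                "final_ring": self.trigger_state.final_ring,
                "contacted_atoms": sorted(self.trigger_state.contacted_atoms),
                "pillar_support": self.trigger_state.pillar_support,
            },
        }


@dataclass
class RuleConfig:
    """Gate set and score weights.

    Defaults follow the CYP2J2 rule set: Width-gauge, plural Rear-wall
    contact, Ring-B occupancy, Site occupancy, Trigger fastening and the
    lactone restriction are mandatory; Left-end and descent are mandatory by
    default but relaxable; Facial-wall and Shelf contacts only stabilize.
    Score weights are model constants, not fitted quantities.
    """

    left_end_mandatory: bool = True
    descent_mandatory: bool = True
    ring_b_mandatory: bool = True
    weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "rear": 2.0,
            "facial": 1.0,
            "shelf": 1.0,
            "left_end": 2.0,
            "site": 3.0,
            "pillar": 1.0,
        }
    )


def _ev(pairs: Iterable[tuple[int, str]]) -> frozenset[tuple[int, str]]:
    return frozenset(pairs)


def _require_bound(p: AtomPlacement, t: TemplateGrid) -> None:
    if not p.assignment:
        return
    unknown = {v for v, _ in p.assignment.values()} - set(t.vertices)
    if unknown:
        raise RuntimeError(f"placement not bound to template: unknown vertices {sorted(unknown)}")


def check_width(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """All atoms held between Facial- and Rear-walls (inside the Width-gauge)."""
    _require_bound(p, t)
    bad = sorted(p.out_of_slab) + sorted(
        i for i, (_, d) in p.assignment.items() if not isinstance(d, Depth)
    )
    ev = _ev((i, p.assignment[i][0]) if i in p.assignment else (i, "?") for i in bad)
    return RuleResult("R_WIDTH", not bad, ev, "atoms outside the Width-gauge" if bad else "")


def check_plural_rear_contact(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """Simultaneous plural contact: >= 2 non-lactone atoms on the Rear-wall."""
    lact = p.ligand.annotation("lactone_ring_atom")
    rear = sorted(p.atoms_with_depth(Depth.REAR) - lact)
    ok = len(rear) >= 2
    return RuleResult(
        "R_PLURAL_REAR",
        ok,
        _ev((i, p.assignment[i][0]) for i in rear),
        f"{len(rear)} non-lactone Rear-wall contacts",
    )


def check_ring_b(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """Occupancy of Ring B: required for fastening and hence metabolism."""
    b = set(t.rings.get("B", ()))
    atoms = sorted(p.atoms_at(b))
    return RuleResult(
        "R_RING_B",
        bool(atoms),
        _ev((i, p.assignment[i][0]) for i in atoms),
        "" if atoms else "no occupancy at Ring B",
    )


def check_site_occupancy(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """An oxidizable atom sits in the Site of oxidation (positions 2-4)."""
    cand = p.ligand.annotation("candidate_oxidation_site")
    atoms = sorted(p.atoms_at(t.site_of_oxidation) & cand)
    return RuleResult(
        "R_SITE",
        bool(atoms),
        _ev((i, p.assignment[i][0]) for i in atoms),
        "" if atoms else "no oxidizable atom at the Site of oxidation",
    )


def check_left_end(p: AtomPlacement, t: TemplateGrid, cfg: RuleConfig | None = None) -> RuleResult:
    """Fixation at the Left-end border polyline."""
    cfg = cfg or RuleConfig()
    atoms = sorted(p.atoms_at(t.left_end))
    return RuleResult(
        "R_LEFT_END",
        bool(atoms),
        _ev((i, p.assignment[i][0]) for i in atoms),
        "" if atoms else "no Left-end contact",
        mandatory=cfg.left_end_mandatory,
    )


def check_shelf(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """No atom under the Shelf; contacts on its top edge are stabilizing."""
    under = sorted(p.atoms_at(t.shelf_forbidden))
    edge = sorted(p.atoms_at(t.shelf_edge))
    return RuleResult(
        "R_SHELF",
        not under,
        _ev((i, p.assignment[i][0]) for i in (under if under else edge)),
        "atoms under the Shelf" if under else f"{len(edge)} Shelf-edge contacts",
    )


def check_facial(p: AtomPlacement, t: TemplateGrid) -> RuleResult:
    """Facial-wall contact (stabilizing only)."""
    atoms = sorted(p.atoms_with_depth(Depth.FACIAL))
    return RuleResult(
        "R_FACIAL",
        bool(atoms),
        _ev((i, p.assignment[i][0]) for i in atoms),
        f"{len(atoms)} Facial-wall contacts",
        mandatory=False,
    )


def check_lactone(
    p: AtomPlacement,
    t: TemplateGrid,
    trigger_contacts: frozenset[int] = frozenset(),
) -> RuleResult:
    """Non-rigid lactone-like rings keep off the Rear-wall and the Trigger."""
    lact = p.ligand.annotation("lactone_ring_atom")
    bad = sorted((p.atoms_with_depth(Depth.REAR) & lact) | (set(trigger_contacts) & lact))
    return RuleResult(
        "R_LACTONE",
        not bad,
        _ev((i, p.assignment[i][0]) for i in bad if i in p.assignment),
        "lactone-like ring touches Rear-wall/Trigger" if bad else "",
    )


def check_descent(p: AtomPlacement, t: TemplateGrid, cfg: RuleConfig | None = None) -> RuleResult:
    """The conformer must be able to slide down from the Entrance without
    conformational change: a straight vertical descent is blocked only by the
    Shelf plateau, so no atom may end in the pocket beneath it."""
    cfg = cfg or RuleConfig()
    if not t.shelf_forbidden and not t.shelf_edge:
        return RuleResult("R_DESCENT", True, frozenset(), "no Shelf on this template",
                          mandatory=cfg.descent_mandatory)
    shelf_y = max((t.vertices[v].y for v in t.shelf_edge), default=0.0)
    shelf_x = [t.vertices[v].x for v in t.shelf_edge]
    lo, hi = (min(shelf_x), max(shelf_x)) if shelf_x else (0.0, 0.0)
    hi -= 0.5  # the pocket stops at the A/E junction column
    blocked = sorted(
        i
        for i, (v, _) in p.assignment.items()
        if lo - 1e-9 < t.vertices[v].x < hi - 1e-9 and t.vertices[v].y < shelf_y - 1e-9
    )
    return RuleResult(
        "R_DESCENT",
        not blocked,
        _ev((i, p.assignment[i][0]) for i in blocked),
        "atoms cannot descend past the Shelf" if blocked else "",
        mandatory=cfg.descent_mandatory,
    )


def _score(p: AtomPlacement, t: TemplateGrid, results: dict[str, RuleResult],
           pillar: bool, cfg: RuleConfig) -> float:
    w = cfg.weights
    rear = len(p.atoms_with_depth(Depth.REAR) - p.ligand.annotation("lactone_ring_atom"))
    facial = len(p.atoms_with_depth(Depth.FACIAL))
    shelf = len(p.atoms_at(t.shelf_edge))
    left = len(p.atoms_at(t.left_end))
    site = len(results["R_SITE"].evidence)
    score = (
        w.get("rear", 0) * rear
        + w.get("facial", 0) * facial
        + w.get("shelf", 0) * shelf
        + w.get("left_end", 0) * left
        + w.get("site", 0) * site
        + (w.get("pillar", 0) if pillar else 0.0)
    )
    return float(score)


def evaluate_placement(
    p: AtomPlacement,
    t: TemplateGrid,
    trigger_state: "TriggerState | None" = None,
    cfg: RuleConfig | None = None,
) -> Verdict:
    """Run every rule and classify the placement.

    ``trigger_state`` should come from :func:`p450template.trigger.simulate_trigger`
    on the same placement; if omitted it is computed here.
    """
    cfg = cfg or RuleConfig()
    _require_bound(p, t)
    if trigger_state is None:
        from .trigger import simulate_trigger

        trigger_state = simulate_trigger(p, t)

    checks: dict[str, Callable[[], RuleResult]] = {
        "R_WIDTH": lambda: check_width(p, t),
        "R_PLURAL_REAR": lambda: check_plural_rear_contact(p, t),
        "R_RING_B": lambda: check_ring_b(p, t),
        "R_SITE": lambda: check_site_occupancy(p, t),
        "R_LEFT_END": lambda: check_left_end(p, t, cfg),
        "R_SHELF": lambda: check_shelf(p, t),
        "R_FACIAL": lambda: check_facial(p, t),
        "R_LACTONE": lambda: check_lactone(p, t, frozenset(trigger_state.contacted_atoms)),
        "R_DESCENT": lambda: check_descent(p, t, cfg),
    }
    results = {rid: fn() for rid, fn in checks.items()}
    results["R_TRIGGER"] = RuleResult(
        "R_TRIGGER",
        trigger_state.fastened,
        _ev(
            (i, p.assignment[i][0])
            for i in sorted(trigger_state.contacted_atoms)
            if i in p.assignment
        ),
        f"Trigger-residue stopped at Ring {trigger_state.final_ring}",
    )

    site_atoms = {i for i, _ in results["R_SITE"].evidence}
    heme = p.ligand.annotation("heme_ligating_heteroatom")
    # only nitrogen ligators block the site: a thioether S parked there is
    # S-oxidized rather than iron-bound
    heme_n = {i for i in heme if p.ligand.atoms[i].element == "N"}
    heme_at_site = sorted(p.atoms_at(t.site_of_oxidation) & heme_n)
    oxidizable_at_site = site_atoms - set(heme_at_site)

    mandatory = ["R_WIDTH", "R_PLURAL_REAR", "R_SITE", "R_LACTONE", "R_SHELF"]
    if cfg.ring_b_mandatory:
        # Ring-B occupancy and Trigger fastening are two facets of the same
        # mechanism (the residue reaches at most Ring B); an ablation of the
        # minimal-occupancy rule removes both
        mandatory.extend(["R_RING_B", "R_TRIGGER"])
    if cfg.left_end_mandatory:
        mandatory.append("R_LEFT_END")
    if cfg.descent_mandatory:
        mandatory.append("R_DESCENT")

    if not results["R_WIDTH"].passed:
        category = Category.NON_LIGAND
        predicted: frozenset[int] = frozenset()
    elif heme_at_site and not oxidizable_at_site:
        # a heme-ligating heteroatom occupies the site and nothing there can
        # be oxidized: the molecule blocks rather than turns over
        category = Category.INHIBITOR
        predicted = frozenset()
    elif all(results[r].passed for r in mandatory):
        category = Category.GOOD_SUBSTRATE
        predicted = frozenset(oxidizable_at_site)
    else:
        category = Category.POOR_SUBSTRATE
        predicted = frozenset()

    order = [
        "R_WIDTH", "R_PLURAL_REAR", "R_RING_B", "R_SITE", "R_TRIGGER",
        "R_LACTONE", "R_LEFT_END", "R_SHELF", "R_DESCENT", "R_FACIAL",
    ]
    rule_results = [results[r] for r in order]
    score = _score(p, t, results, trigger_state.pillar_support, cfg)
    return Verdict(
        category=category,
        rule_results=rule_results,
        predicted_sites=predicted,
        score=score,
        trigger_state=trigger_state,
    )
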