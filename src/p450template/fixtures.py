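"""Packaged worked-example fixtures and the concordance suite.

``data/fixtures.yaml`` transcribes the published CYP2J2 worked placements:
the 24 reaction records of the Template construction set, plus the
additional ligands of the results narrative (inhibitors, slender and bent
ligands, endobiotics, bi-molecule partners).  Each record carries the ligand
name and reaction, a transcribed SMILES, the ring-path notation where one
was printed, the expected classification, and the atom-level anchor pins
("this atom at that Position, at that depth") that encode the described
contacts.  ``run_fixture_suite`` realizes every placeable record and checks
that the rule engine reproduces the expected category (and site, where the
record pins one).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

from .geometry import TemplateGrid, load_canonical_template
from .ligand import LigandGraph, load_ligand
from .notation import RingPath, parse_placement
from .placing import Pin, realize_placement
from .rules import AtomPlacement, Category, Depth, RuleConfig, Verdict, evaluate_placement
from .trigger import simulate_trigger

__all__ = [
    "FixtureRecord",
    "FixtureReportRow",
    "load_fixture_set",
    "run_fixture_suite",
    "generate_toy_ligands",
]


def _depth(s: str | None) -> Depth | None:
    return None if s is None else Depth(s)


@dataclass
class FixtureRecord:
    ligand: str
    reaction: str
    group: str  # "construction" | "additional"
    smiles: str
    source: str
    notation: str | None = None
    category: Category | None = None
    contacts: str = ""
    structure_approx: bool = False
    site: dict | None = None  # {smarts|atom, vertex, depth} - also the expected site
    pins: list[dict] = field(default_factory=list)
    rear: list[str] = field(default_factory=list)
    facial: list[str] = field(default_factory=list)
    _graph: LigandGraph | None = field(default=None, repr=False)

    @property
    def key(self) -> str:
        return f"{self.ligand} {self.reaction}"

    def load(self) -> LigandGraph:
        if self._graph is None:
            self._graph = load_ligand(self.smiles, name=self.ligand)
        return self._graph

    def ring_path(self, t: TemplateGrid | None = None) -> RingPath | None:
        if self.notation is None:
            return None
        return parse_placement(self.notation, set(t.rings) if t else None)

    def all_pins(self) -> list[Pin]:
        raw = ([self.site] if self.site else []) + list(self.pins)
        return [
            Pin(
                vertex=str(p["vertex"]),
                depth=_depth(p.get("depth")),
                smarts=p.get("smarts"),
                atom=p.get("atom"),
                select=int(p.get("select", 0)),
            )
            for p in raw
        ]

    def realize(self, t: TemplateGrid) -> AtomPlacement | None:
        path = self.ring_path(t)
        if path is None:
            return None
        return realize_placement(
            self.load(), path, t, pins=self.all_pins(), rear=self.rear, facial=self.facial
        )

    def expected_site_atoms(self) -> frozenset[int]:
        if not self.site:
            return frozenset()
        pin = self.all_pins()[0]
        return frozenset({pin.resolve(self.load())})


def load_fixture_set(validate: bool = True) -> list[FixtureRecord]:
    """All packaged fixture records; gate: every notation parses and every
    SMILES loads."""
    ref = resources.files("p450template").joinpath("data/fixtures.yaml")
    doc = yaml.safe_load(ref.read_text())
    records: list[FixtureRecord] = []
    for group in ("construction", "additional"):
        for raw in doc.get(group, ()):
            rec = FixtureRecord(
                ligand=raw["ligand"],
                reaction=raw["reaction"],
                group=group,
                smiles=raw["smiles"],
                source=raw.get("source", ""),
                notation=raw.get("notation"),
                category=Category(raw["category"]) if raw.get("category") else None,
                contacts=raw.get("contacts", ""),
                structure_approx=bool(raw.get("structure_approx", False)),
                site=raw.get("site"),
                pins=list(raw.get("pins", ())),
                rear=list(raw.get("rear", ())),
                facial=list(raw.get("facial", ())),
            )
            if validate:
                rec.load()
                if rec.notation is not None:
                    parse_placement(rec.notation)
            records.append(rec)
    return records


@dataclass
class FixtureReportRow:
    ligand: str
    reaction: str
    expected: str | None
    got: str | None
    category_ok: bool | None
    site_ok: bool | None
    failed_rules: list[str]
    score: float | None
    note: str = ""


def run_fixture_suite(
    t: TemplateGrid | None = None,
    records: Iterable[FixtureRecord] | None = None,
    cfg: RuleConfig | None = None,
    disable_ring_b: bool = False,
) -> list[FixtureReportRow]:
    """Evaluate every placeable record and compare against expectations.

    ``disable_ring_b`` ablates the minimal-occupancy mechanism (the Ring-B
    gate together with the Trigger fastening it mediates) as a negative
    control: with it off, the thalidomide-class discrimination collapses.
    """
    t = t or load_canonical_template()
    records = list(records if records is not None else load_fixture_set())
    if cfg is None:
        cfg = RuleConfig()
    if disable_ring_b:
        cfg = RuleConfig(
            left_end_mandatory=cfg.left_end_mandatory,
            descent_mandatory=cfg.descent_mandatory,
            ring_b_mandatory=False,
            weights=cfg.weights,
        )
    rows: list[FixtureReportRow] = []
    for rec in records:
        if rec.notation is None:
            rows.append(
                FixtureReportRow(
                    rec.ligand, rec.reaction, None, None, None, None, [], None,
                    "no printed placement; record is exercised by the search smoke tests",
                )
            )
            continue
        placement = rec.realize(t)
        state = simulate_trigger(placement, t)
        verdict = evaluate_placement(placement, t, state, cfg)
        expected = rec.category.value if rec.category else None
        got = verdict.category.value
        cat_ok = None if expected is None else (got == expected)
        site_ok: bool | None = None
        if rec.site and rec.category is Category.GOOD_SUBSTRATE and not rec.structure_approx:
            site_ok = bool(rec.expected_site_atoms() & verdict.predicted_sites)
        rows.append(
            FixtureReportRow(
                rec.ligand,
                rec.reaction,
                expected,
                got,
                cat_ok,
                site_ok,
                sorted(
                    r.rule_id
                    for r in verdict.rule_results
                    if not r.passed and r.mandatory
                ),
                verdict.score,
            )
        )
    return rows


def concordance(rows: Iterable[FixtureReportRow]) -> tuple[int, int]:
    """(matches, comparisons) over rows that carry an expectation."""
    rows = [r for r in rows if r.category_ok is not None]
    return sum(r.category_ok for r in rows), len(rows)


# -- toy ligands for property tests ---------------------------------------

_ELEMENTS = ["C", "C", "C", "N", "O", "S"]


def generate_toy_ligands(n: int, seed: int = 0) -> list[LigandGraph]:
    """Deterministic family of small test graphs: chains (2-6 atoms), single
    rings (5-6) and ring-plus-tail graphs, with randomized heteroatoms."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    out: list[LigandGraph] = []
    for i in range(n):
        kind = i % 3
        if kind == 0:  # chain; the first family member is the 2-atom chain
            length = 2 + (i // 3) % 5
            smiles = "".join(
                rng.choice(_ELEMENTS) if k > 0 else "C" for k in range(length)
            )
        elif kind == 1:  # single ring
            size = 5 + (i // 3) % 2
            hetero = rng.choice(["", "O", "N"])
            body = "C" * (size - 1 - len(hetero))
            smiles = f"C1{hetero}{body}1"
        else:  # ring plus tail
            size = 5 + (i // 3) % 2
            tail = rng.choice(["C", "CC", "O", "N"])
            smiles = f"C1{'C' * (size - 1)}1{tail}"
        out.append(load_ligand(smiles, name=f"toy-{i}"))
    return out
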