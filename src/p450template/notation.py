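"""Hyphen-linked ring-path notation.

Placements are written as hyphen-linked ring labels, e.g. ``A-B-C``; a
branching part is given in brackets after the ring it hangs from, e.g.
``A(B)-E(G)-eE-F-L``; a slash marks alternative rings that are equally
acceptable, e.g. ``A-E(D/eE)-F(eL)-L``.  An optional leading ``Rings `` prefix
and whitespace are ignored.  Nested brackets do not occur and are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["RingPath", "NotationError", "parse_placement", "serialize_placement", "rings_occupied"]

_LABEL_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*")


class NotationError(ValueError):
    """Parse failure; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


# A branch token is an ordered list of steps; each step is a tuple of
# alternative ring labels (len 1 unless a slash was used).
Step = tuple[str, ...]


@dataclass(frozen=True)
class RingPath:
    """Parsed ring path: main chain, branches keyed by main index, raw text."""

    main: tuple[Step, ...]
    branches: tuple[tuple[int, tuple[Step, ...]], ...] = ()
    raw: str = field(default="", compare=False)

    def main_labels(self) -> list[str]:
        """First alternative of each main step."""
        return [step[0] for step in self.main]

    def branch_map(self) -> dict[int, list[list[Step]]]:
        out: dict[int, list[list[Step]]] = {}
        for idx, token in self.branches:
            out.setdefault(idx, []).append(list(token))
        return out

    def all_labels(self) -> set[str]:
        labels = {alt for step in self.main for alt in step}
        for _, token in self.branches:
            labels |= {alt for step in token for alt in step}
        return labels

    def alternative_labels(self) -> set[str]:
        """Labels that appear only as slash alternatives (weak occupancy)."""
        out = set()
        for step in self.main:
            if len(step) > 1:
                out |= set(step)
        for _, token in self.branches:
            for step in token:
                if len(step) > 1:
                    out |= set(step)
        return out


def _parse_steps(text: str, base: int) -> tuple[Step, ...]:
    steps: list[Step] = []
    pos = 0
    for seg in text.split("-"):
        if not seg:
            raise NotationError("empty path segment", base + pos)
        alts: list[str] = []
        apos = pos
        for alt in seg.split("/"):
            if not alt:
                raise NotationError("empty slash alternative", base + apos)
            if not _LABEL_RE.fullmatch(alt):
                raise NotationError(f"invalid ring label {alt!r}", base + apos)
            alts.append(alt)
            apos += len(alt) + 1
        steps.append(tuple(alts))
        pos += len(seg) + 1
    return tuple(steps)


def parse_placement(notation: str, known_rings: set[str] | None = None) -> RingPath:
    """Parse hyphen-linked notation into a :class:`RingPath`.

    ``known_rings``, when given, is used to reject labels that are not rings of
    the bound template (reported with the character offset).
    """
    raw = notation
    s = notation.strip()
    if s.lower().startswith("rings "):
        s = s[6:]
    s = s.replace(" ", "")
    if not s:
        raise NotationError("empty notation", 0)

    main: list[Step] = []
    branches: list[tuple[int, tuple[Step, ...]]] = []
    i = 0
    seg_start = 0
    cur = ""

    def flush(end: int):
        nonlocal cur
        if cur:
            for step in _parse_steps(cur, seg_start):
                main.append(step)
            cur = ""
        elif end > 0 and not main:
            raise NotationError("empty segment", end)

    n = len(s)
    while i < n:
        ch = s[i]
        if ch == "(":
            close = s.find(")", i + 1)
            if close < 0:
                raise NotationError("unbalanced parenthesis", i)
            inner = s[i + 1:close]
            if "(" in inner:
                raise NotationError("nested brackets are not supported", i + 1 + inner.index("("))
            if not inner:
                raise NotationError("empty bracket", i + 1)
            flush(i)
            if not main:
                raise NotationError("branch before any main ring", i)
            branches.append((len(main) - 1, _parse_steps(inner, i + 1)))
            i = close + 1
            if i < n and s[i] not in "-(":
                raise NotationError(f"expected '-' after bracket, found {s[i]!r}", i)
            if i < n and s[i] == "-":
                i += 1
            seg_start = i
        elif ch == ")":
            raise NotationError("unbalanced parenthesis", i)
        elif ch == "-":
            if not cur:
                raise NotationError("empty segment", i)
            flush(i)
            i += 1
            seg_start = i
        else:
            cur += ch
            i += 1
    if cur:
        flush(n)
    if not main:
        raise NotationError("notation has no main path", 0)
    if s.endswith("-"):
        raise NotationError("trailing hyphen", n - 1)

    path = RingPath(main=tuple(main), branches=tuple(branches), raw=raw)
    if known_rings is not None:
        offset = 0
        for lbl in sorted(path.all_labels()):
            if lbl not in known_rings:
                offset = s.find(lbl)
                raise NotationError(f"unknown ring label {lbl!r}", max(offset, 0))
    return path


def _fmt_steps(steps: tuple[Step, ...]) -> str:
    return "-".join("/".join(step) for step in steps)


def serialize_placement(p: RingPath) -> str:
    """Canonical string: no spaces, no prefix; parse/serialize round-trips."""
    branch_map = p.branch_map()
    parts: list[str] = []
    for idx, step in enumerate(p.main):
        text = "/".join(step)
        for token in branch_map.get(idx, ()):
            text += f"({_fmt_steps(tuple(token))})"
        parts.append(text)
    return "-".join(parts)


def rings_occupied(p: RingPath) -> set[str]:
    """Union of main and branch labels (slash alternatives contribute all
    members; :meth:`RingPath.alternative_labels` flags the weak ones)."""
    return p.all_labels()
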