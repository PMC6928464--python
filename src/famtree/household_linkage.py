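"""Reconstruct pedigree edges from household / insurance-unit rosters.

Source data never state relationships between arbitrary people: each yearly
roster row only gives one member's relation to the unit's head.  This module
turns those head-relative codes into person-to-person edges by

* taking first-degree head-member relations (parent, child, spouse, step
  variants) as direct edge evidence, and
* composing pairs of head-relative codes (``invert(head->a)`` followed by
  ``head->b``) to relate two non-head members, keeping only compositions
  that are unambiguous once distinct person identities are taken into
  account.

Evidence is accumulated across years and across the two sources (health
insurance *eligibility* units and resident *register* households) and
merged; on contradiction the resident register, being the civil record,
takes precedence, and every conflict is logged with the supporting rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .familycode import (
    CodeError,
    FamilyCode,
    _reduce_distinct,
    _sex_compatible,
    format_code,
    invert_code,
    parse_code,
    reduce_code,
    ReductionResult,
)
from .pedigree import PedigreeError, PedigreeGraph, Person

SOURCES = ("eligibility", "register")
SNAPSHOT_COLUMNS = ["unit_id", "person_id", "relation_to_head", "year", "source"]


@dataclass(frozen=True)
class MembershipSnapshot:
    """One roster row: a person's relation to the head of one unit-year."""

    unit_id: str
    person_id: str
    relation_to_head: str
    year: int
    source: str


@dataclass
class LinkageReport:
    edges_added: int = 0
    conflicts: list[dict] = field(default_factory=list)
    rejects: list[dict] = field(default_factory=list)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"edges_added": self.edges_added}) + "\n")
            for c in self.conflicts:
                fh.write(json.dumps({"conflict": c}) + "\n")
            for r in self.rejects:
                fh.write(json.dumps({"reject": r}) + "\n")


def _iter_snapshots(snapshots) -> Iterable[MembershipSnapshot]:
    if isinstance(snapshots, pd.DataFrame):
        for row in snapshots.itertuples(index=False):
            yield MembershipSnapshot(
                str(row.unit_id), str(row.person_id),
                str(row.relation_to_head), int(row.year), str(row.source),
            )
    else:
        yield from snapshots


def member_pair_code(
    head_rel_a: FamilyCode | str,
    head_rel_b: FamilyCode | str,
    a_sex: Optional[str] = None,
    distinct: bool = True,
) -> ReductionResult:
    """Relation of member *a* to member *b*, both known only via the head.

    Inverts the head->a code and composes it with the head->b code.  With
    ``distinct`` (the default) the two members are known to be different
    people, so the pure-self reduction alternative is dropped — e.g. the
    head's son and the head's daughter compose unambiguously to siblings.
    """
    a = parse_code(head_rel_a) if isinstance(head_rel_a, str) else head_rel_a
    b = parse_code(head_rel_b) if isinstance(head_rel_b, str) else head_rel_b
    if a.atoms[0] != b.atoms[0]:
        raise CodeError(
            f"codes {a} and {b} do not share the same head self-prefix"
        )
    if a_sex is None:
        a_sex = a.terminal_sex
    if a_sex == "X":
        raise CodeError(f"sex of member {a} unknown; cannot invert")
    inv = invert_code(a, a.subject_sex, a_sex)
    if not _sex_compatible(inv.terminal_sex, b.subject_sex):
        raise CodeError(f"cannot chain {inv} with {b}")
    joined = FamilyCode(inv.atoms + b.tail)
    return _reduce_distinct(joined) if distinct else reduce_code(joined)


class CoMembership:
    """Index of who shared a unit-year with whom, per source."""

    def __init__(self, snapshots) -> None:
        self._index: dict[str, dict[str, set[tuple[str, int]]]] = {
            s: {} for s in SOURCES
        }
        for snap in _iter_snapshots(snapshots):
            if snap.source not in self._index:
                continue
            self._index[snap.source].setdefault(snap.person_id, set()).add(
                (snap.unit_id, snap.year)
            )

    def shared(self, source: str, a: str, b: str) -> bool:
        ia = self._index[source].get(a)
        ib = self._index[source].get(b)
        return bool(ia and ib and ia & ib)

    def pair_code(self, a: str, b: str) -> Optional[int]:
        """HHRR code: 1 both sources, 2 household (register) only,
        3 insurance unit (eligibility) only, None never co-members."""
        reg = self.shared("register", a, b)
        elig = self.shared("eligibility", a, b)
        if reg and elig:
            return 1
        if reg:
            return 2
        if elig:
            return 3
        return None


def membership_history(snapshots, person_a: str, person_b: str) -> Optional[int]:
    """Convenience wrapper: HHRR co-membership code for one pair."""
    return CoMembership(snapshots).pair_code(person_a, person_b)


# ---------------------------------------------------------------------------
# edge inference

@dataclass(frozen=True)
class _Claim:
    kind: str            # "parent" or "spouse"
    a: str               # parent for "parent" claims
    b: str
    bond: str            # biological / step ("" for spouse)
    source: str
    direct: bool         # direct head-member relation vs composed
    provenance: tuple    # (unit, year)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))

    @property
    def label(self) -> tuple:
        if self.kind == "spouse":
            return ("spouse", None, None)
        return ("parent", self.a, self.bond)


def _parent_bond(parent: Optional[Person], child: Optional[Person],
                 min_age: int, max_age: int) -> str:
    """Blood vs step heuristic for compositions that cannot tell the two
    apart (e.g. head's spouse vs head's child): biological only when the
    age gap is a plausible parental age."""
    if parent is None or child is None:
        return "step"
    if parent.birth_year is None or child.birth_year is None:
        return "step"
    gap = child.birth_year - parent.birth_year
    return "biological" if min_age <= gap <= max_age else "step"


def infer_edges(
    snapshots,
    persons: Iterable[Person],
    min_parent_age: int = 15,
    max_parent_age: int = 70,
) -> tuple[PedigreeGraph, LinkageReport]:
    """Build a pedigree from roster snapshots.

    Returns the graph together with a report of rejected rows and resolved
    conflicts.  Every edge is supported by at least one direct head-member
    relation or one unambiguous member-pair composition.
    """
    report = LinkageReport()
    people = {p.person_id: p for p in persons}

    # -- validate, deduplicate -------------------------------------------
    rows: dict[tuple, MembershipSnapshot] = {}
    parsed: dict[tuple, FamilyCode] = {}
    for snap in _iter_snapshots(snapshots):
        try:
            if snap.source not in SOURCES:
                raise CodeError(f"unknown source {snap.source!r}")
            code = parse_code(snap.relation_to_head)
        except CodeError as exc:
            report.rejects.append(
                {"row": snap.__dict__ if hasattr(snap, "__dict__")
                 else str(snap), "reason": str(exc)}
            )
            continue
        key = (snap.source, snap.unit_id, snap.year, snap.person_id)
        if key in rows:
            if rows[key].relation_to_head != snap.relation_to_head:
                report.rejects.append(
                    {"row": vars(snap), "reason": "duplicate row, relation differs"}
                )
            continue
        rows[key] = snap
        parsed[key] = code

    # -- group into unit-year rosters ------------------------------------
    groups: dict[tuple, list[tuple[MembershipSnapshot, FamilyCode]]] = {}
    for key, snap in rows.items():
        groups.setdefault((snap.source, snap.unit_id, snap.year), []).append(
            (snap, parsed[key])
        )

    claims: list[_Claim] = []
    for (source, unit, year), members in sorted(groups.items()):
        heads = [(s, c) for s, c in members if not c.tail]
        if len(heads) != 1:
            report.rejects.append(
                {"unit": unit, "year": year, "source": source,
                 "reason": f"{len(heads)} heads in roster"}
            )
            continue
        head_snap, head_code = heads[0]
        head_id = head_snap.person_id
        prov = (unit, year)

        def sex_of(pid: str, code: FamilyCode) -> str:
            p = people.get(pid)
            if p is not None and p.sex != "X":
                return p.sex
            return code.terminal_sex

        # direct head-member relations
        for snap, code in members:
            if not code.tail or snap.person_id == head_id:
                continue
            if code.atoms[0] != head_code.atoms[0]:
                report.rejects.append(
                    {"row": vars(snap),
                     "reason": "relation self-prefix disagrees with head"}
                )
                continue
            if len(code.tail) != 1:
                continue  # second-degree-plus codes carry no direct edge
            atom = code.tail[0]
            mid = snap.person_id
            if (atom.degree, atom.relation) in ((1, "A"), (1, "a")):
                claims.append(_Claim(
                    "parent", mid, head_id,
                    "step" if atom.is_step else "biological",
                    source, True, prov))
            elif (atom.degree, atom.relation) in ((1, "D"), (1, "d")):
                claims.append(_Claim(
                    "parent", head_id, mid,
                    "step" if atom.is_step else "biological",
                    source, True, prov))
            elif atom.is_spouse:
                claims.append(_Claim("spouse", head_id, mid, "", source,
                                     True, prov))

        # member-member compositions
        non_head = [(s, c) for s, c in members if s.person_id != head_id
                    and c.atoms[0] == head_code.atoms[0]]
        for i, (sa, ca) in enumerate(non_head):
            for sb, cb in non_head:
                if sb.person_id == sa.person_id:
                    continue
                try:
                    res = member_pair_code(
                        ca, cb, a_sex=sex_of(sa.person_id, ca))
                except CodeError:
                    continue
                if res.ambiguous:
                    continue
                tail = res.code.tail
                kinds = tuple((a.degree, a.relation) for a in tail)
                if kinds == ((1, "A"),):
                    claims.append(_Claim("parent", sb.person_id, sa.person_id,
                                         "biological", source, False, prov))
                elif kinds == ((1, "D"),):
                    claims.append(_Claim("parent", sa.person_id, sb.person_id,
                                         "biological", source, False, prov))
                elif kinds == ((0, "O"),):
                    claims.append(_Claim("spouse", sa.person_id, sb.person_id,
                                         "", source, False, prov))
                elif kinds == ((0, "O"), (1, "D")):
                    # a's spouse's child: parent or step-parent of b
                    bond = _parent_bond(people.get(sa.person_id),
                                        people.get(sb.person_id),
                                        min_parent_age, max_parent_age)
                    claims.append(_Claim("parent", sa.person_id, sb.person_id,
                                         bond, source, False, prov))
                elif kinds == ((1, "A"), (0, "O")):
                    # a's parent's spouse: parent or step-parent of a
                    bond = _parent_bond(people.get(sb.person_id),
                                        people.get(sa.person_id),
                                        min_parent_age, max_parent_age)
                    claims.append(_Claim("parent", sb.person_id, sa.person_id,
                                         bond, source, False, prov))

    # -- resolve claims per unordered pair -------------------------------
    graph = PedigreeGraph()
    for pid, person in people.items():
        graph.add_person(person)

    by_pair: dict[frozenset, list[_Claim]] = {}
    for cl in claims:
        # make sure snapshot-only people exist in the graph
        for pid in (cl.a, cl.b):
            if pid not in graph:
                graph.add_person(Person(pid, "X", None))
        by_pair.setdefault(cl.pair, []).append(cl)

    resolved: list[_Claim] = []
    for pair, cls in by_pair.items():
        labels = {c.label for c in cls}
        if len(labels) > 1:
            # precedence: register over eligibility, direct over composed,
            # then biological over step
            best = sorted(
                cls,
                key=lambda c: (c.source != "register", not c.direct,
                               c.bond == "step", c.label),
            )[0]
            report.conflicts.append({
                "pair": sorted(pair),
                "claims": [
                    {"label": list(map(str, c.label)), "source": c.source,
                     "direct": c.direct, "unit": c.provenance[0],
                     "year": c.provenance[1]}
                    for c in cls
                ],
                "resolution": list(map(str, best.label)),
            })
            resolved.append(best)
        else:
            resolved.append(cls[0])

    # spouse edges first; then parent claims in precedence order so that
    # when more than two parents are claimed the best-supported ones win
    resolved.sort(key=lambda c: (c.kind != "spouse", c.source != "register",
                                 not c.direct, c.a, c.b))
    for cl in resolved:
        try:
            if cl.kind == "spouse":
                graph.add_spouse_edge(cl.a, cl.b)
            else:
                graph.add_parent_edge(cl.a, cl.b, cl.bond)
            report.edges_added += 1
        except PedigreeError as exc:
            report.rejects.append(
                {"claim": [cl.kind, cl.a, cl.b, cl.bond], "reason": str(exc)}
            )
    return graph, report


# ---------------------------------------------------------------------------
# CSV interchange

def snapshots_to_csv(snapshots: Iterable[MembershipSnapshot], path) -> None:
    df = pd.DataFrame(
        [(s.unit_id, s.person_id, s.relation_to_head, s.year, s.source)
         for s in _iter_snapshots(snapshots)],
        columns=SNAPSHOT_COLUMNS,
    )
    df.to_csv(path, index=False)


def snapshots_from_csv(path) -> list[MembershipSnapshot]:
    df = pd.read_csv(path, dtype={"unit_id": str, "person_id": str,
                                  "relation_to_head": str, "source": str})
    return list(_iter_snapshots(df))
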