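"""Enumerate all kin within a maximum degree and emit family-tree records.

A kinship path is a simple path through the pedigree of the shape

    [spouse]? up* down* [spouse]?

i.e. a blood path climbing to a common ancestor and descending again,
optionally entered through the subject's marriage and/or left through the
relative's marriage.  This mirrors the statutory notion of affinity (a
spouse's blood relatives, a blood relative's spouse, and a spouse's blood
relative's spouse); chains alternating blood and marriage more than that are
not kin here.  Parent/child steps add 1 to the degree, spouse steps 0, and
an up-down pivot through a shared parent contracts to a single sibling step
of weight 2, so the degree of the emitted code equals the weight of the
path.

For every unordered pair within the degree bound exactly one canonical path
is selected deterministically, and two directed records (subject -> family
member and its inverse) are emitted in the FMLY_* column layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .familycode import (
    BasicCode,
    FamilyCode,
    classify_family_type,
    degree_of,
    format_code,
)
from .pedigree import PedigreeGraph

RECORD_COLUMNS = [
    "TG_ID", "FMLY_ID", "TG_SEX_TYPE", "TG_BYEAR", "FMLY_SEX_TYPE",
    "FMLY_BYEAR", "FMLY_CD", "FMLY_DGR", "FMLY_TYPE", "HHRR_CD",
]


@dataclass(frozen=True)
class RelationshipPath:
    """One concrete chain of persons linking a subject to a relative.

    ``steps[i]`` is ``(kind, bond)`` with kind in ``up``/``down``/``spouse``
    and bond the parent-edge bond (``None`` for spouse steps), leading from
    ``person_ids[i]`` to ``person_ids[i + 1]``.
    """

    person_ids: tuple[str, ...]
    steps: tuple[tuple[str, Optional[str]], ...]

    @property
    def degree(self) -> int:
        return sum(1 for k, _ in self.steps if k != "spouse")

    @property
    def n_spouse(self) -> int:
        return sum(1 for k, _ in self.steps if k == "spouse")

    @property
    def n_nonbiological(self) -> int:
        return sum(1 for _, b in self.steps if b in ("step", "adoptive"))

    @property
    def subject(self) -> str:
        return self.person_ids[0]

    @property
    def target(self) -> str:
        return self.person_ids[-1]

    def reversed(self) -> "RelationshipPath":
        flip = {"up": "down", "down": "up", "spouse": "spouse"}
        steps = tuple((flip[k], b) for k, b in reversed(self.steps))
        return RelationshipPath(tuple(reversed(self.person_ids)), steps)


@dataclass(frozen=True)
class FamilyTreeRecord:
    """One directed subject -> family member row of the family-tree table."""

    tg_id: str
    fmly_id: str
    tg_sex_type: str
    tg_byear: Optional[int]
    fmly_sex_type: str
    fmly_byear: Optional[int]
    fmly_cd: str
    fmly_dgr: int
    fmly_type: str
    hhrr_cd: Optional[int]


def enumerate_paths(
    graph: PedigreeGraph,
    subject_id: str,
    max_degree: int = 4,
    max_spouse_edges: int = 2,
) -> list[RelationshipPath]:
    """All kinship paths from ``subject_id`` with degree <= ``max_degree``.

    ``max_spouse_edges`` caps the marriage steps (0 = blood only, 1 = one
    end, 2 = both ends); spouse steps are only ever taken as the first or
    the last step of the path.
    """
    graph._check(subject_id)
    out: list[RelationshipPath] = []

    def emit(persons: list[str], steps: list[tuple[str, Optional[str]]]):
        out.append(RelationshipPath(tuple(persons), tuple(steps)))

    def dfs(cur: str, persons: list[str], steps: list,
            degree: int, spouses: int, descending: bool) -> None:
        # trailing spouse: closes the path
        if spouses < max_spouse_edges:
            for sp in sorted(graph.spouses_of(cur)):
                if sp in persons:
                    continue
                emit(persons + [sp], steps + [("spouse", None)])
        if degree >= max_degree:
            return
        if not descending:
            for par, bond in sorted(graph.parents_of(cur).items()):
                if par in persons:
                    continue
                persons.append(par)
                steps.append(("up", bond))
                emit(persons, steps)
                dfs(par, persons, steps, degree + 1, spouses, False)
                persons.pop()
                steps.pop()
        for ch, bond in sorted(graph.children_of(cur).items()):
            if ch in persons:
                continue
            persons.append(ch)
            steps.append(("down", bond))
            emit(persons, steps)
            dfs(ch, persons, steps, degree + 1, spouses, True)
            persons.pop()
            steps.pop()

    # blood start
    dfs(subject_id, [subject_id], [], 0, 0, False)
    # leading spouse, then a blood segment from the spouse (the bare
    # spouse path itself was already emitted by the trailing-spouse rule)
    if max_spouse_edges >= 1:
        for sp in sorted(graph.spouses_of(subject_id)):
            persons = [subject_id, sp]
            steps: list[tuple[str, Optional[str]]] = [("spouse", None)]
            dfs(sp, persons, steps, 0, 1, False)
    return out


def _sibling_atom(graph: PedigreeGraph, near: str, kin: str) -> BasicCode:
    """Sibling atom for the pivot contraction, ordered by birth year."""
    a = graph.persons[near]
    b = graph.persons[kin]
    if a.birth_year is None or b.birth_year is None or a.birth_year == b.birth_year:
        rel = "U"
    elif b.birth_year < a.birth_year:
        rel = "A"  # kin born earlier: older sibling
    else:
        rel = "D"
    return BasicCode(2, rel, b.sex)


def path_to_code(path: RelationshipPath, graph: PedigreeGraph) -> FamilyCode:
    """Translate a concrete path into its (reduced, unambiguous) family code.

    Person identities are known here, so the up-down pivot through a shared
    biological parent contracts directly to the sibling atom; no ambiguous
    reduction is ever needed.
    """
    subject = graph.persons[path.subject]
    atoms: list[BasicCode] = [BasicCode(0, "I", subject.sex)]
    i = 0
    steps, persons = path.steps, path.person_ids
    while i < len(steps):
        kind, bond = steps[i]
        reached = graph.persons[persons[i + 1]]
        if (
            kind == "up"
            and bond == "biological"
            and i + 1 < len(steps)
            and steps[i + 1][0] == "down"
            and steps[i + 1][1] == "biological"
        ):
            atoms.append(_sibling_atom(graph, persons[i], persons[i + 2]))
            i += 2
            continue
        if kind == "spouse":
            atoms.append(BasicCode(0, "O", reached.sex))
        elif kind == "up":
            atoms.append(BasicCode(1, "a" if bond == "step" else "A", reached.sex))
        else:
            atoms.append(BasicCode(1, "d" if bond == "step" else "D", reached.sex))
        i += 1
    return FamilyCode(tuple(atoms))


def select_canonical(
    paths: Iterable[RelationshipPath], graph: PedigreeGraph
) -> RelationshipPath:
    """Deterministic representative among alternative paths for one pair.

    Minimum of (degree, spouse steps, non-biological steps, code string,
    person-id chain); the last key makes the winner unique even when two
    distinct paths spell the same code.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("no paths to select from")
    return min(
        paths,
        key=lambda p: (
            p.degree,
            p.n_spouse,
            p.n_nonbiological,
            format_code(path_to_code(p, graph)),
            p.person_ids,
        ),
    )


def _hhrr(comembership, a: str, b: str) -> Optional[int]:
    if comembership is None:
        return None
    return comembership.pair_code(a, b)


def expand_all(
    graph: PedigreeGraph,
    snapshots=None,
    max_degree: int = 4,
    max_spouse_edges: int = 2,
    close_threshold: int = 2,
    keep_alternates: bool = False,
):
    """Build the full family-tree table for every pair within ``max_degree``.

    Returns the sorted list of :class:`FamilyTreeRecord`; with
    ``keep_alternates`` also a dict mapping (subject, kin) to the
    non-canonical paths, for debugging.  ``snapshots`` (any iterable of
    membership snapshot rows, see :mod:`famtree.household_linkage`) feeds
    the HHRR_CD co-membership history column; without it the column is
    empty.
    """
    from .household_linkage import CoMembership

    comember = CoMembership(snapshots) if snapshots is not None else None
    records: list[FamilyTreeRecord] = []
    alternates: dict[tuple[str, str], list[RelationshipPath]] = {}

    def make_record(path: RelationshipPath, code: FamilyCode,
                    hhrr: Optional[int]) -> FamilyTreeRecord:
        subj = graph.persons[path.subject]
        kin = graph.persons[path.target]
        dgr = degree_of(code)
        assert dgr == path.degree
        has_step = any(b == "step" for _, b in path.steps)
        has_adoptive = any(b == "adoptive" for _, b in path.steps)
        ftype = classify_family_type(
            code, has_step=has_step, has_adoptive=has_adoptive,
            close_threshold=close_threshold,
        )
        return FamilyTreeRecord(
            tg_id=subj.person_id, fmly_id=kin.person_id,
            tg_sex_type=subj.sex, tg_byear=subj.birth_year,
            fmly_sex_type=kin.sex, fmly_byear=kin.birth_year,
            fmly_cd=format_code(code), fmly_dgr=dgr,
            fmly_type=ftype.value, hhrr_cd=hhrr,
        )

    for subject_id in sorted(graph.persons):
        paths = enumerate_paths(graph, subject_id, max_degree, max_spouse_edges)
        by_target: dict[str, list[RelationshipPath]] = {}
        for p in paths:
            by_target.setdefault(p.target, []).append(p)
        for target_id, plist in by_target.items():
            if target_id <= subject_id:
                continue  # each unordered pair handled once, from the lower id
            best = select_canonical(plist, graph)
            hhrr = _hhrr(comember, subject_id, target_id)
            fwd = path_to_code(best, graph)
            rev = path_to_code(best.reversed(), graph)
            records.append(make_record(best, fwd, hhrr))
            records.append(make_record(best.reversed(), rev, hhrr))
            if keep_alternates and len(plist) > 1:
                alternates[(subject_id, target_id)] = [
                    p for p in plist if p is not best
                ]

    records.sort(key=lambda r: (r.tg_id, r.fmly_id))
    if keep_alternates:
        return records, alternates
    return records


def records_to_frame(records: Iterable[FamilyTreeRecord]) -> pd.DataFrame:
    rows = [
        (r.tg_id, r.fmly_id, r.tg_sex_type, r.tg_byear, r.fmly_sex_type,
         r.fmly_byear, r.fmly_cd, r.fmly_dgr, r.fmly_type, r.hhrr_cd)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df["HHRR_CD"] = df["HHRR_CD"].astype("Int64")
    df["TG_BYEAR"] = df["TG_BYEAR"].astype("Int64")
    df["FMLY_BYEAR"] = df["FMLY_BYEAR"].astype("Int64")
    return df


def records_to_csv(records: Iterable[FamilyTreeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"TG_ID": str, "FMLY_ID": str, "FMLY_CD": str, "FMLY_TYPE": str},
    )
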