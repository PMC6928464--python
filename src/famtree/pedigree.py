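"""Person-level kinship graph.

Holds persons plus typed parent-child edges (biological, step, adoptive) and
spouse edges.  Sibling relationships are never stored: they are derived from
shared biological parents, which keeps a single source of truth.  The module
also provides :func:`kinship_distance_oracle`, a deliberately brute-force
simple-path search used as an independent check on the production code-path
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

BONDS = ("biological", "step", "adoptive")


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Person:
    person_id: str
    sex: str = "X"  # M / W / X
    birth_year: Optional[int] = None
    death_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "W", "X"):
            raise PedigreeError(f"bad sex {self.sex!r} for {self.person_id}")


class PedigreeGraph:
    """Mutable pedigree: persons, typed parent edges, spouse edges."""

    def __init__(self) -> None:
        self.persons: dict[str, Person] = {}
        # child -> {parent_id: bond}
        self._parents: dict[str, dict[str, str]] = {}
        # parent -> {child_id: bond}
        self._children: dict[str, dict[str, str]] = {}
        self._spouses: dict[str, set[str]] = {}

    # -- construction -----------------------------------------------------
    def add_person(self, person: Person) -> None:
        old = self.persons.get(person.person_id)
        if old is not None and old != person:
            raise PedigreeError(f"person {person.person_id} already present")
        self.persons[person.person_id] = person

    def add_parent_edge(self, parent_id: str, child_id: str,
                        bond: str = "biological") -> None:
        if bond not in BONDS:
            raise PedigreeError(f"unknown bond {bond!r}")
        if parent_id == child_id:
            raise PedigreeError("self parent edge")
        for pid in (parent_id, child_id):
            if pid not in self.persons:
                raise PedigreeError(f"unknown person {pid}")
        existing = self._parents.get(child_id, {})
        if existing.get(parent_id) == bond:
            return  # idempotent
        if bond == "biological":
            nbio = sum(1 for b in existing.values() if b == "biological")
            if nbio >= 2 and existing.get(parent_id) != "biological":
                raise PedigreeError(
                    f"child {child_id} already has two biological parents"
                )
            if self._is_ancestor(child_id, parent_id):
                raise PedigreeError(
                    f"edge {parent_id}->{child_id} creates parentage cycle"
                )
            p, c = self.persons[parent_id], self.persons[child_id]
            if (p.birth_year is not None and c.birth_year is not None
                    and p.birth_year >= c.birth_year):
                raise PedigreeError(
                    f"biological parent {parent_id} not older than {child_id}"
                )
        self._parents.setdefault(child_id, {})[parent_id] = bond
        self._children.setdefault(parent_id, {})[child_id] = bond

    def add_spouse_edge(self, a_id: str, b_id: str) -> None:
        if a_id == b_id:
            raise PedigreeError("self spouse edge")
        for pid in (a_id, b_id):
            if pid not in self.persons:
                raise PedigreeError(f"unknown person {pid}")
        self._spouses.setdefault(a_id, set()).add(b_id)
        self._spouses.setdefault(b_id, set()).add(a_id)

    def _is_ancestor(self, anc: str, desc: str) -> bool:
        """True if ``anc`` is reachable upward from ``desc`` via biological edges."""
        stack = [desc]
        seen = set()
        while stack:
            cur = stack.pop()
            for pid, bond in self._parents.get(cur, {}).items():
                if bond != "biological" or pid in seen:
                    continue
                if pid == anc:
                    return True
                seen.add(pid)
                stack.append(pid)
        return False

    # -- queries ----------------------------------------------------------
    def parents_of(self, person_id: str) -> dict[str, str]:
        self._check(person_id)
        return dict(self._parents.get(person_id, {}))

    def children_of(self, person_id: str) -> dict[str, str]:
        self._check(person_id)
        return dict(self._children.get(person_id, {}))

    def spouses_of(self, person_id: str) -> set[str]:
        self._check(person_id)
        return set(self._spouses.get(person_id, set()))

    def siblings_of(self, person_id: str) -> set[tuple[str, int]]:
        """Persons sharing at least one biological parent, with the count
        of shared parents (2 = full siblings, 1 = half siblings)."""
        self._check(person_id)
        my_parents = {p for p, b in self._parents.get(person_id, {}).items()
                      if b == "biological"}
        counts: dict[str, int] = {}
        for par in my_parents:
            for child, bond in self._children.get(par, {}).items():
                if bond == "biological" and child != person_id:
                    counts[child] = counts.get(child, 0) + 1
        return {(c, n) for c, n in counts.items()}

    def _check(self, person_id: str) -> None:
        if person_id not in self.persons:
            raise PedigreeError(f"unknown person {person_id}")

    def __contains__(self, person_id: str) -> bool:
        return person_id in self.persons

    def parent_edges(self) -> Iterable[tuple[str, str, str]]:
        for child, pars in sorted(self._parents.items()):
            for parent, bond in sorted(pars.items()):
                yield parent, child, bond

    def spouse_edges(self) -> Iterable[tuple[str, str]]:
        seen = set()
        for a, bs in sorted(self._spouses.items()):
            for b in sorted(bs):
                key = tuple(sorted((a, b)))
                if key not in seen:
                    seen.add(key)
                    yield key


def kinship_distance_oracle(graph: PedigreeGraph, a_id: str, b_id: str,
                            max_degree: int = 4) -> Optional[int]:
    """Brute-force degree of kinship by exhaustive simple-path search.

    Parent-child edges (any bond) weigh 1, spouse edges 0; the minimum total
    weight over simple paths not exceeding ``max_degree`` is returned, else
    ``None``.  Intentionally naive and independent of the production
    expansion so the two can be checked against each other.
    """
    graph._check(a_id)
    graph._check(b_id)
    if a_id == b_id:
        return 0
    best: list[Optional[int]] = [None]

    def neighbours(pid: str):
        for q in graph._parents.get(pid, {}):
            yield q, 1
        for q in graph._children.get(pid, {}):
            yield q, 1
        for q in graph._spouses.get(pid, set()):
            yield q, 0

    def dfs(cur: str, weight: int, visited: set[str]) -> None:
        for nxt, w in neighbours(cur):
            nw = weight + w
            if nxt in visited or nw > max_degree:
                continue
            if best[0] is not None and nw > best[0]:
                continue
            if nxt == b_id:
                if best[0] is None or nw < best[0]:
                    best[0] = nw
                continue
            visited.add(nxt)
            dfs(nxt, nw, visited)
            visited.remove(nxt)

    dfs(a_id, 0, {a_id})
    return best[0]


# ---------------------------------------------------------------------------
# CSV interchange

def persons_to_csv(persons: Iterable[Person], path) -> None:
    df = pd.DataFrame(
        [(p.person_id, p.sex, p.birth_year, p.death_year)
         for p in persons],
        columns=["person_id", "sex", "birth_year", "death_year"],
    )
    df.to_csv(path, index=False)


def persons_from_csv(path) -> list[Person]:
    df = pd.read_csv(path, dtype={"person_id": str})
    out = []
    for row in df.itertuples(index=False):
        by = None if pd.isna(row.birth_year) else int(row.birth_year)
        dy = None
        if hasattr(row, "death_year") and not pd.isna(row.death_year):
            dy = int(row.death_year)
        out.append(Person(str(row.person_id), row.sex, by, dy))
    return out


def graph_to_edges_csv(graph: PedigreeGraph, path) -> None:
    rows = [("parent", p, c, b) for p, c, b in graph.parent_edges()]
    rows += [("spouse", a, b, "") for a, b in graph.spouse_edges()]
    pd.DataFrame(rows, columns=["type", "parent_or_a", "child_or_b", "bond"]) \
        .to_csv(path, index=False)


def graph_from_csv(persons_path, edges_path) -> PedigreeGraph:
    g = PedigreeGraph()
    for p in persons_from_csv(persons_path):
        g.add_person(p)
    edges = pd.read_csv(edges_path, dtype=str).fillna("")
    for row in edges.itertuples(index=False):
        if row.type == "parent":
            g.add_parent_edge(row.parent_or_a, row.child_or_b,
                              row.bond or "biological")
        elif row.type == "spouse":
            g.add_spouse_edge(row.parent_or_a, row.child_or_b)
        else:
            raise PedigreeError(f"unknown edge type {row.type!r}")
    return g
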