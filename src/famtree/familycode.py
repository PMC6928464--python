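"""Compositional family-code algebra for interpersonal kinship.

A *family code* is a string of three-character atoms that traces a chain of
elementary kinship steps from a subject to one of their relatives.  Each atom
is ``<degree digit><relation letter><gender letter>``:

* degree digit — contribution of the step to the degree of kinship
  (*chon*): 0 for self and spouse, 1 for parent/child, 2 for sibling;
* relation letter — ``I`` self, ``O`` spouse, ``A`` parent, ``D`` child,
  ``a``/``d`` step-parent/step-child, and for siblings ``A`` (older),
  ``D`` (younger) or ``U`` (unknown order);
* gender letter — ``M`` man, ``W`` woman, ``X`` unspecified; the gender of
  the person *reached* by the step.

Every code starts with a self atom (``0IM`` or ``0IW``) naming the subject,
e.g. ``0IM1AM`` is a man's father and ``0IM1AM1AW`` his paternal
grandmother.  The algebra supports inverting a code (reading the chain from
the relative's side), composing two codes that share a middle person, and
reducing a composed chain by contracting patterns such as parent-then-child.
Because roster data identify people only relative to a household head, some
contractions are inherently ambiguous (a parent's child may be the subject
or a sibling); reduction therefore returns *all* realizable alternatives
together with an ambiguity flag rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "BasicCode",
    "FamilyCode",
    "KinshipCategory",
    "FamilyType",
    "ReductionResult",
    "CodeError",
    "parse_code",
    "format_code",
    "degree_of",
    "invert_code",
    "compose_codes",
    "reduce_code",
    "classify_category",
    "classify_family_type",
]

#: the nine admissible (degree digit, relation letter) pairs
VALID_PAIRS = frozenset(
    [(0, "I"), (0, "O"), (1, "A"), (1, "D"), (2, "A"), (2, "D"), (2, "U"),
     (1, "a"), (1, "d")]
)
GENDERS = frozenset("MWX")

_INVERT_REL = {
    (0, "O"): (0, "O"),
    (1, "A"): (1, "D"),
    (1, "D"): (1, "A"),
    (1, "a"): (1, "d"),
    (1, "d"): (1, "a"),
    (2, "A"): (2, "D"),   # my older sibling's younger sibling is me
    (2, "D"): (2, "A"),
    (2, "U"): (2, "U"),
}


class CodeError(ValueError):
    """Raised for malformed code strings or invalid algebra operations."""


@dataclass(frozen=True, order=True)
class BasicCode:
    """One three-character atom of a family code."""

    degree: int
    relation: str
    gender: str

    def __post_init__(self) -> None:
        if (self.degree, self.relation) not in VALID_PAIRS:
            raise CodeError(
                f"invalid degree/relation pair {self.degree}{self.relation!r}"
            )
        if self.gender not in GENDERS:
            raise CodeError(f"invalid gender letter {self.gender!r}")

    @property
    def is_self(self) -> bool:
        return self.relation == "I"

    @property
    def is_spouse(self) -> bool:
        return self.relation == "O"

    @property
    def is_step(self) -> bool:
        return self.relation in ("a", "d")

    def __str__(self) -> str:
        return f"{self.degree}{self.relation}{self.gender}"


def _atom(text: str, offset: int = 0) -> BasicCode:
    if len(text) != 3:
        raise CodeError(f"triple {text!r} at offset {offset} is not 3 characters")
    if not text[0].isdigit():
        raise CodeError(f"triple {text!r} at offset {offset}: bad degree digit")
    try:
        return BasicCode(int(text[0]), text[1], text[2])
    except CodeError as exc:
        raise CodeError(f"triple {text!r} at offset {offset}: {exc}") from None


@dataclass(frozen=True, order=True)
class FamilyCode:
    """A self-prefixed sequence of :class:`BasicCode` atoms.

    ``atoms[0]`` is the subject's self atom; each later atom is one step
    toward the family member, its gender letter being the sex of the person
    reached after that step.
    """

    atoms: tuple[BasicCode, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise CodeError("family code needs at least the self atom")
        head = self.atoms[0]
        if not head.is_self or head.gender not in ("M", "W"):
            raise CodeError(
                f"family code must start with 0IM or 0IW, got {head}"
            )
        for i, a in enumerate(self.atoms[1:], start=1):
            if a.is_self:
                raise CodeError(
                    f"self atom {a} at position {i} (offset {3 * i}) not allowed"
                )

    @property
    def tail(self) -> tuple[BasicCode, ...]:
        """Atoms after the self prefix — the actual kinship steps."""
        return self.atoms[1:]

    @property
    def subject_sex(self) -> str:
        return self.atoms[0].gender

    @property
    def terminal_sex(self) -> str:
        """Sex letter of the family member the code points at."""
        return self.atoms[-1].gender

    def __str__(self) -> str:
        return format_code(self)

    def __len__(self) -> int:
        return len(self.atoms)


class KinshipCategory(Enum):
    SELF = "self"
    SPOUSE = "spouse"
    DIRECT_ANCESTOR = "direct_ancestor"
    DIRECT_DESCENDANT = "direct_descendant"
    COLLATERAL_BLOOD = "collateral_blood"
    AFFINAL = "affinal"


class FamilyType(Enum):
    """FMLY_TYPE codes of the family-tree record layout.

    ``A3`` (non-close affinal kin under the old law) is accepted on input
    for completeness but never produced by classification.
    """

    C1 = "C1"  # close blood relatives
    C2 = "C2"  # non-close blood relatives
    A0 = "A0"  # spouse
    A1 = "A1"  # close relatives by affinity
    A2 = "A2"  # non-close relatives by affinity
    A3 = "A3"  # non-close affinity, old law (label only)
    R1 = "R1"  # adoptive parents or children


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of reducing a (possibly composed) family code.

    When the contraction is ambiguous, ``alternatives`` holds every
    realizable reduced code and ``code`` a deterministic representative
    (shortest, then lexicographically first).
    """

    code: FamilyCode
    ambiguous: bool = False
    alternatives: frozenset[FamilyCode] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ambiguous and self.alternatives:
            raise CodeError("unambiguous result must have no alternatives")


# ---------------------------------------------------------------------------
# parsing / formatting

def parse_code(text: str) -> FamilyCode:
    """Parse a concatenated-triple code string into a :class:`FamilyCode`."""
    if not text or len(text) % 3 != 0:
        raise CodeError(
            f"code string {text!r} length {len(text)} is not a positive multiple of 3"
        )
    atoms = tuple(_atom(text[i : i + 3], i) for i in range(0, len(text), 3))
    return FamilyCode(atoms)


def format_code(code: FamilyCode) -> str:
    return "".join(str(a) for a in code.atoms)


def _as_code(code: FamilyCode | str) -> FamilyCode:
    return parse_code(code) if isinstance(code, str) else code


# ---------------------------------------------------------------------------
# degree

#: adjacent tail patterns that reduce_code knows how to contract
def _contractible(x: BasicCode, y: BasicCode) -> bool:
    p, q = (x.degree, x.relation), (y.degree, y.relation)
    if p == (1, "A") and q == (1, "D"):
        return True
    if p == (1, "D") and q == (1, "A"):
        return True
    if p == (0, "O") and q == (0, "O"):
        return True
    if x.degree == 2 and y.degree == 2:
        return True
    return False


def degree_of(code: FamilyCode | str) -> int:
    """Degree of kinship (*chon*) of a reduced code.

    Each parent/child step counts 1, each sibling step 2, spouse steps 0;
    the degree of an affinal code is thus the blood degree on the spouse's
    side.  Raises if the code still contains a contractible pattern, which
    means :func:`reduce_code` must be applied first.
    """
    code = _as_code(code)
    tail = code.tail
    for i in range(len(tail) - 1):
        if _contractible(tail[i], tail[i + 1]):
            raise CodeError(
                f"code {code} contains contractible pair "
                f"{tail[i]}{tail[i + 1]}; reduce it first"
            )
    return sum(a.degree for a in tail)


# ---------------------------------------------------------------------------
# inversion

def _sex_compatible(a: str, b: str) -> bool:
    return a == b or a == "X" or b == "X"


def invert_code(
    code: FamilyCode | str, subject_sex: str, family_sex: str
) -> FamilyCode:
    """Return the code naming the subject as seen from the family member.

    The tail is reversed with every relation inverted (parent<->child,
    older<->younger sibling, spouse and unordered sibling self-inverse) and
    gender letters reassigned so each atom still names the sex of the person
    reached along the *reversed* chain.  Given both end sexes, inversion is
    an involution.
    """
    code = _as_code(code)
    if family_sex == "X":
        raise CodeError("cannot invert toward family member of unspecified sex")
    if subject_sex not in ("M", "W") or family_sex not in ("M", "W"):
        raise CodeError("subject_sex and family_sex must be M or W")
    if subject_sex != code.subject_sex:
        raise CodeError(
            f"subject_sex {subject_sex} disagrees with self atom {code.atoms[0]}"
        )
    if not _sex_compatible(code.terminal_sex, family_sex):
        raise CodeError(
            f"family_sex {family_sex} incompatible with terminal atom "
            f"{code.atoms[-1]}"
        )
    tail = code.tail
    k = len(tail)
    new_tail = []
    for j in range(1, k + 1):
        step = tail[k - j]
        deg, rel = _INVERT_REL[(step.degree, step.relation)]
        if k - j == 0:
            gender = subject_sex
        else:
            gender = tail[k - j - 1].gender
        new_tail.append(BasicCode(deg, rel, gender))
    return FamilyCode((BasicCode(0, "I", family_sex), *new_tail))


# ---------------------------------------------------------------------------
# reduction

def _pair_alternatives(
    x: BasicCode, y: BasicCode, prev_gender: str
) -> tuple[list[tuple[BasicCode, ...] | None], bool] | None:
    """Rewrite alternatives for the adjacent pair ``x, y``.

    Returns ``(alternatives, inherent)`` where each alternative is the
    replacement atom tuple (``None`` marks the identity collapse, i.e. the
    pair cancels and the chain returns to the previous person) and
    ``inherent`` flags contractions that stay ambiguous even when a single
    alternative survives (a child's other parent need not be a spouse; a
    spouse's spouse need not be the subject unless monogamy is assumed).
    ``None`` as overall result: the pair is not contractible.
    """
    p, q = (x.degree, x.relation), (y.degree, y.relation)
    collapse_ok = _sex_compatible(y.gender, prev_gender)
    if p == (1, "A") and q == (1, "D"):
        # parent's child: the subject again, or a sibling
        alts: list[tuple[BasicCode, ...] | None] = []
        if collapse_ok:
            alts.append(None)
        alts.append((BasicCode(2, "U", y.gender),))
        return alts, False
    if p == (1, "D") and q == (1, "A"):
        # child's parent: the subject again, or the co-parent (spouse or not)
        alts = []
        if collapse_ok:
            alts.append(None)
        alts.append((BasicCode(0, "O", y.gender),))
        return alts, True
    if p == (0, "O") and q == (0, "O"):
        # spouse's spouse: the subject under monogamy; flagged regardless
        alts = [None] if collapse_ok else []
        return alts, True
    if x.degree == 2 and y.degree == 2:
        # sibling's sibling; birth-order letters rule some branches out
        if x.relation == "A" and y.relation == "A":
            return [(BasicCode(2, "A", y.gender),)], False
        if x.relation == "D" and y.relation == "D":
            return [(BasicCode(2, "D", y.gender),)], False
        alts = []
        if collapse_ok:
            alts.append(None)
        alts.append((BasicCode(2, "U", y.gender),))
        return alts, False
    return None


def _reduce_tail(
    self_gender: str, tail: tuple[BasicCode, ...]
) -> tuple[set[tuple[BasicCode, ...]], bool]:
    """Exhaustively rewrite ``tail``; returns (irreducible tails, inherent)."""
    results: set[tuple[BasicCode, ...]] = set()
    inherent = False
    stack = [tail]
    seen: set[tuple[BasicCode, ...]] = set()
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        branched = False
        for i in range(len(t) - 1):
            prev = t[i - 1].gender if i > 0 else self_gender
            rule = _pair_alternatives(t[i], t[i + 1], prev)
            if rule is None:
                continue
            alts, inh = rule
            inherent = inherent or inh
            if not alts:
                continue  # pattern matched but no realizable rewrite
            for repl in alts:
                if repl is None:
                    head = list(t[:i])
                    # collapse may pin down an unknown intermediate sex
                    if i > 0 and head[-1].gender == "X" and t[i + 1].gender != "X":
                        head[-1] = BasicCode(
                            head[-1].degree, head[-1].relation, t[i + 1].gender
                        )
                    new = tuple(head) + t[i + 2 :]
                else:
                    new = t[:i] + repl + t[i + 2 :]
                stack.append(new)
            branched = True
            break
        if not branched:
            results.add(t)
    return results, inherent


def reduce_code(code: FamilyCode | str) -> ReductionResult:
    """Contract a composed code to its irreducible alternatives.

    The rewrite is identity-blind (person ids are unknown at this level) but
    sex-aware: an alternative is kept only if some concrete pedigree
    realizes it, e.g. a man's mother's daughter cannot be himself.
    """
    code = _as_code(code)
    results, inherent = _reduce_tail(code.subject_sex, code.tail)
    self_atom = code.atoms[0]
    codes = frozenset(FamilyCode((self_atom, *t)) for t in results)
    if not codes:
        # no realizable rewrite survived; return the input, flagged
        return ReductionResult(code, ambiguous=True, alternatives=frozenset([code]))
    ambiguous = inherent or len(codes) > 1
    rep = min(codes, key=lambda c: (len(c.atoms), format_code(c)))
    if ambiguous:
        return ReductionResult(rep, True, codes)
    return ReductionResult(rep, False, frozenset())


def _reduce_distinct(code: FamilyCode | str) -> ReductionResult:
    """Reduce knowing subject and family member are distinct persons.

    Drops the pure-self alternative; used when composing roster relations
    between two identified people.
    """
    code = _as_code(code)
    results, inherent = _reduce_tail(code.subject_sex, code.tail)
    results = {t for t in results if t}  # identity excluded
    self_atom = code.atoms[0]
    codes = frozenset(FamilyCode((self_atom, *t)) for t in results)
    if not codes:
        return ReductionResult(code, ambiguous=True, alternatives=frozenset([code]))
    ambiguous = inherent or len(codes) > 1
    rep = min(codes, key=lambda c: (len(c.atoms), format_code(c)))
    if ambiguous:
        return ReductionResult(rep, True, codes)
    return ReductionResult(rep, False, frozenset())


# ---------------------------------------------------------------------------
# composition

def compose_codes(
    code_ab: FamilyCode | str, code_bc: FamilyCode | str
) -> ReductionResult:
    """Chain a subject->B code with a B->C code and reduce the result.

    The terminal sex of the first code must be compatible with the self atom
    of the second (they name the same person B); an ``X`` terminal is
    refined to B's known sex.
    """
    a = _as_code(code_ab)
    b = _as_code(code_bc)
    if not _sex_compatible(a.terminal_sex, b.subject_sex):
        raise CodeError(
            f"cannot compose {a} with {b}: middle person sex "
            f"{a.terminal_sex} vs {b.subject_sex}"
        )
    atoms = list(a.atoms)
    if len(atoms) > 1 and atoms[-1].gender == "X":
        last = atoms[-1]
        atoms[-1] = BasicCode(last.degree, last.relation, b.subject_sex)
    return reduce_code(FamilyCode(tuple(atoms) + b.tail))


# ---------------------------------------------------------------------------
# classification

def classify_category(code: FamilyCode | str) -> KinshipCategory:
    """Type of kinship of a reduced code."""
    code = _as_code(code)
    tail = code.tail
    if not tail:
        return KinshipCategory.SELF
    if len(tail) == 1 and tail[0].is_spouse:
        return KinshipCategory.SPOUSE
    if any(a.is_spouse for a in tail):
        return KinshipCategory.AFFINAL
    if all(a.relation in ("A", "a") and a.degree == 1 for a in tail):
        return KinshipCategory.DIRECT_ANCESTOR
    if all(a.relation in ("D", "d") and a.degree == 1 for a in tail):
        return KinshipCategory.DIRECT_DESCENDANT
    return KinshipCategory.COLLATERAL_BLOOD


def classify_family_type(
    code: FamilyCode | str,
    has_step: bool = False,
    has_adoptive: bool = False,
    close_threshold: int = 2,
) -> FamilyType:
    """FMLY_TYPE of a reduced code.

    ``close_threshold`` separates close (C1/A1) from non-close (C2/A2) kin
    by degree; the record layout does not pin the cut-off down, so it is a
    configuration knob defaulting to second degree.  ``A3`` is never
    produced.
    """
    if close_threshold < 1:
        raise CodeError("close_threshold must be >= 1")
    code = _as_code(code)
    if has_adoptive:
        return FamilyType.R1
    cat = classify_category(code)
    if cat is KinshipCategory.SPOUSE:
        return FamilyType.A0
    deg = degree_of(code)
    step_atoms = any(a.is_step for a in code.tail)
    if cat is KinshipCategory.AFFINAL or has_step or step_atoms:
        # step kin are kin through a parent's (or child's) marriage
        return FamilyType.A1 if deg <= close_threshold else FamilyType.A2
    return FamilyType.C1 if deg <= close_threshold else FamilyType.C2


def codes_equal(a: Iterable[BasicCode], b: Iterable[BasicCode]) -> bool:
    return tuple(a) == tuple(b)
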