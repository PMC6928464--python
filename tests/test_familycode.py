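"""Unit and property tests for the family-code algebra."""

import pytest
from hypothesis import given, settings, strategies as st

from famtree.familycode import (
    BasicCode,
    CodeError,
    FamilyCode,
    FamilyType,
    KinshipCategory,
    classify_category,
    classify_family_type,
    compose_codes,
    degree_of,
    format_code,
    invert_code,
    parse_code,
    reduce_code,
)


def strs(codes):
    return sorted(format_code(c) for c in codes)


# ---------------------------------------------------------------------------
# parsing and formatting

@pytest.mark.parametrize("text, atoms", [
    ("0IM1AM", ["0IM", "1AM"]),           # a man's father
    ("0IW1AM", ["0IW", "1AM"]),           # a woman's father
    ("0IW", ["0IW"]),                     # self
    ("0IM1AM1AW", ["0IM", "1AM", "1AW"]),  # paternal grandmother
    ("0IM1aW1dX", ["0IM", "1aW", "1dX"]),  # step codes, case-sensitive
])
def test_parse_valid(text, atoms):
    code = parse_code(text)
    assert [str(a) for a in code.atoms] == atoms
    assert format_code(code) == text


@pytest.mark.parametrize("text", [
    "", "0I", "0IM1A", "1AM0IM", "0IM0IW", "0IX", "0IM3AM", "0IM1BM",
    "0IM1AZ", "xIM1AM",
])
def test_parse_invalid(text):
    with pytest.raises(CodeError):
        parse_code(text)


def test_parse_error_names_offending_triple():
    with pytest.raises(CodeError, match="1BM"):
        parse_code("0IM1BM")
    with pytest.raises(CodeError, match="offset 3|position 1"):
        parse_code("0IM0IW")


# ---------------------------------------------------------------------------
# degree of kinship

@pytest.mark.parametrize("text, degree", [
    ("0IM1AM", 1),        # parent, 1st degree
    ("0IW2AM", 2),        # older sibling, 2nd degree
    ("0IM1AM1AW", 2),     # grandparent
    ("0IM0OW1AM", 1),     # spouse's father: the spouse step weighs 0
    ("0IM0OW", 0),        # spouse, zero degree
    ("0IW", 0),           # self
    ("0IM1AM2AM1DW", 4),  # cousin
])
def test_degree(text, degree):
    assert degree_of(parse_code(text)) == degree


def test_degree_rejects_unreduced():
    with pytest.raises(CodeError, match="reduce"):
        degree_of(parse_code("0IM1AM1DM"))


# ---------------------------------------------------------------------------
# inversion

@pytest.mark.parametrize("text, ssex, fsex, expected", [
    ("0IM1AM", "M", "M", "0IM1DM"),        # father's son
    ("0IM1AM1AW", "M", "W", "0IW1DM1DM"),  # grandmother's son's son
    ("0IW", "W", "W", "0IW"),              # self is its own inverse
    ("0IM0OW", "M", "W", "0IW0OM"),
    ("0IW2AM", "W", "M", "0IM2DW"),        # older brother's younger sister
])
def test_invert(text, ssex, fsex, expected):
    assert format_code(invert_code(parse_code(text), ssex, fsex)) == expected


def test_invert_requires_known_family_sex():
    with pytest.raises(CodeError):
        invert_code(parse_code("0IM1AX"), "M", "X")


# ---------------------------------------------------------------------------
# composition

def test_compose_father_then_mother_is_paternal_grandmother():
    res = compose_codes("0IM1AM", "0IM1AW")
    assert not res.ambiguous
    assert format_code(res.code) == "0IM1AM1AW"


def test_compose_self_is_left_identity():
    res = compose_codes("0IM", "0IM1AW")
    assert not res.ambiguous
    assert format_code(res.code) == "0IM1AW"


def test_compose_fathers_child_is_self_or_sibling():
    res = compose_codes("0IM1AM", "0IM1DX")
    assert res.ambiguous
    assert strs(res.alternatives) == ["0IM", "0IM2UX"]


def test_compose_incompatible_genders_error():
    with pytest.raises(CodeError):
        compose_codes("0IM1AM", "0IW1AW")  # middle person M vs W


# ---------------------------------------------------------------------------
# reduction

def test_reduce_mothers_son_keeps_self_and_sibling():
    res = reduce_code("0IM1AW1DM")
    assert res.ambiguous
    assert strs(res.alternatives) == ["0IM", "0IM2UM"]


def test_reduce_mothers_daughter_of_man_is_sibling_only():
    # the subject is a man, so his mother's daughter cannot be himself
    res = reduce_code("0IM1AW1DW")
    assert not res.ambiguous
    assert format_code(res.code) == "0IM2UW"


def test_reduce_spouses_spouse_stays_flagged():
    # collapses to self only under monogamy, so the flag must stay
    res = reduce_code("0IM0OW0OM")
    assert res.ambiguous
    assert strs(res.alternatives) == ["0IM"]


def test_reduce_childs_parent_spouse_or_coparent():
    res = reduce_code("0IM1DM1AW")
    assert res.ambiguous  # the co-parent need not be a spouse
    assert strs(res.alternatives) == ["0IM0OW"]


def test_reduce_irreducible_unchanged():
    res = reduce_code("0IM1AM1AW")
    assert not res.ambiguous
    assert format_code(res.code) == "0IM1AM1AW"


def test_reduce_ordered_sibling_chain():
    # an older sibling's older sibling is an older sibling, never self
    res = reduce_code("0IM2AM2AW")
    assert not res.ambiguous
    assert format_code(res.code) == "0IM2AW"


def test_reduce_alternatives_are_realizable(nuclear_family):
    """Each surviving alternative of the mother's-son reduction is realized
    by a concrete pedigree (self: the subject himself; sibling: a brother)."""
    from famtree.expansion import enumerate_paths, path_to_code
    from famtree.pedigree import PedigreeGraph, Person

    # sibling alternative realized in a pedigree without birth years
    g = PedigreeGraph()
    for pid, sex in [("s", "M"), ("m", "W"), ("b", "M")]:
        g.add_person(Person(pid, sex))
    g.add_parent_edge("m", "s")
    g.add_parent_edge("m", "b")
    paths = [p for p in enumerate_paths(g, "s") if p.target == "b"]
    realized = {format_code(path_to_code(p, g)) for p in paths}
    alts = strs(reduce_code("0IM1AW1DM").alternatives)
    assert "0IM2UM" in realized
    assert set(alts) == {"0IM", "0IM2UM"}  # self realized trivially (s == s)


# ---------------------------------------------------------------------------
# classification

@pytest.mark.parametrize("text, category", [
    ("0IM1AM1AW", KinshipCategory.DIRECT_ANCESTOR),
    ("0IM0OW", KinshipCategory.SPOUSE),
    ("0IW2AM1DW", KinshipCategory.COLLATERAL_BLOOD),  # niece via brother
    ("0IM1DW1DM", KinshipCategory.DIRECT_DESCENDANT),
    ("0IM0OW1AM", KinshipCategory.AFFINAL),
    ("0IW", KinshipCategory.SELF),
    ("0IM2UM0OW", KinshipCategory.AFFINAL),  # brother's wife
])
def test_classify_category(text, category):
    assert classify_category(parse_code(text)) is category


@pytest.mark.parametrize("text, kwargs, ftype", [
    ("0IM1AM", {}, FamilyType.C1),
    ("0IM0OW", {}, FamilyType.A0),
    ("0IM1AM", {"has_adoptive": True}, FamilyType.R1),
    ("0IM1AM2AM1DW", {}, FamilyType.C2),          # cousin, degree 4
    ("0IM0OW1AM", {}, FamilyType.A1),             # spouse's father
    ("0IM0OW1AM2AM", {}, FamilyType.A2),          # spouse's uncle, degree 3
    ("0IM1aW", {}, FamilyType.A1),                # step parent: by marriage
])
def test_classify_family_type(text, kwargs, ftype):
    assert classify_family_type(parse_code(text), **kwargs) is ftype


def test_close_threshold_is_configurable():
    uncle = parse_code("0IM1AM2AM")  # degree 3
    assert classify_family_type(uncle) is FamilyType.C2
    assert classify_family_type(uncle, close_threshold=3) is FamilyType.C1


# ---------------------------------------------------------------------------
# properties

_SEXED = st.sampled_from("MW")
_NONSELF = [(0, "O"), (1, "A"), (1, "D"), (2, "A"), (2, "D"), (2, "U"),
            (1, "a"), (1, "d")]


@st.composite
def family_codes(draw, max_tail=4, reduced_only=False, sexed_only=False):
    self_atom = BasicCode(0, "I", draw(_SEXED))
    atoms = [self_atom]
    n = draw(st.integers(0, max_tail))
    for _ in range(n):
        deg, rel = draw(st.sampled_from(_NONSELF))
        sex = draw(_SEXED if sexed_only else st.sampled_from("MWX"))
        atoms.append(BasicCode(deg, rel, sex))
    code = FamilyCode(tuple(atoms))
    if reduced_only:
        try:
            degree_of(code)
        except CodeError:
            return draw(family_codes(max_tail=max_tail,
                                     reduced_only=True,
                                     sexed_only=sexed_only))
    return code


@settings(max_examples=300, derandomize=True)
@given(family_codes())
def test_parse_format_round_trip(code):
    assert parse_code(format_code(code)) == code


@settings(max_examples=300, derandomize=True)
@given(family_codes(reduced_only=True, sexed_only=True))
def test_invert_is_involution_and_preserves_degree(code):
    s, f = code.subject_sex, code.terminal_sex
    inv = invert_code(code, s, f)
    assert degree_of(inv) == degree_of(code)
    assert invert_code(inv, f, s) == code


@settings(max_examples=300, derandomize=True)
@given(family_codes(max_tail=2, sexed_only=True),
       family_codes(max_tail=2, sexed_only=True))
def test_degree_additive_when_composition_does_not_contract(a, b):
    if a.terminal_sex != b.subject_sex:
        return
    try:
        da, db = degree_of(a), degree_of(b)
    except CodeError:
        return
    res = compose_codes(a, b)
    if not res.ambiguous and len(res.code.atoms) == len(a.atoms) + len(b.tail):
        assert degree_of(res.code) == da + db
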