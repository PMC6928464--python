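"""Family-history-of-disease analysis on top of the family-tree records.

Cases are defined from claims rows (ICD-10 code range plus, per disease,
medication, hospital-admission or primary-diagnosis requirements), each
person is assigned family-history strata through their recorded kin, and
prevalence is directly standardized by five-year age groups against a fixed
standard population.  The module also produces the two descriptive reports
of the database build: parent/grandparent matching rates by birth cohort and
kin counts by degree and family type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Union

import numpy as np
import pandas as pd

from .pedigree import Person

AGE_BANDS = tuple(range(0, 90, 5))  # 5-year groups, 85+ open-ended


@dataclass(frozen=True)
class CaseDefinition:
    """One disease's claims-based case definition."""

    name: str
    code_ranges: tuple[tuple[str, int, int], ...]  # (letter, low, high)
    requires_medication: bool = False
    requires_admission: bool = False
    primary_dx_only: bool = False

    def code_matches(self, letter: str, number: int) -> bool:
        return any(letter == lt and lo <= number <= hi
                   for lt, lo, hi in self.code_ranges)


def default_case_definitions() -> tuple[CaseDefinition, ...]:
    """The five standard definitions: hypertension and diabetes need a
    disease code plus prescribed medication; ischemic heart disease,
    cerebrovascular disease and cancer need a hospital admission with the
    code, cancer counting primary diagnoses only."""
    return (
        CaseDefinition("hypertension", (("I", 10, 15),),
                       requires_medication=True),
        CaseDefinition("diabetes", (("E", 10, 14),),
                       requires_medication=True),
        CaseDefinition("ischemic_heart_disease", (("I", 20, 25),),
                       requires_admission=True),
        CaseDefinition("cerebrovascular_disease", (("I", 60, 69),),
                       requires_admission=True),
        CaseDefinition("cancer", (("C", 0, 97),),
                       requires_admission=True, primary_dx_only=True),
    )


_ICD_RE = re.compile(r"^([A-Z])(\d{2})")


def parse_icd10(code: str) -> Optional[tuple[str, int]]:
    m = _ICD_RE.match(str(code).strip().upper())
    if not m:
        return None
    return m.group(1), int(m.group(2))


def apply_case_definitions(
    claims: pd.DataFrame,
    definitions: Iterable[CaseDefinition] = None,
    reference_year: int = 2017,
) -> tuple[pd.DataFrame, int]:
    """Affected flags per (person, disease) from claims up to the reference
    year.  Returns (flags frame indexed by person_id, skipped-row count);
    rows whose ICD-10 code cannot be parsed are skipped and counted."""
    if definitions is None:
        definitions = default_case_definitions()
    definitions = list(definitions)
    parsed = claims["icd10"].map(parse_icd10)
    skipped = int(parsed.isna().sum())
    ok = parsed.notna() & (claims["year"] <= reference_year)
    sub = claims[ok].copy()
    letters = parsed[ok].str[0]
    numbers = parsed[ok].str[1]

    persons = pd.Index(claims["person_id"].unique(), name="person_id")
    flags = pd.DataFrame(False, index=persons,
                         columns=[d.name for d in definitions])
    for d in definitions:
        mask = pd.Series(
            [d.code_matches(lt, nb) for lt, nb in zip(letters, numbers)],
            index=sub.index,
        )
        if d.requires_medication:
            mask &= sub["medication"].astype(int) == 1
        if d.requires_admission:
            mask &= sub["admission"].astype(int) == 1
        if d.primary_dx_only:
            mask &= sub["primary_dx"].astype(int) == 1
        cases = sub.loc[mask, "person_id"].unique()
        flags.loc[flags.index.intersection(cases), d.name] = True
    return flags, skipped


# ---------------------------------------------------------------------------
# family-history strata

#: named kin filters over the record table; side-specific history follows
#: the code prefix (0I?1AM... = ancestors through the father, 0I?1AW...
#: through the mother)
KIN_FILTERS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "father": lambda r: r["FMLY_CD"].str.fullmatch(r"0I[MW]1AM"),
    "mother": lambda r: r["FMLY_CD"].str.fullmatch(r"0I[MW]1AW"),
    "parents": lambda r: r["FMLY_CD"].str.fullmatch(r"0I[MW]1A[MWX]"),
    "first_degree_blood": lambda r: (r["FMLY_DGR"] == 1)
        & r["FMLY_TYPE"].str.startswith("C"),
    "father_side": lambda r: r["FMLY_CD"].str.fullmatch(
        r"0I[MW]1AM(1[Aa][MWX])*"),
    "mother_side": lambda r: r["FMLY_CD"].str.fullmatch(
        r"0I[MW]1AW(1[Aa][MWX])*"),
}


def has_kin(
    records: pd.DataFrame,
    kin_filter: Union[str, Callable[[pd.DataFrame], pd.Series]] = "parents",
) -> pd.Series:
    """True for subjects with >= 1 recorded kin passing ``kin_filter``.

    A family history is only observable for these subjects; restricting an
    analysis to them separates 'no history' from 'history unknown'.
    """
    if isinstance(kin_filter, str):
        kin_filter = KIN_FILTERS[kin_filter]
    mask = kin_filter(records).astype("boolean").fillna(False).astype(bool)
    by_subject = mask.groupby(records["TG_ID"]).any()
    all_subjects = pd.Index(records["TG_ID"].unique(), name="person_id")
    return by_subject.reindex(all_subjects, fill_value=False).astype(bool)


def family_history_flag(
    records: pd.DataFrame,
    affected: pd.DataFrame,
    disease: str,
    kin_filter: Union[str, Callable[[pd.DataFrame], pd.Series]] = "parents",
) -> pd.Series:
    """True for every subject with >= 1 affected kin passing ``kin_filter``.

    ``records`` is the family-tree table (one row per directed subject-kin
    pair); ``affected`` the flags frame from
    :func:`apply_case_definitions`.  Returns a boolean series indexed by
    subject id covering every subject present in ``records``; persons
    without qualifying kin are False (the no-history stratum).
    """
    if isinstance(kin_filter, str):
        kin_filter = KIN_FILTERS[kin_filter]
    mask = kin_filter(records).astype("boolean").fillna(False).astype(bool)
    sub = records.loc[mask, ["TG_ID", "FMLY_ID"]].copy()
    aff = affected[disease] if disease in affected else pd.Series(dtype=bool)
    sub["kin_affected"] = sub["FMLY_ID"].map(aff).astype("boolean").fillna(False).astype(bool)
    by_subject = sub.groupby("TG_ID")["kin_affected"].any()
    all_subjects = pd.Index(records["TG_ID"].unique(), name="person_id")
    return by_subject.reindex(all_subjects, fill_value=False).astype(bool)


# ---------------------------------------------------------------------------
# direct age standardization

@dataclass(frozen=True)
class StandardPopulation:
    """Normalized five-year age-group weights for direct standardization."""

    weights: tuple[tuple[int, float], ...]  # (band lower bound, weight)

    def __post_init__(self) -> None:
        ws = [w for _, w in self.weights]
        if any(w < 0 for w in ws):
            raise ValueError("weights must be non-negative")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @staticmethod
    def band(age: int) -> int:
        return min(85, 5 * (max(age, 0) // 5))

    @classmethod
    def uniform(cls, bands: Iterable[int]) -> "StandardPopulation":
        bands = sorted(set(bands))
        w = 1.0 / len(bands)
        return cls(tuple((b, w) for b in bands))

    def restrict(self, bands: Iterable[int]) -> "StandardPopulation":
        """Renormalized weights over a subset of age bands.

        Used when comparing strata on their common age support, so that a
        band populated in one stratum only cannot bias the ratio."""
        bands = set(bands)
        kept = [(b, w) for b, w in self.weights if b in bands]
        total = sum(w for _, w in kept)
        if total <= 0:
            raise ValueError("no standard weight left on the given bands")
        return StandardPopulation(tuple((b, w / total) for b, w in kept))

    @classmethod
    def from_persons(cls, persons: Iterable[Person],
                     year: int) -> "StandardPopulation":
        """Age structure of a reference population alive in ``year`` —
        the synthetic analogue of standardizing to the insured population
        of a fixed year."""
        counts: dict[int, int] = {}
        for p in persons:
            if p.birth_year is None or p.birth_year > year:
                continue
            if p.death_year is not None and p.death_year <= year:
                continue
            b = cls.band(year - p.birth_year)
            counts[b] = counts.get(b, 0) + 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"no one alive in {year}")
        return cls(tuple((b, n / total) for b, n in sorted(counts.items())))


def age_standardized_prevalence(
    affected: pd.Series,
    persons: Iterable[Person],
    strata: dict[str, pd.Series],
    standard: StandardPopulation,
    reference_year: int = 2017,
) -> pd.DataFrame:
    """Directly standardized prevalence per family-history stratum.

    ``affected`` is a boolean series (one disease) indexed by person id;
    each stratum is a boolean membership series over the same ids.  For
    each stratum the five-year age-group prevalences are weighted by the
    standard population; age groups with no one in the stratum contribute
    0 and are counted in ``empty_groups``.  The sampling variance is the
    weighted binomial variance, reported as ``se``.  Strata with no
    members yield NaN.
    """
    people = [p for p in persons
              if p.birth_year is not None and p.birth_year <= reference_year
              and (p.death_year is None or p.death_year > reference_year)]
    frame = pd.DataFrame({
        "person_id": [p.person_id for p in people],
        "band": [StandardPopulation.band(reference_year - p.birth_year)
                 for p in people],
    }).set_index("person_id")
    frame["affected"] = affected.reindex(frame.index).astype("boolean").fillna(False).astype(bool)

    out = []
    for name, member in strata.items():
        member = member.reindex(frame.index, fill_value=False).astype(bool)
        sub = frame[member]
        n = len(sub)
        if n == 0:
            out.append((name, np.nan, np.nan, 0, 0,
                        len(standard.weights)))
            continue
        grp = sub.groupby("band")["affected"].agg(["sum", "count"])
        std = 0.0
        var = 0.0
        empty = 0
        for band, w in standard.weights:
            if band in grp.index:
                cases = grp.loc[band, "sum"]
                total = grp.loc[band, "count"]
                p = cases / total
                std += w * p
                var += w * w * p * (1 - p) / total
            else:
                empty += 1
        out.append((name, std, float(np.sqrt(var)), n,
                    int(sub["affected"].sum()), empty))
    return pd.DataFrame(
        out, columns=["stratum", "prevalence", "se", "n", "cases",
                      "empty_groups"],
    ).set_index("stratum")


def history_prevalence_analysis(
    records: pd.DataFrame,
    affected: pd.DataFrame,
    disease: str,
    persons: Iterable[Person],
    kin_filter: Union[str, Callable[[pd.DataFrame], pd.Series]] = "parents",
    standard: Optional[StandardPopulation] = None,
    reference_year: int = 2017,
) -> pd.DataFrame:
    """Standardized prevalence in the history vs no-history stratum.

    Subjects are restricted to those whose qualifying kin are recorded at
    all (history is unobservable otherwise), and the standard population is
    renormalized to the age bands occupied by both strata so the two
    prevalences are compared on common support.
    """
    persons = list(persons)
    if standard is None:
        standard = StandardPopulation.from_persons(persons, reference_year - 2)
    known = has_kin(records, kin_filter)
    hist = family_history_flag(records, affected, disease, kin_filter)
    strata = {"history": known & hist, "no_history": known & ~hist}

    alive = {p.person_id: StandardPopulation.band(reference_year - p.birth_year)
             for p in persons
             if p.birth_year is not None and p.birth_year <= reference_year
             and (p.death_year is None or p.death_year > reference_year)}
    bands_by_stratum = []
    for member in strata.values():
        ids = member[member].index
        bands_by_stratum.append({alive[i] for i in ids if i in alive})
    common = bands_by_stratum[0] & bands_by_stratum[1]
    std = standard.restrict(common)
    return age_standardized_prevalence(
        affected[disease], persons, strata, std, reference_year)


def prevalence_ratio(std_table: pd.DataFrame, numerator: str,
                     denominator: str) -> tuple[float, float]:
    """Ratio of standardized prevalences with a delta-method SE."""
    p1, s1 = std_table.loc[numerator, ["prevalence", "se"]]
    p0, s0 = std_table.loc[denominator, ["prevalence", "se"]]
    ratio = p1 / p0
    se = ratio * np.sqrt((s1 / p1) ** 2 + (s0 / p0) ** 2)
    return float(ratio), float(se)


# ---------------------------------------------------------------------------
# cohort reports

def birth_decade(year) -> str:
    if pd.isna(year):
        return "unknown"
    year = int(year)
    if year < 1960:
        return "-1950s"
    return f"{10 * (year // 10)}s"


_PARENT_RE = re.compile(r"^0I[MW]1[Aa][MWX]$")
_FATHER_RE = re.compile(r"^0I[MW]1[Aa]M$")
_MOTHER_RE = re.compile(r"^0I[MW]1[Aa]W$")
_GRANDPARENT_RE = re.compile(r"^0I[MW]1[Aa][MWX]1[Aa][MWX]$")


def matching_rate_table(
    records: pd.DataFrame,
    persons: Iterable[Person],
    reference_year: int = 2017,
) -> pd.DataFrame:
    """Share of persons with a matched father / mother / any parent / any
    parent or grandparent, by sex and birth decade.

    Only kin with a shared household or insurance-unit history (HHRR_CD
    present) count as matched; denominators are persons alive in the
    reference year.
    """
    people = [p for p in persons
              if p.birth_year is not None and p.birth_year <= reference_year
              and (p.death_year is None or p.death_year > reference_year)]
    linked = records[records["HHRR_CD"].notna()]
    cd = linked["FMLY_CD"].astype(str)
    cat = pd.DataFrame({
        "TG_ID": linked["TG_ID"],
        "father": cd.str.fullmatch(_FATHER_RE),
        "mother": cd.str.fullmatch(_MOTHER_RE),
        "grandparent": cd.str.fullmatch(_GRANDPARENT_RE),
    })
    agg = cat.groupby("TG_ID")[["father", "mother", "grandparent"]].any()

    rows = []
    for p in people:
        hit = agg.loc[p.person_id] if p.person_id in agg.index else None
        father = bool(hit is not None and hit["father"])
        mother = bool(hit is not None and hit["mother"])
        grand = bool(hit is not None and hit["grandparent"])
        rows.append((p.sex, birth_decade(p.birth_year), father, mother,
                     father or mother, father or mother or grand))
    df = pd.DataFrame(rows, columns=["sex", "cohort", "father", "mother",
                                     "any_parent", "any_parent_or_grandparent"])
    table = df.groupby(["sex", "cohort"]).agg(
        n=("father", "size"),
        father=("father", "mean"),
        mother=("mother", "mean"),
        any_parent=("any_parent", "mean"),
        any_parent_or_grandparent=("any_parent_or_grandparent", "mean"),
    )
    for col in ["father", "mother", "any_parent", "any_parent_or_grandparent"]:
        table[col] = 100.0 * table[col]
    return table


def kin_count_table(
    records: pd.DataFrame,
    include_spouse_in_affinity: bool = False,
) -> pd.DataFrame:
    """Kin counts by subject sex and birth decade: one column per degree of
    kinship 1-4 plus consanguinity/affinity totals.

    Blood types (C1, C2) and adoptive kin (R1, blood-equivalent in law)
    count as consanguinity; A1-A3 as affinity.  The zero-degree spouse
    (A0) joins the affinity column only when
    ``include_spouse_in_affinity`` is set, in which case the degree
    columns (which start at 1) no longer sum to the type columns.
    """
    if len(records) == 0:
        cols = ["n_subjects", "degree_1", "degree_2", "degree_3", "degree_4",
                "consanguinity", "affinity"]
        return pd.DataFrame(columns=cols)
    df = records.copy()
    df["cohort"] = df["TG_BYEAR"].map(birth_decade)
    df["consang"] = df["FMLY_TYPE"].isin(["C1", "C2", "R1"]) \
        & (df["FMLY_DGR"] >= 1)
    aff_types = ["A1", "A2", "A3"] + (
        ["A0"] if include_spouse_in_affinity else [])
    df["affinal"] = df["FMLY_TYPE"].isin(aff_types)
    if not include_spouse_in_affinity:
        df["affinal"] &= df["FMLY_DGR"] >= 1

    def one(group: pd.DataFrame) -> pd.Series:
        out = {"n_subjects": group["TG_ID"].nunique()}
        for d in (1, 2, 3, 4):
            out[f"degree_{d}"] = int((group["FMLY_DGR"] == d).sum())
        out["consanguinity"] = int(group["consang"].sum())
        out["affinity"] = int(group["affinal"].sum())
        return pd.Series(out)

    return df.groupby(["TG_SEX_TYPE", "cohort"]).apply(one, include_groups=False)
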