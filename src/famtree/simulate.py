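"""Synthetic multi-generation population, roster snapshots and claims.

The generator emulates the shape of the source data the family-tree build
consumes, with no real data involved:

* a population of founder couples and their descendants over several
  generations, with marry-in spouses and per-generation birth-year windows;
* yearly household and insurance-unit rosters that encode, as in the source
  systems, only each member's relation to the unit head — with the two
  sources electronized from different start years (2002 for insurance
  eligibility, 2004 for the resident register), so that people who died or
  left their parental household before those years are never observed
  together with their parents;
* claims rows with familially aggregated disease: a person's risk is their
  age-band base prevalence multiplied by a relative risk when at least one
  biological parent is affected.

Everything is driven by a single integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .household_linkage import MembershipSnapshot
from .pedigree import PedigreeGraph, Person

CLAIMS_COLUMNS = ["person_id", "year", "icd10", "admission", "medication",
                  "primary_dx"]


@dataclass(frozen=True)
class DiseaseParams:
    """Generative parameters for one familially aggregated disease."""

    name: str
    icd_range: tuple[str, int, int]       # (letter, low number, high number)
    requires_medication: bool = False
    requires_admission: bool = False
    primary_dx_only: bool = False
    #: (age lower bound, prevalence) steps, ascending
    base_prevalence: tuple[tuple[int, float], ...] = (
        (0, 0.005), (30, 0.03), (40, 0.08), (50, 0.15), (60, 0.25), (70, 0.32),
    )
    parental_rr: float = 2.0

    def base_at(self, age: int) -> float:
        p = self.base_prevalence[0][1]
        for lo, val in self.base_prevalence:
            if age >= lo:
                p = val
        return p


def default_diseases() -> tuple[DiseaseParams, ...]:
    """The five diseases of the standard family-history analysis."""
    return (
        DiseaseParams("hypertension", ("I", 10, 15), requires_medication=True,
                      base_prevalence=((0, 0.005), (30, 0.04), (40, 0.10),
                                       (50, 0.22), (60, 0.35), (70, 0.45))),
        DiseaseParams("diabetes", ("E", 10, 14), requires_medication=True,
                      base_prevalence=((0, 0.003), (30, 0.02), (40, 0.06),
                                       (50, 0.12), (60, 0.20), (70, 0.25))),
        DiseaseParams("ischemic_heart_disease", ("I", 20, 25),
                      requires_admission=True,
                      base_prevalence=((0, 0.001), (40, 0.01), (50, 0.03),
                                       (60, 0.07), (70, 0.12))),
        DiseaseParams("cerebrovascular_disease", ("I", 60, 69),
                      requires_admission=True,
                      base_prevalence=((0, 0.001), (40, 0.008), (50, 0.02),
                                       (60, 0.06), (70, 0.12))),
        DiseaseParams("cancer", ("C", 0, 97), requires_admission=True,
                      primary_dx_only=True,
                      base_prevalence=((0, 0.002), (30, 0.01), (40, 0.03),
                                       (50, 0.06), (60, 0.10), (70, 0.15))),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_founder_couples: int = 30
    n_generations: int = 4
    fertility: float = 2.2          # mean children per couple (Poisson)
    marriage_prob: float = 0.8
    #: per-generation birth-year windows; children are additionally
    #: constrained to a plausible maternal age (20-42)
    birth_year_ranges: tuple[tuple[int, int], ...] = (
        (1920, 1935), (1945, 1965), (1972, 1992), (2000, 2015),
    )
    household_split_age: int = 30
    eligibility_start_year: int = 2002
    register_start_year: int = 2004
    end_year: int = 2017
    record_coverage_before_start: float = 0.0
    mean_lifespan: float = 76.0
    sd_lifespan: float = 11.0
    diseases: tuple[DiseaseParams, ...] = field(default_factory=default_diseases)
    decoy_claim_rate: float = 0.05  # code-without-required-flag noise rows

    def __post_init__(self) -> None:
        for p in (self.marriage_prob, self.record_coverage_before_start):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_generations < 2:
            raise ValueError("need at least 2 generations")

    def with_full_observation(self) -> "SimulationConfig":
        """Variant with rosters observed from before everyone's birth."""
        first = min(lo for lo, _ in self.birth_year_ranges)
        return replace(self, eligibility_start_year=first,
                       register_start_year=first)


@dataclass
class Population:
    persons: list[Person]
    graph: PedigreeGraph

    @property
    def by_id(self) -> dict[str, Person]:
        return {p.person_id: p for p in self.persons}


def _birth_windows(config: SimulationConfig) -> list[tuple[int, int]]:
    wins = list(config.birth_year_ranges)
    while len(wins) < config.n_generations:
        lo, hi = wins[-1]
        wins.append((lo + 27, hi + 27))
    return wins


def simulate_population(config: SimulationConfig) -> Population:
    """Generate the ground-truth pedigree.

    Founder couples are drawn in the first birth window; each subsequent
    generation consists of the couples' Poisson-fertility children, who
    marry (with ``marriage_prob``) spouses spawned without ancestry of
    their own, so all kinship flows through the founder lines.
    """
    rng = np.random.default_rng(config.seed)
    windows = _birth_windows(config)
    graph = PedigreeGraph()
    persons: list[Person] = []
    counter = [0]

    def new_person(sex: str, birth: int) -> Person:
        counter[0] += 1
        lifespan = max(1, int(round(rng.normal(config.mean_lifespan,
                                               config.sd_lifespan))))
        p = Person(f"P{counter[0]:06d}", sex, int(birth), int(birth) + lifespan)
        persons.append(p)
        graph.add_person(p)
        return p

    couples: list[tuple[Person, Person]] = []
    lo, hi = windows[0]
    for _ in range(config.n_founder_couples):
        hb = int(rng.integers(lo, hi + 1))
        wb = hb + int(rng.integers(-4, 5))
        h = new_person("M", hb)
        w = new_person("W", wb)
        graph.add_spouse_edge(h.person_id, w.person_id)
        couples.append((h, w))

    for gen in range(1, config.n_generations):
        glo, ghi = windows[gen]
        next_couples: list[tuple[Person, Person]] = []
        for father, mother in couples:
            mb = mother.birth_year
            blo = max(glo, mb + 20)
            # children require both parents alive at (or just before) birth
            bhi = min(ghi, mb + 42, father.death_year - 1,
                      mother.death_year - 1)
            if blo > bhi:
                continue
            n_kids = int(rng.poisson(config.fertility))
            births = sorted(int(b) for b in rng.integers(blo, bhi + 1,
                                                         size=n_kids))
            for birth in births:
                sex = "M" if rng.random() < 0.5 else "W"
                child = new_person(sex, birth)
                graph.add_parent_edge(father.person_id, child.person_id)
                graph.add_parent_edge(mother.person_id, child.person_id)
                # the final generation is still of pre-marriage age at the
                # end of the observation window; no spouses are spawned
                if gen < config.n_generations - 1 \
                        and rng.random() < config.marriage_prob:
                    sp_sex = "W" if sex == "M" else "M"
                    sp_birth = birth + int(rng.integers(-4, 5))
                    spouse = new_person(sp_sex, sp_birth)
                    graph.add_spouse_edge(child.person_id, spouse.person_id)
                    pair = (child, spouse) if sex == "M" else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples
    return Population(persons, graph)


# ---------------------------------------------------------------------------
# roster snapshots

def _marriage_year(graph: PedigreeGraph, a: Person, b: Person) -> int:
    """Marriage year implied by the pedigree: just before the first shared
    child, or a conventional age for childless couples."""
    shared = set(graph.children_of(a.person_id)) & set(
        graph.children_of(b.person_id))
    births = [graph.persons[c].birth_year for c in shared
              if graph.persons[c].birth_year is not None]
    if births:
        return min(births) - 1
    known = [y for y in (a.birth_year, b.birth_year) if y is not None]
    return (max(known) if known else 0) + 27


def emit_snapshots(
    persons: list[Person],
    graph: PedigreeGraph,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[MembershipSnapshot]:
    """Yearly household and insurance-unit rosters implied by the pedigree.

    A married couple forms a unit from its marriage year; children belong to
    their parents' unit until they marry or reach ``household_split_age``;
    everyone else heads a single-person unit.  Insurance units mirror the
    households here, but the two sources start in different years, so they
    cover different slices of the population history.  Rows before a
    source's start year appear only with probability
    ``record_coverage_before_start``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    people = {p.person_id: p for p in persons}

    couples = []
    for a_id, b_id in graph.spouse_edges():
        a, b = people[a_id], people[b_id]
        head, other = (a, b) if (a.sex == "M" or b.sex == "W") else (b, a)
        couples.append((head, other, _marriage_year(graph, a, b)))

    # person -> (couple index, role) once married
    marriage_of: dict[str, tuple[int, int]] = {}
    for idx, (h, o, my) in enumerate(couples):
        marriage_of[h.person_id] = (idx, my)
        marriage_of[o.person_id] = (idx, my)

    def departure_year(p: Person) -> int:
        leave = p.birth_year + config.household_split_age
        if p.person_id in marriage_of:
            leave = min(leave, marriage_of[p.person_id][1])
        return leave

    starts = {"eligibility": config.eligibility_start_year,
              "register": config.register_start_year}
    min_birth = min(p.birth_year for p in persons)
    first_year = max(min(starts.values()), min_birth)
    if config.record_coverage_before_start > 0:
        first_year = min_birth

    def alive(p: Person, year: int) -> bool:
        return p.birth_year <= year and (p.death_year is None
                                         or year < p.death_year)

    snapshots: list[MembershipSnapshot] = []
    for year in range(first_year, config.end_year + 1):
        # membership plan for this year: unit key -> [(person, role)]
        units: dict[str, list[tuple[Person, str]]] = {}
        for p in persons:
            if not alive(p, year):
                continue
            placed = False
            if p.person_id in marriage_of:
                idx, my = marriage_of[p.person_id]
                if year >= my:
                    h, o, _ = couples[idx]
                    if alive(h, year):
                        role = "head" if p is h else "spouse"
                    else:
                        role = "head"  # widowed survivor heads the unit
                    units.setdefault(f"C{idx}", []).append((p, role))
                    placed = True
            if not placed and year < departure_year(p):
                parents = [q for q in graph.parents_of(p.person_id)
                           if alive(people[q], year)]
                if parents:
                    par = people[parents[0]]
                    if par.person_id in marriage_of:
                        idx, my = marriage_of[par.person_id]
                        units.setdefault(f"C{idx}", []).append((p, "child"))
                        placed = True
            if not placed:
                units.setdefault(f"S{p.person_id}", []).append((p, "head"))

        for ukey, members in units.items():
            heads = [p for p, role in members if role == "head"]
            if not heads:
                continue
            head = sorted(heads, key=lambda q: q.person_id)[0]
            self_atom = f"0I{head.sex}"
            for source, start in starts.items():
                if year < start:
                    if rng.random() >= config.record_coverage_before_start:
                        continue
                unit_id = f"{'H' if source == 'register' else 'E'}{ukey}"
                for p, role in members:
                    if p is head:
                        rel = self_atom
                    elif role == "spouse":
                        rel = f"{self_atom}0O{p.sex}"
                    else:
                        rel = f"{self_atom}1D{p.sex}"
                    snapshots.append(MembershipSnapshot(
                        unit_id, p.person_id, rel, year, source))
    return snapshots


# ---------------------------------------------------------------------------
# claims

def draw_affection(
    population: Population,
    config: SimulationConfig,
    reference_year: int = 2017,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Ground-truth affected status per person and disease.

    Persons are processed in birth order so parents are always decided
    first; a person's probability is the age-band base prevalence times the
    disease's parental relative risk when any biological parent is
    affected, capped at 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    graph = population.graph
    ordered = sorted(population.persons, key=lambda p: (p.birth_year,
                                                        p.person_id))
    out: dict[str, dict[str, bool]] = {d.name: {} for d in config.diseases}
    for p in ordered:
        age = reference_year - p.birth_year
        dead = p.death_year is not None and p.death_year <= reference_year
        bio_parents = [q for q, bond in graph.parents_of(p.person_id).items()
                       if bond == "biological"]
        for dis in config.diseases:
            if dead or age < 0:
                out[dis.name][p.person_id] = False
                continue
            prob = dis.base_at(age)
            if any(out[dis.name].get(q, False) for q in bio_parents):
                prob = min(1.0, prob * dis.parental_rr)
            out[dis.name][p.person_id] = bool(rng.random() < prob)
    df = pd.DataFrame(out)
    df.index.name = "person_id"
    return df


def simulate_claims(
    population: Population,
    config: SimulationConfig,
    reference_year: int = 2017,
    rng: Optional[np.random.Generator] = None,
    affection: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Claims rows realizing the drawn affection status.

    Every affected person emits at least one row satisfying the disease's
    case definition (code range plus medication / admission / primary
    diagnosis requirements).  A small rate of decoy rows carries a disease
    code *without* the required flags, which a correct case definition must
    ignore.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if affection is None:
        affection = draw_affection(population, config, reference_year,
                                   np.random.default_rng(config.seed + 2))
    rows = []

    def code_for(dis: DiseaseParams) -> str:
        letter, lo, hi = dis.icd_range
        return f"{letter}{int(rng.integers(lo, hi + 1)):02d}"

    for p in population.persons:
        last = reference_year
        if p.death_year is not None:
            last = min(last, p.death_year)
        first = max(p.birth_year, 2002)
        if first > last:
            continue
        for dis in config.diseases:
            affected = bool(affection.loc[p.person_id, dis.name])
            if affected:
                for _ in range(1 + int(rng.poisson(0.7))):
                    rows.append((
                        p.person_id, int(rng.integers(first, last + 1)),
                        code_for(dis),
                        1 if dis.requires_admission else int(rng.random() < 0.3),
                        1 if dis.requires_medication else int(rng.random() < 0.2),
                        1 if dis.primary_dx_only else int(rng.random() < 0.7),
                    ))
            elif rng.random() < config.decoy_claim_rate:
                # a code sighting that fails the definition's flags
                rows.append((
                    p.person_id, int(rng.integers(first, last + 1)),
                    code_for(dis),
                    0 if dis.requires_admission else 1,
                    0 if dis.requires_medication else 1,
                    0 if dis.primary_dx_only else 1,
                ))
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
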