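# Methods

This note documents the models and procedures `famtree` implements, the
assumptions behind them, and the choices made where the design was open.

## 1. The code algebra

A family code is a sequence of atoms, each `degree digit + relation letter
+ gender letter`.  Nine degree/relation pairs are admissible (`0I`, `0O`,
`1A`, `1D`, `2A`, `2D`, `2U`, `1a`, `1d`); gender letters are `M`, `W`, `X`.
Codes are read **subject → family member**: the leading atom is the
subject's self atom (`0IM`/`0IW`), and the gender letter of each later atom
is the sex of the person *reached* by that step.  This directional
convention makes inversion well defined: reverse the tail, invert each
relation (parent ↔ child, older ↔ younger sibling; spouse and unordered
sibling are self-inverse), and shift the gender letters so each atom again
names the person reached along the reversed chain.  Given both end sexes,
inversion is an involution and preserves degree.

**Degree of kinship** is the sum of the tail atoms' degree digits:
parent/child steps count 1, sibling steps 2 (up to the shared parent and
down again), spouse steps 0.  An affinal relative's degree is therefore the
blood degree on the spouse's side.  Step atoms (`1a`/`1d`) count 1 like
their biological counterparts; stepness is carried as metadata and surfaces
in the family type, not in the degree.

**Reduction.**  Composing two codes through a shared middle person can
create contractible patterns.  The rewrite rules are applied exhaustively
and are *identity-blind* (no person ids at this level) but *sex-aware* — an
alternative is kept only if some concrete pedigree realizes it:

| pattern | alternatives | note |
|---------|--------------|------|
| `1A·1D` | ε (self), `2U` | parent's child; ε only if the reached sex matches the previous person |
| `1D·1A` | ε, `0O` | child's parent; stays flagged — the co-parent need not be a spouse |
| `0O·0O` | ε | spouse's spouse; stays flagged — collapses to self only under monogamy |
| `2x·2y` | ε, `2U` | sibling's sibling; same-direction chains (`2A·2A`, `2D·2D`) keep their direction and can never be ε |

The result is a set of realizable alternatives plus an ambiguity flag; the
reported representative is the shortest (then lexicographically first)
alternative.  Monogamy is deliberately *not* assumed for correctness.
Identity-aware reduction — dropping the ε alternative because the two
people are known to be distinct — happens only where person ids exist: in
the roster-composition step of the linkage module.

**Family types.**  `C1`/`C2` split blood relatives at a configurable
`close_threshold` (default: degree ≤ 2 — the record layout never defines
"close", so it is a knob).  `A0` is the spouse, `A1`/`A2` split affinal kin
at the same threshold.  Step kin are typed as affinal (a step parent is a
parent's spouse), adoptive bonds map to `R1`.  `A3` (old-law affinity) is
accepted on input but never produced.

## 2. Pedigree and path model

The pedigree stores persons, typed parent edges (biological / step /
adoptive, at most two biological parents, acyclic, parent older than child
when years are known) and spouse edges.  Siblings are never stored; they
are derived from shared biological parents, so there is one source of
truth.  Half and full siblings both get sibling atoms and degree 2 (the
code set has no half-sibling atom); the older/younger letters come from the
two siblings' birth years, falling back to `2U` on ties or unknowns.

A **kinship path** used by the expansion has the shape
`[spouse]? up* down* [spouse]?`: a blood path through a common ancestor,
optionally entered through the subject's marriage and/or left through the
relative's marriage.  This mirrors the statutory scope of affinity — a
spouse's blood relatives, a blood relative's spouse, and a spouse's blood
relative's spouse — while chains of the form blood–spouse–blood (the
old-law `A3` scope) are excluded.  Up-down pivots through a shared
biological parent contract to a single sibling step, so the degree of the
emitted code equals the path weight (1 per parent/child edge, 0 per spouse
edge).  Pivots *down through a shared child and up to the co-parent* are
not kinship paths; when the co-parents are married the spouse edge
dominates them anyway.

Per unordered pair one **canonical path** is chosen: minimum of (degree,
spouse steps, non-biological steps, code string, person-id chain) — the
last key makes the winner unique even when two distinct paths spell the
same code.  The record table stores both directions; the mirrored record is
generated by reversing the canonical path, which coincides with code
inversion whenever both sexes are known.  Records are sorted by
(`TG_ID`, `FMLY_ID`), so output is byte-identical across runs.

The independent check on all of this is a deliberately naive
`kinship_distance_oracle`: exhaustive simple-path search with the same edge
weights, sharing no code with the production path enumeration.  Tests
verify degree agreement and pair completeness over random pedigrees.

## 3. Linkage from rosters

Rosters give one row per (unit, person, year, source), with the person's
relation to the unit head encoded in the same code grammar (one grammar for
everything; head rows carry the bare self atom, exactly one per
unit-year).  Edge evidence comes from

* first-degree head-member codes (parent, child, spouse, step variants),
  taken as direct claims, and
* member-member compositions `invert(head→a) ∘ (head→b)`, kept only when
  unambiguous after dropping the self alternative (distinct ids).  The
  composition "head's spouse × head's child" cannot distinguish a parent
  from a step-parent; it defaults to biological only when the age gap is a
  plausible parental age (15–70 years, configurable), else step.

Claims accumulate across years and sources and are resolved per pair; on
contradiction the resident register (the civil record) beats the insurance
eligibility file, direct claims beat composed ones, and every conflict is
logged with its supporting rows.  Adding snapshots can only add evidence,
never remove an edge.  The `HHRR_CD` column is computed independently of
edge inference: 1 = the pair ever shared both a register household and an
eligibility unit, 2 = household only, 3 = insurance unit only.

## 4. The synthetic population

The generator emulates the *shape* of the source data, not Korean
demography:

* founder couples drawn in a first birth window (1920–1935 by default),
  then per-generation windows (1945–1965, 1972–1992, 2000–2015, default 4
  generations) intersected with a plausible maternal age of 20–42 and the
  parents' lifetimes;
* Poisson fertility (mean 2.2 children per couple); children marry with
  probability 0.8, spouses are spawned without ancestry of their own
  (all kinship flows through founder lines, which keeps pedigrees
  monogamous and non-inbred); the final generation is still of
  pre-marriage age within the observation window and gets no spouses;
* lifespans N(76, 11²) years, which makes the founder generation die
  around the electronization years — the mechanism behind missing
  ancestors;
* households: a couple forms a unit at marriage (year of first child − 1,
  or a conventional age-27 year if childless); children stay until
  marriage or age 30; everyone else heads a singleton unit.  Insurance
  units mirror household composition but the two sources start in 2002
  (eligibility) and 2004 (register), so they observe different slices of
  history.  `with_full_observation()` moves both start years before all
  births for recovery tests.

Disease is a per-person Bernoulli: age-band base prevalence (five-year
bands, stepwise rising with age) multiplied by the disease's parental
relative risk (default 2.0) when ≥ 1 biological parent is affected, capped
at 1, drawn in birth order so parents are always decided first.  People
dead by the reference year are not cases and emit no claims, so the
generative truth and the claims-derived flags agree by construction.
Affected persons emit claim rows satisfying their case definition;
unaffected persons occasionally emit *decoy* rows carrying the disease code
without the required medication/admission/primary-diagnosis flags, which a
correct case definition must ignore.

What the generator does **not** model: migration, divorce, remarriage and
step/adoptive families (the step/adoptive code paths are exercised by
hand-built fixtures instead), assortative disease in couples, mortality
differentials by disease, and within-population marriage (no
consanguineous marriages).  Passing tests therefore demonstrate the
correctness of the algebra, linkage and bookkeeping under these idealized
conditions, not demographic realism.

## 5. Analysis layer

Case definitions follow the usual claims conventions: hypertension
(I10–I15) and diabetes (E10–E14) require a prescribed medication; ischemic
heart disease (I20–I25), cerebrovascular disease (I60–I69) and cancer
(C00–C97, primary diagnosis only) require a hospital admission.  Rows with
unparseable ICD-10 codes are skipped and counted.  Age is computed as
reference year − birth year (completed-year convention).

Family-history strata are predicates over the record table; presets cover
parents, first-degree blood kin, and father-/mother-side ancestors (code
prefix `0I?1AM…` / `0I?1AW…` with an all-ancestor tail).  Strata may
overlap (both parents affected counts on both sides).

Prevalence is **directly standardized** over five-year age bands:
Σ w_g · (cases_g / n_g), with the binomial variance Σ w_g² p_g(1−p_g)/n_g
reported as an SE.  Bands empty in a stratum contribute 0 and are counted.
Because of that convention, comparing two strata with different age
support biases their ratio; `history_prevalence_analysis` therefore
restricts subjects to those with recorded qualifying kin (history is
unobservable otherwise) and renormalizes the standard to the bands
occupied by *both* strata before taking the ratio, whose SE comes from the
delta method.  No hypothesis tests are performed; the module reports
estimates and sampling SEs only.

The matching-rate report counts a parent or grandparent as matched only
when the record carries a co-membership history (`HHRR_CD` present).  In
the synthetic setting the denominators are restricted to persons whose
parents exist in the simulated world at all — founders and married-in
spouses have none by construction, an artifact of the population boundary
that has no real-data analogue.  The kin-count report partitions records
of degree 1–4 into consanguinity (C1, C2, and R1 — adoptive kin are
blood-equivalent in law) versus affinity (A1–A3); whether the zero-degree
spouse joins the affinity column is a flag, off by default so the degree
columns and the type columns sum to the same total.

## 6. Problem sizes and numerical conventions

The shipped checks use: 100 random pedigrees of ≤ 40 persons for oracle
agreement; a ~700-person population for the matching-rate gradient; a
~50 000-person, 3-generation population for relative-risk recovery
(point estimate within 3 SE of the simulated RR 2.0) plus ten ~7 000-person
replicates for the direction test; the standardization identity is checked
to 1e-12 on equally occupied bands, where uniform weights coincide with the
population's own age structure and standardized equals crude prevalence
exactly.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; deterministic tie-breaks (code string, then
person-id chain) make every pipeline output byte-reproducible.
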