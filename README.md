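# famtree

Construction of a population-scale **family-tree database** from
head-of-household roster data, built around a compositional **family-code
algebra** for interpersonal kinship, plus the standard downstream analysis:
claims-based disease definitions and age-standardized prevalence by
family-history stratum.

## The problem

Administrative data sources (health-insurance eligibility files, resident
registers) record each person's relationship *to the head of their unit*
only.  From "head's spouse" and "head's son" alone you cannot directly query
the relationship between two arbitrary people, and relationships across
households are lost entirely.  Yet person-to-person kinship — who is whose
parent, sibling, cousin, in-law — is exactly what family-history
epidemiology and family-structure research need.

`famtree` solves this with a small code algebra.  A **family code** is a
string of three-character atoms `degree digit + relation letter + gender
letter` tracing a chain of elementary steps from a subject to a relative:

| atom | meaning | degree |
|------|---------|--------|
| `0I` | self    | 0 |
| `0O` | spouse  | 0 |
| `1A` / `1D` | parent / child | 1 |
| `1a` / `1d` | step-parent / step-child | 1 |
| `2A` / `2D` / `2U` | older / younger / unordered sibling | 2 |

with gender letters `M`, `W`, `X` (unspecified).  Every code starts with the
subject's self atom: `0IM1AM` is a man's father, `0IM1AM1AW` his paternal
grandmother ("one's father's mother").  The algebra supports:

* **degree of kinship** (*chon*): the sum of tail atom degrees — spouse
  steps weigh 0, so an in-law's degree is the blood degree on the spouse's
  side;
* **inversion** — the same relationship read from the relative's end
  (`0IM1AM` inverts to `0IM1DM`, "father's son");
* **composition and reduction** — chaining two codes through a shared
  person and contracting patterns like parent-then-child.  Contractions
  that head-relative data cannot resolve (a parent's child may be the
  subject or a sibling; a child's other parent need not be a spouse) return
  *all realizable alternatives* with an ambiguity flag instead of guessing;
* **classification** — direct ancestor / descendant, collateral blood,
  spouse, affinal; and the record-layout family types C1/C2 (close /
  non-close blood), A0 (spouse), A1/A2 (affinity), R1 (adoptive).

On top of the algebra, the package reconstructs a pedigree from yearly unit
rosters of two sources (insurance *eligibility* units and resident
*register* households, electronized from 2002 and 2004 respectively),
enumerates every pair of persons within the **fourth degree of kinship**,
and emits a two-directional record table (`TG_ID, FMLY_ID, …, FMLY_CD,
FMLY_DGR, FMLY_TYPE, HHRR_CD`).  A synthetic-population generator provides
multi-generation households, cohort-dependent record missingness, and
familially aggregated disease, so the whole pipeline is testable without
any real data.

## Worked example

One-shot algebra queries:

```console
$ famtree code degree 0IM1AM1AW        # a man's paternal grandmother
2
$ famtree code invert 0IM1AM --subject-sex M --family-sex M
0IM1DM
$ famtree code compose 0IM1AM 0IM1AW   # father's mother
0IM1AM1AW
$ famtree code compose 0IM1AM 0IM1DX   # father's child: self or sibling
ambiguous: 0IM | 0IM2UX
```

The full pipeline on a synthetic population (all numbers below are actual
output for seed 5):

```console
$ famtree simulate --seed 5 --founder-couples 4 --full-observation --out-prefix demo
{"seed": 5, "persons": 102, "snapshot_rows": 6568, "claims_rows": 38}
$ famtree link --snapshots demo_snapshots.csv --persons demo_persons.csv \
      --out-edges demo_linked.csv
{"rows_read": 6568, "edges_added": 163, "conflicts": 0, "rejects": 0}
$ famtree expand --persons demo_persons.csv --edges demo_linked.csv \
      --snapshots demo_snapshots.csv --out demo_records.csv
{"records": 2738}
$ head -4 demo_records.csv
TG_ID,FMLY_ID,TG_SEX_TYPE,TG_BYEAR,FMLY_SEX_TYPE,FMLY_BYEAR,FMLY_CD,FMLY_DGR,FMLY_TYPE,HHRR_CD
P000001,P000002,M,1930,W,1933,0IM0OW,0,A0,1
P000001,P000009,M,1930,M,1953,0IM1DM,1,C1,1
P000001,P000010,M,1930,W,1954,0IM1DM0OW,1,A1,
```

Reading the records: person `P000001` (man, born 1930) has a spouse
(`0IM0OW`, zero degree, family type A0, shared household and insurance
history), a son (`0IM1DM`, first degree, close blood C1) and a
daughter-in-law (`0IM1DM0OW`, first degree by affinity, A1, never
co-resident — empty `HHRR_CD`).  The 2 738 records come in
inverse-closed pairs: for every row the mirrored row with the inverted code
and the same degree exists.

The analysis layer defines disease cases from claims (e.g. hypertension =
code in I10–I15 *plus* prescribed medication; cancer = admission with a
C00–C97 *primary* diagnosis) and compares age-standardized prevalence
between people with and without a recorded parental disease history.  On a
~50 000-person simulation with parental relative risk 2.0, the pipeline
recovers a history/no-history standardized prevalence ratio of 2.02 (SE
0.06).

## Layout

| module | contents |
|--------|----------|
| `famtree.familycode` | code atoms, parsing, inversion, composition, reduction, degree, classification |
| `famtree.pedigree` | typed pedigree graph, sibling derivation, brute-force kinship oracle |
| `famtree.household_linkage` | roster snapshots → pedigree edges, two-source merge, co-membership history |
| `famtree.expansion` | kin enumeration to degree 4, canonical paths, record emission |
| `famtree.simulate` | synthetic population, rosters with missingness, familially aggregated claims |
| `famtree.famhist` | case definitions, history strata, direct age standardization, cohort reports |
| `famtree.cli` | `famtree` command-line interface |

See `docs/methods.md` for the model, its assumptions, and the design
decisions.
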