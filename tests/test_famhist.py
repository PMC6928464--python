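"""Case definitions, history strata, standardization, cohort reports."""

import numpy as np
import pandas as pd
import pytest

from famtree.expansion import expand_all, records_to_frame
from famtree.famhist import (
    StandardPopulation,
    age_standardized_prevalence,
    apply_case_definitions,
    family_history_flag,
    has_kin,
    kin_count_table,
    matching_rate_table,
)
from famtree.pedigree import Person


def claims_frame(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "year", "icd10", "admission",
                       "medication", "primary_dx"])


class TestCaseDefinitions:
    @pytest.mark.parametrize("row, disease, is_case", [
        (("p", 2010, "I21", 1, 0, 0), "ischemic_heart_disease", True),
        (("p", 2010, "I10", 0, 0, 0), "hypertension", False),  # no medication
        (("p", 2010, "I10", 0, 1, 0), "hypertension", True),
        (("p", 2010, "C50", 1, 0, 0), "cancer", False),  # secondary diagnosis
        (("p", 2010, "C50", 1, 0, 1), "cancer", True),
        (("p", 2010, "E11", 0, 1, 0), "diabetes", True),
        (("p", 2010, "I63", 1, 0, 0), "cerebrovascular_disease", True),
        (("p", 2010, "I63", 0, 0, 0), "cerebrovascular_disease", False),
        (("p", 2020, "I21", 1, 0, 0), "ischemic_heart_disease", False),  # late
    ])
    def test_single_row_decisions(self, row, disease, is_case):
        flags, _ = apply_case_definitions(claims_frame([row]),
                                          reference_year=2017)
        assert bool(flags.loc["p", disease]) is is_case

    def test_unparseable_codes_skipped_and_counted(self):
        flags, skipped = apply_case_definitions(claims_frame([
            ("p", 2010, "??", 1, 1, 1),
            ("p", 2010, "I21", 1, 0, 0),
        ]))
        assert skipped == 1
        assert bool(flags.loc["p", "ischemic_heart_disease"])


@pytest.fixture
def family_records(nuclear_family):
    return records_to_frame(expand_all(nuclear_family))


class TestFamilyHistory:
    def affected(self, *ids):
        idx = ["dad", "mum", "son", "daughter"]
        return pd.DataFrame({"d": [i in ids for i in idx]}, index=idx)

    def test_mother_affected_is_mother_side_history(self, family_records):
        hist = family_history_flag(family_records, self.affected("mum"), "d",
                                   "mother_side")
        assert bool(hist["son"]) and bool(hist["daughter"])
        assert not bool(hist["dad"])

    def test_no_qualifying_kin_is_no_history(self, family_records):
        # the affected person is the son; nobody has an affected parent
        hist = family_history_flag(family_records, self.affected("son"), "d",
                                   "parents")
        assert not hist.any()

    def test_both_parents_affected_count_on_both_sides(self, family_records):
        aff = self.affected("dad", "mum")
        father_side = family_history_flag(family_records, aff, "d",
                                          "father_side")
        mother_side = family_history_flag(family_records, aff, "d",
                                          "mother_side")
        assert bool(father_side["son"]) and bool(mother_side["son"])

    def test_has_kin_separates_unknown_from_negative(self, family_records):
        known = has_kin(family_records, "parents")
        assert bool(known["son"]) and not bool(known["dad"])


class TestStandardization:
    def persons_two_bands(self):
        # 10 people aged 42, 10 aged 67 in 2017
        return ([Person(f"a{i}", "M", 1975) for i in range(10)]
                + [Person(f"b{i}", "W", 1950) for i in range(10)])

    def test_two_group_worked_example(self):
        persons = self.persons_two_bands()
        # prevalence 0.1 in the young band, 0.3 in the old, weights 1/2 each
        aff = pd.Series(
            {p.person_id: (i == 0 if p.birth_year == 1975 else i < 3)
             for i, p in enumerate(persons)})
        aff = pd.Series([False] * 20, index=[p.person_id for p in persons])
        aff[["a0", "b0", "b1", "b2"]] = True
        std = StandardPopulation(((40, 0.5), (65, 0.5)))
        table = age_standardized_prevalence(
            aff, persons, {"all": pd.Series(True, index=aff.index)}, std)
        assert table.loc["all", "prevalence"] == pytest.approx(0.2, abs=1e-12)

    def test_uniform_weights_on_equal_bands_reproduce_crude(self):
        persons = self.persons_two_bands()
        aff = pd.Series([False] * 20, index=[p.person_id for p in persons])
        aff[["a0", "a3", "b0", "b1", "b2"]] = True
        std = StandardPopulation.uniform([40, 65])
        table = age_standardized_prevalence(
            aff, persons, {"all": pd.Series(True, index=aff.index)}, std)
        crude = aff.mean()
        assert abs(table.loc["all", "prevalence"] - crude) < 1e-12

    def test_self_standard_reproduces_crude(self):
        rng = np.random.default_rng(0)
        persons = [Person(f"p{i}", "M", int(rng.integers(1930, 2010)))
                   for i in range(200)]
        aff = pd.Series(rng.random(200) < 0.2,
                        index=[p.person_id for p in persons])
        std = StandardPopulation.from_persons(persons, 2017)
        table = age_standardized_prevalence(
            aff, persons, {"all": pd.Series(True, index=aff.index)}, std)
        assert abs(table.loc["all", "prevalence"] - aff.mean()) < 1e-12

    def test_zero_weight_band_contributes_nothing(self):
        persons = self.persons_two_bands()
        aff = pd.Series([False] * 20, index=[p.person_id for p in persons])
        aff[["b0", "b1", "b2"]] = True  # all cases in the old band
        std = StandardPopulation(((40, 1.0), (65, 0.0)))
        table = age_standardized_prevalence(
            aff, persons, {"all": pd.Series(True, index=aff.index)}, std)
        assert table.loc["all", "prevalence"] == 0.0

    def test_empty_stratum_reported_missing(self):
        persons = self.persons_two_bands()
        aff = pd.Series([False] * 20, index=[p.person_id for p in persons])
        std = StandardPopulation.uniform([40, 65])
        table = age_standardized_prevalence(
            aff, persons, {"none": pd.Series(False, index=aff.index)}, std)
        assert np.isnan(table.loc["none", "prevalence"])

    def test_weights_must_normalize(self):
        with pytest.raises(ValueError):
            StandardPopulation(((40, 0.6), (65, 0.6)))


class TestReports:
    def test_matching_rates_full_observation(self, nuclear_family):
        from famtree.household_linkage import MembershipSnapshot
        rows = []
        for source, unit in (("register", "H1"), ("eligibility", "E1")):
            for pid, rel in [("dad", "0IM"), ("mum", "0IM0OW"),
                             ("son", "0IM1DM"), ("daughter", "0IM1DW")]:
                rows.append(MembershipSnapshot(unit, pid, rel, 2005, source))
        records = records_to_frame(expand_all(nuclear_family, rows))
        persons = list(nuclear_family.persons.values())
        table = matching_rate_table(records, persons)
        kids = table.loc[("M", "1990s")]
        assert kids["father"] == 100.0
        assert kids["any_parent_or_grandparent"] == 100.0

    def test_grandparent_only_counts_in_grand_column(self, chain6):
        from famtree.household_linkage import MembershipSnapshot
        # g4 co-resides with grandparent g2 but never with parent g3
        rows = [MembershipSnapshot("H1", "g2", "0IW", 2005, "register"),
                MembershipSnapshot("H1", "g4", "0IW1DW", 2005, "register")]
        records = records_to_frame(expand_all(chain6, rows))
        persons = [chain6.persons["g4"]]
        table = matching_rate_table(records, persons)
        row = table.iloc[0]
        assert row["any_parent"] == 0.0
        assert row["any_parent_or_grandparent"] == 100.0

    def test_kin_counts_partition_identity(self):
        cfg_records = self._simulated_records()
        table = kin_count_table(cfg_records)
        degree_sum = table[[f"degree_{d}" for d in (1, 2, 3, 4)]].sum(axis=1)
        assert (degree_sum == table["consanguinity"] + table["affinity"]).all()

    def test_nuclear_family_counts(self, family_records):
        table = kin_count_table(family_records)
        boys = table.loc[("M", "1990s")]
        assert boys["degree_1"] == 2  # two parents
        assert boys["degree_2"] == 1  # one sibling
        assert boys["consanguinity"] == 3

    def test_empty_records_all_zero(self):
        table = kin_count_table(records_to_frame([]))
        assert len(table) == 0

    @staticmethod
    def _simulated_records():
        from famtree.simulate import SimulationConfig, simulate_population
        pop = simulate_population(SimulationConfig(seed=21,
                                                   n_founder_couples=4))
        return records_to_frame(expand_all(pop.graph))
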