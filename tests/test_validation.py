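"""Validity rules V1–V10 and the clean() repair operation."""

import random

import pandas as pd
import pytest

from taxatables import RULE_CODES, TaxonList, clean, validate
from taxatables.testing import inject_defect
from tests.conftest import make_fixture


def codes(violations):
    return [v.rule_code for v in violations]


class TestValidate:
    def test_mini_is_valid(self, mini):
        assert validate(mini) == []

    @pytest.mark.parametrize("rule", RULE_CODES)
    def test_each_injected_defect_flags_exactly_its_rule(self, rule, rng):
        broken = inject_defect(make_fixture(11), rule, rng)
        assert set(codes(validate(broken))) == {rule}

    def test_duplicate_combination_lists_both_usage_ids(self, mini):
        broken = mini.copy()
        broken.names = pd.concat(
            [
                broken.names,
                pd.DataFrame(
                    [{"usage_id": 300, "concept_id": 2, "full_name": "Cyperus papyrus", "author": "L."}]
                ).astype(broken.names.dtypes.to_dict()),
            ],
            ignore_index=True,
        )
        (violation,) = validate(broken)
        assert violation.rule_code == "V3_DUP_COMBINATION"
        assert violation.offending_ids == (206, 300)

    def test_species_parented_by_equal_rank_violates_rank_order(self, mini):
        broken = mini.copy()
        # make the genus a species: the papyrus -> genus pair is now same-rank
        broken.concepts.loc[broken.concepts["concept_id"] == 2, "rank"] = "species"
        result = validate(broken)
        assert codes(result) == ["V9_RANK_ORDER"]
        assert result[0].offending_ids == (206, 2)

    def test_validate_is_pure_and_deterministically_ordered(self, rng):
        broken = make_fixture(13)
        for rule in ("V4_ORPHANED_NAME", "V7_MISSING_PARENT", "V10_DANGLING_VIEW"):
            broken = inject_defect(broken, rule, rng)
        first, second = validate(broken), validate(broken)
        assert first == second
        order = [RULE_CODES.index(c) for c in codes(first)]
        assert order == sorted(order)

    def test_broken_input_reports_instead_of_raising(self):
        chaos = TaxonList(
            names=pd.DataFrame([{"usage_id": 1, "concept_id": 99, "full_name": "X y", "author": ""}]),
            ranks=[],
        )
        assert {"V4_ORPHANED_NAME"} == set(codes(validate(chaos)))


ORPHAN_RULES = ("V4_ORPHANED_NAME", "V5_ORPHANED_TRAIT", "V6_MISSING_ACCEPTED", "V7_MISSING_PARENT", "V10_DANGLING_VIEW")


class TestClean:
    def test_clean_of_valid_list_is_identity(self, mini, random_list):
        assert clean(mini).equals(mini)
        assert clean(random_list).equals(random_list)

    def test_deleting_a_middle_concept_nulls_child_parent(self, mini):
        broken = mini.copy()
        broken.concepts = broken.concepts[broken.concepts["concept_id"] != 2].reset_index(drop=True)
        repaired = clean(broken)
        assert validate(repaired) == []
        assert sorted(repaired.concept_ids()) == [1, 206]
        # the species lost its parent pointer; the orphaned genus name is gone
        row = repaired.concept_row(206)
        assert pd.isna(row["parent_id"])
        assert 2 not in set(repaired.names["usage_id"].astype(int))

    def test_orphaned_trait_record_removed_concepts_untouched(self, mini):
        broken = mini.copy()
        broken.traits = pd.DataFrame([{"concept_id": 5000, "life_form": "herb"}])
        repaired = clean(broken)
        assert len(repaired.traits) == 0
        assert repaired.concepts.equals(mini.concepts)

    def test_broken_accepted_pointer_repaired_to_lowest_usage_id(self, mini):
        broken = mini.copy()
        broken.concepts.loc[broken.concepts["concept_id"] == 206, "accepted_name_id"] = 9999
        repaired = clean(broken)
        assert validate(repaired) == []
        assert int(repaired.concept_row(206)["accepted_name_id"]) == 206

    @pytest.mark.parametrize("rule", ORPHAN_RULES)
    def test_clean_recovers_every_orphan_class(self, rule, rng):
        broken = inject_defect(make_fixture(17), rule, rng)
        repaired = clean(broken)
        assert not set(codes(validate(repaired))) & set(ORPHAN_RULES)

    def test_clean_is_idempotent_on_broken_input(self, rng):
        broken = inject_defect(make_fixture(19), "V4_ORPHANED_NAME", rng)
        once = clean(broken)
        assert clean(once).equals(once)

    def test_clean_does_not_touch_duplicate_combinations(self, rng):
        broken = inject_defect(make_fixture(23), "V3_DUP_COMBINATION", rng)
        repaired = clean(broken)
        assert "V3_DUP_COMBINATION" in codes(validate(repaired))
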