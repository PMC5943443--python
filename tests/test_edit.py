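"""Editing operations: every accepted edit keeps the list valid."""

import pytest

from taxatables import (
    EditError,
    accepted_name,
    add_concept,
    add_level,
    add_parent,
    add_synonym,
    add_view,
    change_concept,
    get_parents,
    set_accepted_name,
    set_traits,
    set_view,
    summarize_concept,
    summary_list,
    synonyms,
    validate,
)


class TestAddConcept:
    def test_new_species_under_genus(self, mini):
        out, (cid,) = add_concept(mini, [("Cyperus dives", "Delile")], rank="species", parent_id=2)
        assert validate(out) == []
        assert summary_list(out).n_concepts == summary_list(mini).n_concepts + 1
        assert summary_list(out).n_names == summary_list(mini).n_names + 1
        assert accepted_name(out, cid) == ("Cyperus dives", "Delile")
        assert get_parents(out, cid) == [2, 1]

    def test_existing_combination_rejected_naming_the_clash(self, mini):
        with pytest.raises(EditError, match="usage_id 206"):
            add_concept(mini, [("Cyperus papyrus", "L.")])

    def test_equal_rank_parent_rejected(self, mini):
        with pytest.raises(EditError, match="not strictly below"):
            add_concept(mini, [("Cyperus dives", "Delile")], rank="species", parent_id=206)

    def test_unknown_rank_parent_view_rejected(self, mini):
        with pytest.raises(EditError, match="ladder"):
            add_concept(mini, [("Aa bb", "")], rank="order")
        with pytest.raises(EditError, match="parent"):
            add_concept(mini, [("Aa bb", "")], parent_id=777)
        with pytest.raises(EditError, match="view"):
            add_concept(mini, [("Aa bb", "")], view_id=777)

    def test_rejected_edit_leaves_input_unchanged(self, mini):
        snapshot = mini.copy()
        with pytest.raises(EditError):
            add_concept(mini, [("Cyperus papyrus", "L.")])
        assert mini.equals(snapshot)


class TestAddSynonym:
    def test_synonym_count_grows_accepted_untouched(self, mini):
        out = add_synonym(mini, 206, "Cyperus antiquorum", "Roxb.")
        assert validate(out) == []
        assert len(synonyms(out, 206)) == len(synonyms(mini, 206)) + 1
        assert accepted_name(out, 206) == accepted_name(mini, 206)

    def test_same_synonym_twice_errors(self, mini):
        once = add_synonym(mini, 206, "Cyperus antiquorum", "Roxb.")
        with pytest.raises(EditError, match="already exists"):
            add_synonym(once, 206, "Cyperus antiquorum", "Roxb.")

    def test_unknown_concept_errors(self, mini):
        with pytest.raises(EditError, match="does not exist"):
            add_synonym(mini, 4040, "Aa bb", "")


class TestSetAcceptedName:
    def test_double_swap_restores_original(self, mini):
        swapped = set_accepted_name(mini, 206, 207)
        assert accepted_name(swapped, 206) == ("Papyrus antiquorum", "Willd.")
        assert validate(swapped) == []
        back = set_accepted_name(swapped, 206, 206)
        assert back.equals(mini)

    def test_former_accepted_name_listed_as_synonym(self, mini):
        swapped = set_accepted_name(mini, 206, 207)
        assert ("Cyperus papyrus", "L.") in summarize_concept(swapped, 206).synonyms

    def test_name_of_other_concept_rejected(self, mini):
        with pytest.raises(EditError, match="change_concept"):
            set_accepted_name(mini, 206, 2)

    def test_promoting_current_accepted_name_is_an_error(self, mini):
        with pytest.raises(EditError, match="already the accepted name"):
            set_accepted_name(mini, 206, 206)

    def test_name_count_is_conserved(self, mini):
        swapped = set_accepted_name(mini, 206, 207)
        assert summary_list(swapped).n_names == summary_list(mini).n_names


class TestChangeConcept:
    def test_synonym_moves_and_totals_are_conserved(self, mini):
        moved = change_concept(mini, 207, 2)
        assert validate(moved) == []
        assert len(synonyms(moved, 206)) == 0
        assert ("Papyrus antiquorum", "Willd.") in synonyms(moved, 2)
        assert summary_list(moved).n_names == summary_list(mini).n_names

    def test_moved_name_identity_preserved(self, mini):
        moved = change_concept(mini, 207, 2)
        row = moved.names[moved.names["usage_id"] == 207].iloc[0]
        assert (row["full_name"], row["author"]) == ("Papyrus antiquorum", "Willd.")

    def test_accepted_name_cannot_move(self, mini):
        with pytest.raises(EditError, match="accepted name"):
            change_concept(mini, 206, 2)

    def test_unknown_target_rejected(self, mini):
        with pytest.raises(EditError, match="does not exist"):
            change_concept(mini, 207, 4242)


class TestAddParent:
    def test_species_attached_to_genus_has_full_lineage(self, mini):
        out, (cid,) = add_concept(mini, [("Cyperus dives", "Delile")], rank="species")
        attached = add_parent(out, [cid], 2)
        assert get_parents(attached, cid) == [2, 1]
        assert validate(attached) == []

    def test_self_parent_is_a_cycle(self, mini):
        with pytest.raises(EditError, match="cycle"):
            add_parent(mini, [2], 2)

    def test_ancestor_as_child_is_a_cycle(self, mini):
        with pytest.raises(EditError, match="cycle"):
            add_parent(mini, [1], 206)

    def test_genus_under_species_breaks_rank_order(self, mini):
        out, (cid,) = add_concept(mini, [("Cyperus dives", "Delile")], rank="species")
        with pytest.raises(EditError, match="not strictly below"):
            add_parent(out, [2], cid)


class TestAddLevel:
    def test_insert_lowest_rank_shifts_ladder(self, mini):
        out = add_level(mini, "subspecies", 0)
        assert out.ranks == ["subspecies", "species", "genus", "family"]
        assert validate(out) == []

    def test_insert_between_ranks_keeps_validity(self, mini):
        out = add_level(mini, "section", 1)
        assert validate(mini) == [] and validate(out) == []

    def test_duplicate_label_rejected(self, mini):
        with pytest.raises(EditError, match="already on the ladder"):
            add_level(mini, "genus", 0)

    def test_out_of_range_position_rejected(self, mini):
        with pytest.raises(EditError, match="outside"):
            add_level(mini, "order", 9)


class TestTraitsAndViews:
    def test_set_traits_reflected_in_trait_table(self, mini):
        out = set_traits(mini, 206, {"life_form": "reed_plant"})
        assert validate(out) == []
        row = out.traits[out.traits["concept_id"] == 206].iloc[0]
        assert row["life_form"] == "reed_plant"

    def test_set_traits_upserts_not_duplicates(self, mini):
        out = set_traits(set_traits(mini, 206, {"life_form": "reed_plant"}), 206, {"life_form": "helophyte"})
        assert len(out.traits) == 1
        assert out.traits.iloc[0]["life_form"] == "helophyte"

    def test_set_traits_unknown_concept_errors(self, mini):
        with pytest.raises(EditError, match="does not exist"):
            set_traits(mini, 4040, {"life_form": "herb"})

    def test_new_view_assigned_to_all_concepts_validates(self, mini):
        out, vid = add_view(mini, author="Fresh Committee", year=2020, title="A newer circumscription")
        out = set_view(out, sorted(out.concept_ids()), vid)
        assert validate(out) == []
        assert set(out.concepts["view_id"].astype(int)) == {vid}

    def test_set_view_unknown_view_errors(self, mini):
        with pytest.raises(EditError, match="view"):
            set_view(mini, [206], 999)
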