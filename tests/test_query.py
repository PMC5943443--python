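"""Subsetting, closure expansion and name retrieval."""

import networkx as nx
import pytest

from taxatables import (
    LookupMissError,
    QueryError,
    SubsetQuery,
    accepted_name,
    expand_concepts,
    get_children,
    get_parents,
    seed_concepts,
    subset,
    summary_list,
    synonyms,
    validate,
)

PAPYRUS_QUERY = SubsetQuery("names", "full_name", "contains", "papyrus")


def parent_graph(checklist):
    graph = nx.DiGraph()
    graph.add_nodes_from(checklist.concept_ids())
    for _, row in checklist.concepts.iterrows():
        if row["parent_id"] is not None and not row.isna()["parent_id"]:
            graph.add_edge(int(row["parent_id"]), int(row["concept_id"]))
    return graph


class TestSubset:
    def test_papyrus_with_parents_retrieves_full_lineage(self, mini):
        out = subset(mini, PAPYRUS_QUERY, keep_parents=True)
        assert sorted(out.concept_ids()) == [1, 2, 206]
        assert validate(out) == []

    def test_papyrus_without_parents_is_the_seed_only(self, mini):
        out = subset(mini, PAPYRUS_QUERY)
        assert sorted(out.concept_ids()) == [206]
        assert validate(out) == []
        # synonym travels with its concept
        assert summary_list(out).n_names == 2

    def test_family_with_children_retrieves_everything(self, mini):
        out = subset(mini, SubsetQuery("names", "full_name", "contains", "cyperaceae"), keep_children=True)
        assert sorted(out.concept_ids()) == [1, 2, 206]

    def test_no_match_yields_empty_valid_list(self, mini):
        out = subset(mini, SubsetQuery("names", "full_name", "contains", "nothing-here"))
        assert summary_list(out).n_concepts == 0
        assert validate(out) == []
        assert out.ranks == mini.ranks

    def test_trait_query_selects_concepts(self, random_list):
        out = subset(random_list, SubsetQuery("traits", "life_form", "equals", "herb"))
        selected = seed_concepts(random_list, SubsetQuery("traits", "life_form", "equals", "herb"))
        assert out.concept_ids() == selected

    def test_unknown_column_and_table_raise(self, mini):
        with pytest.raises(QueryError, match="column"):
            subset(mini, SubsetQuery("names", "no_such_column", "equals", 1))
        with pytest.raises(QueryError, match="table"):
            SubsetQuery("views", "author", "equals", "x")
        with pytest.raises(QueryError, match="operator"):
            SubsetQuery("names", "full_name", "matches", "x")

    def test_monotonicity_of_flag_combinations(self, random_list):
        query = SubsetQuery("names", "full_name", "contains", "a")
        seed = seed_concepts(random_list, query)
        plain = subset(random_list, query).concept_ids()
        children = subset(random_list, query, keep_children=True).concept_ids()
        both = subset(random_list, query, keep_children=True, keep_parents=True).concept_ids()
        assert seed <= plain <= children <= both

    def test_idempotence_under_name_containment_query(self, random_list):
        once = subset(random_list, SubsetQuery("names", "full_name", "contains", "us"), keep_parents=True)
        twice = subset(once, SubsetQuery("names", "full_name", "contains", "us"), keep_parents=True)
        assert twice.equals(once)

    def test_expansion_matches_graph_reachability(self, random_list):
        graph = parent_graph(random_list)
        query = SubsetQuery("names", "full_name", "contains", "e")
        seed = seed_concepts(random_list, query)
        down = expand_concepts(random_list, seed, keep_children=True)
        expected_down = set(seed)
        for cid in seed:
            expected_down |= nx.descendants(graph, cid)
        assert down == expected_down
        up = expand_concepts(random_list, seed, keep_parents=True)
        expected_up = set(seed)
        for cid in seed:
            expected_up |= nx.ancestors(graph, cid)
        assert up == expected_up


class TestTraversal:
    def test_parents_chain_nearest_first(self, mini):
        assert get_parents(mini, 206) == [2, 1]

    def test_root_has_no_parents(self, mini):
        assert get_parents(mini, 1) == []

    def test_children_direct_and_recursive(self, mini):
        assert get_children(mini, 1) == [2]
        assert get_children(mini, 1, recursive=True) == [2, 206]

    def test_unknown_id_raises(self, mini):
        with pytest.raises(LookupMissError):
            get_parents(mini, 777)
        with pytest.raises(LookupMissError):
            get_children(mini, 777)


class TestNames:
    def test_accepted_name_of_papyrus(self, mini):
        assert accepted_name(mini, 206) == ("Cyperus papyrus", "L.")

    def test_single_name_concept_has_no_synonyms(self, mini):
        assert synonyms(mini, 1) == []

    def test_synonym_count_plus_one_equals_name_rows(self, random_list):
        for cid in sorted(random_list.concept_ids()):
            n_rows = len(random_list.names_of(cid))
            assert len(synonyms(random_list, cid)) + 1 == n_rows
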