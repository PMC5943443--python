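"""The synthetic checklist generator and the Turboveg fixture writer."""

import pandas as pd
import pytest
from scipy import stats as sps

from taxatables import (
    FixtureSpec,
    TaxaTablesError,
    accepted_name,
    easplist_mini,
    generate_fixture,
    get_parents,
    read_turboveg,
    validate,
    write_archive,
    write_turboveg_fixture,
)


def name_partition(checklist):
    """Concept structure as a set of frozensets of (name, author) pairs."""
    return {
        frozenset((str(r["full_name"]), str(r["author"])) for _, r in checklist.names_of(cid).iterrows())
        for cid in checklist.concept_ids()
    }


def flatten(checklist):
    """Strip hierarchy, ranks and views: the shape Turboveg can represent."""
    flat = checklist.copy()
    flat.concepts["parent_id"] = pd.NA
    flat.concepts["rank"] = ""
    flat.concepts["view_id"] = pd.NA
    flat.views = flat.views.iloc[0:0]
    flat.ranks = []
    return flat


class TestEasplistMini:
    def test_shape_and_validity(self, mini):
        assert validate(mini) == []
        assert len(mini.concepts) == 3 and len(mini.names) == 4 and len(mini.views) == 1
        assert mini.ranks == ["species", "genus", "family"]

    def test_papyrus_anchors(self, mini):
        assert accepted_name(mini, 206) == ("Cyperus papyrus", "L.")
        assert len(get_parents(mini, 206)) == 2


class TestGenerator:
    def test_same_seed_same_list(self):
        spec = FixtureSpec(n_families=2, n_genera=4, n_species=20, synonym_rate=0.3, seed=42)
        assert generate_fixture(spec).equals(generate_fixture(spec))

    def test_same_seed_byte_identical_archives(self, tmp_path):
        spec = FixtureSpec(seed=99)
        a = write_archive(generate_fixture(spec), tmp_path / "a.zip")
        b = write_archive(generate_fixture(spec), tmp_path / "b.zip")
        assert a.read_bytes() == b.read_bytes()

    @pytest.mark.parametrize("seed", range(10))
    def test_every_generated_list_is_valid(self, seed):
        checklist = generate_fixture(FixtureSpec(seed=seed))
        assert validate(checklist) == []

    def test_structure_matches_spec(self):
        checklist = generate_fixture(FixtureSpec(n_families=3, n_genera=5, n_species=12, seed=1))
        ranks = checklist.concepts["rank"].value_counts()
        assert ranks["family"] == 3 and ranks["genus"] == 5 and ranks["species"] == 12
        assert list(checklist.traits.columns) == ["concept_id", "life_form"]

    def test_synonym_count_within_binomial_99pct_band(self):
        """Over 200 seeds the synonym total behaves like Binomial(n, rate)."""
        n_species, rate, seeds = 20, 0.3, 200
        total = 0
        for seed in range(seeds):
            checklist = generate_fixture(FixtureSpec(n_species=n_species, synonym_rate=rate, seed=seed))
            total += len(checklist.names) - len(checklist.concepts)
        n = n_species * seeds
        low, high = sps.binom.ppf([0.005, 0.995], n, rate)
        assert low <= total <= high

    def test_infeasible_spec_rejected(self):
        with pytest.raises(TaxaTablesError):
            generate_fixture(FixtureSpec(n_families=0))
        with pytest.raises(TaxaTablesError, match="unique|infeasible"):
            generate_fixture(FixtureSpec(n_families=100000))


class TestTurbovegFixtureWriter:
    def test_partition_recovery_on_flat_list(self, tmp_path):
        flat = flatten(generate_fixture(FixtureSpec(n_species=10, seed=21)))
        species, eco = write_turboveg_fixture(flat, tmp_path)
        recovered = read_turboveg(species, attribute_table=eco)
        assert name_partition(recovered) == name_partition(flat)

    def test_hierarchy_dropped_with_warning(self, tmp_path, caplog):
        checklist = generate_fixture(FixtureSpec(seed=8))
        with caplog.at_level("WARNING", logger="taxatables"):
            species, eco = write_turboveg_fixture(checklist, tmp_path)
        assert any("hierarchy" in rec.message for rec in caplog.records)
        recovered = read_turboveg(species, attribute_table=eco)
        assert name_partition(recovered) == name_partition(checklist)
        assert not recovered.concepts["parent_id"].notna().any()
        assert len(recovered.views) == 0

    def test_empty_list_round_trips(self, tmp_path):
        from taxatables import new_checklist

        species, eco = write_turboveg_fixture(new_checklist(), tmp_path)
        recovered = read_turboveg(species, attribute_table=eco)
        assert len(recovered.concepts) == 0 and len(recovered.names) == 0
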