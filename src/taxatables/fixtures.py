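"""Synthetic checklists for testing and demonstration.

Two sources of data, neither requiring any download:

* :func:`easplist_mini` — a hand-coded miniature of an East-African sedge
  checklist: family Cyperaceae → genus *Cyperus* → species *Cyperus papyrus*
  L. (concept id 206) with one synonym, one taxon view and a three-step rank
  ladder.  The surrounding ids are arbitrary; 206 is fixed because worked
  examples throughout the docs refer to it.
* :func:`generate_fixture` — a seed-deterministic random checklist whose
  names are built from syllable tables (pronounceable, guaranteed unique,
  and obviously not authoritative taxonomy).

:func:`write_turboveg_fixture` serializes a checklist in the Turboveg DBF
dialect so the importer can be tested against files this package itself did
not read.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dbf as _dbf
from .model import TaxaTablesError, TaxonList

logger = logging.getLogger("taxatables")

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z", "br", "cr", "pl", "st", "tr", "ch"]
_VOWELS = ["a", "e", "i", "o", "u"]
_GENUS_SUFFIX = ["us", "a", "um", "is", "ia"]
_EPITHET_SUFFIX = ["ensis", "osa", "atus", "iana", "ifolia", "oides"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a generated checklist.

    Defaults give a small but structurally complete list: two families, four
    genera, twenty species, roughly one synonym per three species, one trait
    variable with three states, and a single taxon view.
    """

    n_families: int = 2
    n_genera: int = 4
    n_species: int = 20
    synonym_rate: float = 0.3
    trait_schema: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"life_form": ("herb", "graminoid", "tree")}
    )
    view_count: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_families, self.n_genera, self.n_species) < 1:
            raise TaxaTablesError("n_families, n_genera and n_species must all be >= 1")
        if not 0.0 <= self.synonym_rate <= 1.0:
            raise TaxaTablesError("synonym_rate must lie in [0, 1]")
        if self.view_count < 0:
            raise TaxaTablesError("view_count must be >= 0")


def _syllables(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_ONSETS) + rng.choice(_VOWELS) for _ in range(n))


def _fresh(rng: random.Random, make, taken: set[str], what: str, attempts: int = 2000) -> str:
    for _ in range(attempts):
        candidate = make()
        if candidate not in taken:
            taken.add(candidate)
            return candidate
    raise TaxaTablesError(f"could not generate enough unique {what}; requested counts are infeasible")


def easplist_mini() -> TaxonList:
    """The miniature sedge checklist used by the worked examples (synthetic).

    Contains exactly three concepts (family, genus, species), four usage
    names, one view and the ladder ``["species", "genus", "family"]``.  The
    papyrus concept carries id 206 and the synonym *Papyrus antiquorum*
    Willd.; no trait records are present until a caller inserts one.
    """
    names = pd.DataFrame(
        [
            {"usage_id": 1, "concept_id": 1, "full_name": "Cyperaceae", "author": "Juss."},
            {"usage_id": 2, "concept_id": 2, "full_name": "Cyperus", "author": "L."},
            {"usage_id": 206, "concept_id": 206, "full_name": "Cyperus papyrus", "author": "L."},
            {"usage_id": 207, "concept_id": 206, "full_name": "Papyrus antiquorum", "author": "Willd."},
        ]
    )
    concepts = pd.DataFrame(
        [
            {"concept_id": 1, "accepted_name_id": 1, "parent_id": pd.NA, "rank": "family", "view_id": 1},
            {"concept_id": 2, "accepted_name_id": 2, "parent_id": 1, "rank": "genus", "view_id": 1},
            {"concept_id": 206, "accepted_name_id": 206, "parent_id": 2, "rank": "species", "view_id": 1},
        ]
    )
    views = pd.DataFrame(
        [
            {
                "view_id": 1,
                "author": "Editorial Committee",
                "year": 2010,
                "title": "Checklist of eastern African sedges (synthetic reference)",
            }
        ]
    )
    return TaxonList(names=names, concepts=concepts, views=views, ranks=["species", "genus", "family"])


def generate_fixture(spec: FixtureSpec | None = None) -> TaxonList:
    """Generate a valid, seed-deterministic random checklist.

    Species hang under genera, genera under families; synonyms are drawn per
    accepted species with probability ``synonym_rate``; trait values are
    sampled uniformly from ``trait_schema``; every concept gets one of the
    ``view_count`` views (when any exist).  The same spec (including seed)
    always yields an identical list.
    """
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    taken_names: set[str] = set()
    taken_authors: set[str] = set()

    def author() -> str:
        return _syllables(rng, 1).capitalize() + _syllables(rng, rng.randint(0, 1)) + "."

    names_rows, concept_rows, view_rows, trait_rows = [], [], [], []
    next_concept, next_usage = 1, 1

    view_ids = []
    for i in range(spec.view_count):
        view_rows.append(
            {
                "view_id": i + 1,
                "author": _fresh(rng, author, taken_authors, "view authors"),
                "year": 1980 + rng.randint(0, 40),
                "title": f"Synthetic checklist reference no. {i + 1}",
            }
        )
        view_ids.append(i + 1)

    def pick_view():
        return rng.choice(view_ids) if view_ids else pd.NA

    def new_concept(name: str, auth: str, rank: str, parent: int | None) -> int:
        nonlocal next_concept, next_usage
        cid, uid = next_concept, next_usage
        next_concept, next_usage = cid + 1, uid + 1
        names_rows.append({"usage_id": uid, "concept_id": cid, "full_name": name, "author": auth})
        concept_rows.append(
            {
                "concept_id": cid,
                "accepted_name_id": uid,
                "parent_id": pd.NA if parent is None else parent,
                "rank": rank,
                "view_id": pick_view(),
            }
        )
        return cid

    family_ids = [
        new_concept(
            _fresh(rng, lambda: _syllables(rng, 2).capitalize() + "aceae", taken_names, "family names"),
            author(),
            "family",
            None,
        )
        for _ in range(spec.n_families)
    ]

    genus_ids, genus_names = [], {}
    for _ in range(spec.n_genera):
        name = _fresh(
            rng,
            lambda: _syllables(rng, rng.randint(1, 2)).capitalize() + rng.choice(_GENUS_SUFFIX),
            taken_names,
            "genus names",
        )
        cid = new_concept(name, author(), "genus", rng.choice(family_ids))
        genus_ids.append(cid)
        genus_names[cid] = name

    def epithet() -> str:
        return _syllables(rng, rng.randint(1, 2)) + rng.choice(_EPITHET_SUFFIX)

    species_ids = []
    for _ in range(spec.n_species):
        genus = rng.choice(genus_ids)
        binomial = _fresh(rng, lambda: f"{genus_names[genus]} {epithet()}", taken_names, "species names")
        species_ids.append(new_concept(binomial, author(), "species", genus))

    for cid in species_ids:
        if rng.random() < spec.synonym_rate:
            genus = rng.choice(genus_ids)
            synonym = _fresh(rng, lambda: f"{genus_names[genus]} {epithet()}", taken_names, "synonym names")
            names_rows.append(
                {"usage_id": next_usage, "concept_id": cid, "full_name": synonym, "author": author()}
            )
            next_usage += 1

    for cid in species_ids:
        values = {var: rng.choice(list(states)) for var, states in spec.trait_schema.items()}
        if values:
            trait_rows.append({"concept_id": cid, **values})

    kwargs = {
        "names": pd.DataFrame(names_rows),
        "concepts": pd.DataFrame(concept_rows),
        "ranks": ["species", "genus", "family"],
    }
    if view_rows:
        kwargs["views"] = pd.DataFrame(view_rows)
    if trait_rows:
        kwargs["traits"] = pd.DataFrame(trait_rows)
    return TaxonList(**kwargs)


# ---------------------------------------------------------------------------
# Turboveg-dialect fixture writer
# ---------------------------------------------------------------------------

def write_turboveg_fixture(checklist: TaxonList, directory: str | Path, encoding: str = "latin-1") -> tuple[Path, Path]:
    """Write a checklist as a Turboveg species + attribute DBF pair.

    Turboveg's flat dialect cannot carry hierarchy or taxon views; when the
    input has either, a warning is logged and they are dropped.  Trait
    variables become attribute-table columns (names uppercased, at most 10
    characters).  Returns (species path, attribute path).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if checklist.concepts["parent_id"].notna().any() or len(checklist.views):
        logger.warning("Turboveg dialect cannot store hierarchy or taxon views; dropping them")

    accepted_of = dict(
        zip(
            checklist.concepts["concept_id"].dropna().astype(int),
            checklist.concepts["accepted_name_id"].astype(int),
        )
    )
    species_rows = []
    for _, row in checklist.names.iterrows():
        uid, cid = int(row["usage_id"]), int(row["concept_id"])
        species_rows.append(
            {
                "SPECIES_NR": uid,
                "ABBREVIAT": str(row["full_name"]),
                "AUTHOR": str(row["author"]),
                "SYNONYM": accepted_of.get(cid) != uid,
                "VALID_NR": accepted_of.get(cid, uid),
            }
        )
    species_df = pd.DataFrame(
        species_rows, columns=["SPECIES_NR", "ABBREVIAT", "AUTHOR", "SYNONYM", "VALID_NR"]
    )
    species_fields = [
        _dbf.DbfField("SPECIES_NR", "N", 8),
        _dbf.DbfField("ABBREVIAT", "C", 80),
        _dbf.DbfField("AUTHOR", "C", 50),
        _dbf.DbfField("SYNONYM", "L", 1),
        _dbf.DbfField("VALID_NR", "N", 8),
    ]
    species_path = _dbf.write_dbf(directory / "species.dbf", species_df, species_fields, encoding=encoding)

    trait_vars = [c for c in checklist.traits.columns if c != "concept_id"]
    eco_fields = [_dbf.DbfField("SPECIES_NR", "N", 8)]
    seen_cols = {"SPECIES_NR"}
    col_map = {}
    for var in trait_vars:
        dbf_name = var.upper()[:10]
        if dbf_name in seen_cols:
            raise TaxaTablesError(f"trait variable '{var}' collides with another column after DBF renaming")
        seen_cols.add(dbf_name)
        col_map[var] = dbf_name
        eco_fields.append(_dbf.DbfField(dbf_name, "C", 40))
    eco_rows = []
    for _, row in checklist.traits.iterrows():
        cid = int(row["concept_id"])
        if cid not in accepted_of:
            continue
        record = {"SPECIES_NR": accepted_of[cid]}
        for var in trait_vars:
            value = row[var]
            record[col_map[var]] = "" if pd.isna(value) else str(value)
        eco_rows.append(record)
    eco_df = pd.DataFrame(eco_rows, columns=["SPECIES_NR"] + [col_map[v] for v in trait_vars])
    eco_path = _dbf.write_dbf(directory / "ecodbase.dbf", eco_df, eco_fields, encoding=encoding)
    return species_path, eco_path


__all__ = ["FixtureSpec", "easplist_mini", "generate_fixture", "write_turboveg_fixture"]
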