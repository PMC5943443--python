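"""Core data model: a taxonomic checklist as four linked tables.

A :class:`TaxonList` separates *taxon usage names* (every application of a
name, accepted or synonym) from *taxon concepts* (the circumscribed taxa the
names point to).  Concepts may reference a *taxon view* — the bibliographic
source fixing their circumscription — and may carry per-concept *trait*
records.  An optional parent pointer plus a user-defined rank ladder give the
list a taxonomic hierarchy.

Table layout
------------
``names``     usage_id, concept_id, full_name, author (+ free extra columns)
``concepts``  concept_id, accepted_name_id, parent_id, rank, view_id (+ extras)
``views``     view_id, author, year, title (+ extras)
``traits``    concept_id, one column per trait variable

Conventions: id columns are nullable pandas ``Int64``; text columns are plain
object columns where the empty string (never NA) marks an absent value, so
archives round-trip exactly.  The rank ladder is ordered lowest rank first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("taxatables")

#: Mandatory columns of each table, in canonical order.
NAME_COLUMNS = ("usage_id", "concept_id", "full_name", "author")
CONCEPT_COLUMNS = ("concept_id", "accepted_name_id", "parent_id", "rank", "view_id")
VIEW_COLUMNS = ("view_id", "author", "year", "title")
TRAIT_COLUMNS = ("concept_id",)

#: Columns stored as nullable pandas Int64.
INT_COLUMNS = {
    "usage_id",
    "concept_id",
    "accepted_name_id",
    "parent_id",
    "view_id",
    "year",
}


class TaxaTablesError(Exception):
    """Base class for all errors raised by this package."""


class LookupMissError(TaxaTablesError):
    """A concept, name or view id does not exist in the list."""


def normalize_text(value: object) -> str:
    """Collapse internal whitespace and trim; used for combination uniqueness.

    Comparison stays case-sensitive because letter case is meaningful in
    botanical names.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return " ".join(str(value).split())


def _empty_frame(columns: Sequence[str]) -> pd.DataFrame:
    data = {}
    for col in columns:
        dtype = "Int64" if col in INT_COLUMNS else object
        data[col] = pd.Series([], dtype=dtype)
    return pd.DataFrame(data)


def _coerce_frame(df: pd.DataFrame, mandatory: Sequence[str]) -> pd.DataFrame:
    """Return a copy with mandatory columns first and conventional dtypes."""
    df = df.copy().reset_index(drop=True)
    for col in mandatory:
        if col not in df.columns:
            df[col] = pd.Series([pd.NA] * len(df), dtype="Int64" if col in INT_COLUMNS else object)
    order = list(mandatory) + [c for c in df.columns if c not in mandatory]
    df = df[order]
    for col in df.columns:
        if col in INT_COLUMNS:
            df[col] = df[col].astype("Int64")
        elif df[col].dtype == object:
            df[col] = df[col].map(lambda v: "" if v is None or (pd.api.types.is_scalar(v) and pd.isna(v)) else v)
    return df.reset_index(drop=True)


@dataclass
class TaxonList:
    """A taxonomic checklist: four linked tables plus a rank ladder.

    Construct via :func:`new_checklist` (empty prototype) or the readers in
    :mod:`taxatables.io`; mutate only through the editing functions in
    :mod:`taxatables.edit`, which guarantee the result stays valid.
    """

    names: pd.DataFrame = field(default_factory=lambda: _empty_frame(NAME_COLUMNS))
    concepts: pd.DataFrame = field(default_factory=lambda: _empty_frame(CONCEPT_COLUMNS))
    views: pd.DataFrame = field(default_factory=lambda: _empty_frame(VIEW_COLUMNS))
    traits: pd.DataFrame = field(default_factory=lambda: _empty_frame(TRAIT_COLUMNS))
    ranks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = _coerce_frame(self.names, NAME_COLUMNS)
        self.concepts = _coerce_frame(self.concepts, CONCEPT_COLUMNS)
        self.views = _coerce_frame(self.views, VIEW_COLUMNS)
        self.traits = _coerce_frame(self.traits, TRAIT_COLUMNS)
        self.ranks = list(self.ranks)

    # -- basic introspection -------------------------------------------------
    def copy(self) -> "TaxonList":
        return TaxonList(
            names=self.names.copy(),
            concepts=self.concepts.copy(),
            views=self.views.copy(),
            traits=self.traits.copy(),
            ranks=list(self.ranks),
        )

    def concept_ids(self) -> set[int]:
        return set(self.concepts["concept_id"].dropna().astype(int))

    def usage_ids(self) -> set[int]:
        return set(self.names["usage_id"].dropna().astype(int))

    def view_ids(self) -> set[int]:
        return set(self.views["view_id"].dropna().astype(int))

    def has_concept(self, concept_id: int) -> bool:
        return int(concept_id) in self.concept_ids()

    def next_concept_id(self) -> int:
        ids = self.concepts["concept_id"].dropna()
        return int(ids.max()) + 1 if len(ids) else 1

    def next_usage_id(self) -> int:
        ids = self.names["usage_id"].dropna()
        return int(ids.max()) + 1 if len(ids) else 1

    def next_view_id(self) -> int:
        ids = self.views["view_id"].dropna()
        return int(ids.max()) + 1 if len(ids) else 1

    def concept_row(self, concept_id: int) -> pd.Series:
        rows = self.concepts[self.concepts["concept_id"] == int(concept_id)]
        if rows.empty:
            raise LookupMissError(f"concept {concept_id} does not exist")
        return rows.iloc[0]

    def names_of(self, concept_id: int) -> pd.DataFrame:
        return self.names[self.names["concept_id"] == int(concept_id)]

    def equals(self, other: "TaxonList") -> bool:
        """Value-level equality of all four tables and the ladder."""
        if self.ranks != other.ranks:
            return False
        for a, b in (
            (self.names, other.names),
            (self.concepts, other.concepts),
            (self.views, other.views),
            (self.traits, other.traits),
        ):
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            if not a.reset_index(drop=True).equals(b.reset_index(drop=True)):
                return False
        return True


def new_checklist() -> TaxonList:
    """Return an empty, valid checklist (the prototype object)."""
    return TaxonList()


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    """Whole-list overview: table sizes, hierarchy flag and rank labels."""

    n_names: int
    n_concepts: int
    n_trait_variables: int
    n_views: int
    has_parent_child: bool
    rank_labels: tuple[str, ...]


@dataclass(frozen=True)
class ConceptSummary:
    """Per-concept overview: accepted name, view, synonyms, rank, parent."""

    concept_id: int
    accepted_name: tuple[str, str]
    view: str | None
    synonyms: tuple[tuple[str, str], ...]
    rank: str | None
    parent: tuple[str, str] | None


def summary_list(checklist: TaxonList) -> SummaryStats:
    """Count names, concepts, trait variables and views; report hierarchy.

    The trait count is the number of trait *variables* (columns besides the
    concept key), not the number of concepts carrying trait records.
    """
    has_parents = bool(checklist.concepts["parent_id"].notna().any())
    return SummaryStats(
        n_names=len(checklist.names),
        n_concepts=len(checklist.concepts),
        n_trait_variables=max(len(checklist.traits.columns) - 1, 0),
        n_views=len(checklist.views),
        has_parent_child=has_parents,
        rank_labels=tuple(checklist.ranks),
    )


def _format_view(checklist: TaxonList, view_id: object) -> str | None:
    if pd.isna(view_id):
        return None
    rows = checklist.views[checklist.views["view_id"] == int(view_id)]
    if rows.empty:
        return None
    row = rows.iloc[0]
    year = "" if pd.isna(row.get("year")) else str(int(row["year"]))
    parts = [p for p in (str(row.get("author", "")), f"({year})" if year else "", str(row.get("title", ""))) if p]
    return " ".join(parts)


def _accepted_pair(checklist: TaxonList, concept_id: int) -> tuple[str, str]:
    row = checklist.concept_row(concept_id)
    names = checklist.names[checklist.names["usage_id"] == row["accepted_name_id"]]
    if names.empty:
        raise LookupMissError(f"concept {concept_id} has no accepted name row")
    name = names.iloc[0]
    return (str(name["full_name"]), str(name["author"]))


def summarize_concept(checklist: TaxonList, concept_id: int) -> ConceptSummary:
    """Build the per-concept overview for one existing concept."""
    row = checklist.concept_row(concept_id)
    accepted = _accepted_pair(checklist, concept_id)
    own = checklist.names_of(concept_id).sort_values("usage_id")
    synonyms = tuple(
        (str(r["full_name"]), str(r["author"]))
        for _, r in own.iterrows()
        if r["usage_id"] != row["accepted_name_id"]
    )
    rank = str(row["rank"]) if row["rank"] else None
    parent = None
    if not pd.isna(row["parent_id"]):
        parent = _accepted_pair(checklist, int(row["parent_id"]))
    return ConceptSummary(
        concept_id=int(concept_id),
        accepted_name=accepted,
        view=_format_view(checklist, row["view_id"]),
        synonyms=synonyms,
        rank=rank,
        parent=parent,
    )


def summary_concept(checklist: TaxonList, query: int | str) -> list[ConceptSummary]:
    """Look concepts up by exact id (integer) or name substring (text).

    Text queries match case-insensitively against every usage name of a
    concept — accepted or synonym.  An empty result simply means no concept
    matched; malformed queries raise.
    """
    if isinstance(query, bool):
        raise TaxaTablesError("query must be an integer id or a text fragment")
    if isinstance(query, int):
        if not checklist.has_concept(query):
            return []
        return [summarize_concept(checklist, int(query))]
    if not isinstance(query, str) or not query:
        raise TaxaTablesError("query must be a non-empty string or an integer id")
    needle = query.lower()
    hits = checklist.names[checklist.names["full_name"].str.lower().str.contains(needle, regex=False)]
    concept_ids = sorted(set(hits["concept_id"].dropna().astype(int)))
    return [summarize_concept(checklist, cid) for cid in concept_ids if checklist.has_concept(cid)]


# ---------------------------------------------------------------------------
# Rank ladder access
# ---------------------------------------------------------------------------

def levels_get(checklist: TaxonList) -> list[str]:
    """Return the rank ladder, lowest rank first."""
    return list(checklist.ranks)


def levels_set(checklist: TaxonList, ladder: Iterable[str]) -> TaxonList:
    """Replace the rank ladder, refusing ladders that break existing data.

    A new ladder must keep every rank already assigned to a concept and must
    not invert the strict parent-above-child ordering of any existing ranked
    parent/child pair.
    """
    ladder = [str(label) for label in ladder]
    if len(set(ladder)) != len(ladder):
        raise TaxaTablesError("rank ladder labels must be unique")
    in_use = {str(r) for r in checklist.concepts["rank"] if r}
    missing = in_use - set(ladder)
    if missing:
        raise TaxaTablesError(f"new ladder drops ranks in use: {sorted(missing)}")
    index = {label: i for i, label in enumerate(ladder)}
    by_id = checklist.concepts.set_index("concept_id")
    for _, row in checklist.concepts.iterrows():
        if not row["rank"] or pd.isna(row["parent_id"]):
            continue
        parent_id = int(row["parent_id"])
        if parent_id not in by_id.index:
            continue
        parent_rank = by_id.loc[parent_id, "rank"]
        if not parent_rank:
            continue
        if index[str(parent_rank)] <= index[str(row["rank"])]:
            raise TaxaTablesError(
                f"ladder would invert rank order for child {int(row['concept_id'])} "
                f"({row['rank']}) under parent {parent_id} ({parent_rank})"
            )
    out = checklist.copy()
    out.ranks = ladder
    return out


__all__ = [
    "TaxonList",
    "TaxaTablesError",
    "LookupMissError",
    "SummaryStats",
    "ConceptSummary",
    "new_checklist",
    "summary_list",
    "summary_concept",
    "summarize_concept",
    "levels_get",
    "levels_set",
    "normalize_text",
    "NAME_COLUMNS",
    "CONCEPT_COLUMNS",
    "VIEW_COLUMNS",
    "TRAIT_COLUMNS",
    "INT_COLUMNS",
]
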