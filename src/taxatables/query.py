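"""Subsetting and hierarchy navigation.

``subset`` extracts taxon concepts by a structured query against one table
(names, concepts or traits) and can pull in the full ancestor and/or
descendant closure of the matched concepts, always returning a valid
checklist.  The structured (table, column, operator, value) form replaces
free host-language expressions so queries are portable to the command line;
conjunction is composition of ``subset`` calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .model import TaxaTablesError, TaxonList, LookupMissError

OPERATORS = ("equals", "contains", "less_than", "greater_than", "in_set")
QUERYABLE_TABLES = ("names", "concepts", "traits")


class QueryError(TaxaTablesError):
    """Malformed query: unknown table/column or type-incompatible operator."""


@dataclass(frozen=True)
class SubsetQuery:
    """One predicate over one column of one table.

    ``contains`` matches text case-insensitively; ``equals`` is exact and
    case-sensitive; ``less_than``/``greater_than`` compare numerically;
    ``in_set`` tests membership in a collection of literals.
    """

    table: str
    column: str
    operator: str
    value: object

    def __post_init__(self) -> None:
        if self.table not in QUERYABLE_TABLES:
            raise QueryError(f"table must be one of {QUERYABLE_TABLES}, got '{self.table}'")
        if self.operator not in OPERATORS:
            raise QueryError(f"operator must be one of {OPERATORS}, got '{self.operator}'")


def _match_mask(df: pd.DataFrame, query: SubsetQuery) -> pd.Series:
    if query.column not in df.columns:
        raise QueryError(f"column '{query.column}' not in table '{query.table}'")
    col = df[query.column]
    try:
        if query.operator == "equals":
            mask = col == query.value
        elif query.operator == "contains":
            mask = col.astype(str).str.lower().str.contains(str(query.value).lower(), regex=False)
        elif query.operator == "less_than":
            mask = pd.to_numeric(col, errors="coerce") < float(query.value)
        elif query.operator == "greater_than":
            mask = pd.to_numeric(col, errors="coerce") > float(query.value)
        else:  # in_set
            mask = col.isin(list(query.value))
    except (TypeError, ValueError) as exc:
        raise QueryError(f"operator '{query.operator}' incompatible with column '{query.column}': {exc}") from None
    return mask.fillna(False).astype(bool)


def seed_concepts(checklist: TaxonList, query: SubsetQuery) -> set[int]:
    """Concept ids selected directly by the query (before closure expansion)."""
    table = getattr(checklist, query.table)
    mask = _match_mask(table, query)
    return set(table.loc[mask, "concept_id"].dropna().astype(int)) & checklist.concept_ids()


def _parent_map(checklist: TaxonList) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for _, row in checklist.concepts.iterrows():
        cid = int(row["concept_id"])
        out[cid] = None if pd.isna(row["parent_id"]) else int(row["parent_id"])
    return out


def get_parents(checklist: TaxonList, concept_id: int) -> list[int]:
    """Ancestor chain of a concept, nearest parent first, root last."""
    if int(concept_id) not in checklist.concept_ids():
        raise LookupMissError(f"concept {concept_id} does not exist")
    parent_of = _parent_map(checklist)
    chain, current, seen = [], int(concept_id), set()
    while True:
        parent = parent_of.get(current)
        if parent is None or parent not in parent_of or parent in seen:
            return chain
        seen.add(parent)
        chain.append(parent)
        current = parent


def get_children(checklist: TaxonList, concept_id: int, recursive: bool = False) -> list[int]:
    """Direct children of a concept, or all descendants when ``recursive``."""
    if int(concept_id) not in checklist.concept_ids():
        raise LookupMissError(f"concept {concept_id} does not exist")
    children_of: dict[int, list[int]] = {}
    for cid, parent in _parent_map(checklist).items():
        if parent is not None:
            children_of.setdefault(parent, []).append(cid)
    if not recursive:
        return sorted(children_of.get(int(concept_id), []))
    out: set[int] = set()
    frontier = list(children_of.get(int(concept_id), []))
    while frontier:
        cid = frontier.pop()
        if cid in out:
            continue
        out.add(cid)
        frontier.extend(children_of.get(cid, []))
    return sorted(out)


def expand_concepts(
    checklist: TaxonList,
    seeds: Iterable[int],
    keep_children: bool = False,
    keep_parents: bool = False,
) -> set[int]:
    """Close a concept set over descendants and/or transitive ancestors.

    ``keep_parents`` pulls the *full* lineage up to the root, so a species
    selection can be displayed with its genus and family.
    """
    selected = set(int(s) for s in seeds)
    if keep_children:
        for cid in list(selected):
            selected.update(get_children(checklist, cid, recursive=True))
    if keep_parents:
        for cid in list(selected):
            selected.update(get_parents(checklist, cid))
    return selected


def subset(
    checklist: TaxonList,
    query: SubsetQuery,
    keep_children: bool = False,
    keep_parents: bool = False,
) -> TaxonList:
    """Extract the concepts matched by ``query`` as a new, valid checklist.

    The output keeps every usage name of the retained concepts, their trait
    records, the views they reference and the full rank ladder.  Parent
    pointers to concepts outside the selection are nulled (this can only
    happen with ``keep_parents=False``).
    """
    selected = expand_concepts(checklist, seed_concepts(checklist, query), keep_children, keep_parents)
    out = checklist.copy()
    out.concepts = out.concepts[out.concepts["concept_id"].isin(list(selected))].reset_index(drop=True)
    dangling = out.concepts["parent_id"].notna() & ~out.concepts["parent_id"].isin(list(selected))
    out.concepts.loc[dangling, "parent_id"] = pd.NA
    out.names = out.names[out.names["concept_id"].isin(list(selected))].reset_index(drop=True)
    out.traits = out.traits[out.traits["concept_id"].isin(list(selected))].reset_index(drop=True)
    used_views = set(out.concepts["view_id"].dropna().astype(int))
    out.views = out.views[out.views["view_id"].isin(list(used_views))].reset_index(drop=True)
    return out


def accepted_name(checklist: TaxonList, concept_id: int) -> tuple[str, str]:
    """The (full_name, author) combination currently designating the concept."""
    row = checklist.concept_row(concept_id)
    names = checklist.names[checklist.names["usage_id"] == row["accepted_name_id"]]
    if names.empty:
        raise LookupMissError(f"concept {concept_id} has no accepted name row")
    hit = names.iloc[0]
    return (str(hit["full_name"]), str(hit["author"]))


def synonyms(checklist: TaxonList, concept_id: int) -> list[tuple[str, str]]:
    """All non-accepted usage names of the concept, ordered by usage_id."""
    row = checklist.concept_row(concept_id)
    own = checklist.names_of(int(concept_id)).sort_values("usage_id")
    return [
        (str(r["full_name"]), str(r["author"]))
        for _, r in own.iterrows()
        if r["usage_id"] != row["accepted_name_id"]
    ]


__all__ = [
    "SubsetQuery",
    "QueryError",
    "OPERATORS",
    "QUERYABLE_TABLES",
    "subset",
    "seed_concepts",
    "expand_concepts",
    "get_parents",
    "get_children",
    "accepted_name",
    "synonyms",
]
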