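"""Safe editing of checklists: every accepted edit preserves validity.

All functions are transactional in the copy-or-raise sense: they never touch
the input object, and a rejected edit raises :class:`EditError` before any
output exists, so the caller's list is untouched either way.

The safety restrictions mirror curatorial practice: only synonyms may move
between concepts (swap the accepted name first), a new accepted name must
already be a synonym of its concept, and parent assignments must respect the
rank ladder and acyclicity.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    TaxaTablesError,
    TaxonList,
    normalize_text,
)


class EditError(TaxaTablesError):
    """An edit was rejected; the input list is unchanged."""


def _combination_clash(checklist: TaxonList, full_name: str, author: str) -> int | None:
    """usage_id of an existing row with the same normalized combination, if any."""
    key_name, key_author = normalize_text(full_name), normalize_text(author)
    for _, row in checklist.names.iterrows():
        if normalize_text(row["full_name"]) == key_name and normalize_text(row["author"]) == key_author:
            return int(row["usage_id"])
    return None


def _ladder_index(checklist: TaxonList, rank: str) -> int:
    try:
        return checklist.ranks.index(rank)
    except ValueError:
        raise EditError(f"rank '{rank}' is not on the ladder {checklist.ranks}") from None


def _check_rank_under_parent(checklist: TaxonList, rank: str | None, parent_id: int | None) -> None:
    if rank is None or parent_id is None:
        return
    parent_rank = checklist.concept_row(parent_id)["rank"]
    if not parent_rank:
        return
    if _ladder_index(checklist, str(parent_rank)) <= _ladder_index(checklist, rank):
        raise EditError(
            f"rank '{rank}' is not strictly below parent {parent_id}'s rank '{parent_rank}'"
        )


def _append_row(df: pd.DataFrame, row: dict) -> pd.DataFrame:
    new = {col: row.get(col, pd.NA if str(df[col].dtype) == "Int64" else "") for col in df.columns}
    return pd.concat([df, pd.DataFrame([new]).astype(df.dtypes.to_dict())], ignore_index=True)


def add_concept(
    checklist: TaxonList,
    accepted_names: Sequence[tuple[str, str]],
    rank: str | None = None,
    view_id: int | None = None,
    parent_id: int | None = None,
) -> tuple[TaxonList, list[int]]:
    """Create one new concept per (full_name, author) pair, each accepted.

    Returns the new list and the fresh concept ids, in input order.
    """
    if rank is not None:
        _ladder_index(checklist, rank)
    if view_id is not None and int(view_id) not in checklist.view_ids():
        raise EditError(f"view {view_id} does not exist")
    if parent_id is not None:
        if int(parent_id) not in checklist.concept_ids():
            raise EditError(f"parent concept {parent_id} does not exist")
        _check_rank_under_parent(checklist, rank, int(parent_id))

    seen: set[tuple[str, str]] = set()
    for full_name, author in accepted_names:
        clash = _combination_clash(checklist, full_name, author)
        if clash is not None:
            raise EditError(
                f"combination '{full_name} / {author}' already exists as usage_id {clash} (duplicated combination)"
            )
        key = (normalize_text(full_name), normalize_text(author))
        if key in seen:
            raise EditError(f"combination '{full_name} / {author}' given twice in one call")
        seen.add(key)

    out = checklist.copy()
    new_ids: list[int] = []
    for full_name, author in accepted_names:
        cid, uid = out.next_concept_id(), out.next_usage_id()
        out.names = _append_row(
            out.names,
            {"usage_id": uid, "concept_id": cid, "full_name": str(full_name), "author": str(author)},
        )
        out.concepts = _append_row(
            out.concepts,
            {
                "concept_id": cid,
                "accepted_name_id": uid,
                "parent_id": pd.NA if parent_id is None else int(parent_id),
                "rank": rank or "",
                "view_id": pd.NA if view_id is None else int(view_id),
            },
        )
        new_ids.append(cid)
    return out, new_ids


def add_synonym(checklist: TaxonList, concept_id: int, full_name: str, author: str) -> TaxonList:
    """Attach a new (non-accepted) usage name to an existing concept."""
    if int(concept_id) not in checklist.concept_ids():
        raise EditError(f"concept {concept_id} does not exist")
    clash = _combination_clash(checklist, full_name, author)
    if clash is not None:
        raise EditError(f"combination '{full_name} / {author}' already exists as usage_id {clash}")
    out = checklist.copy()
    out.names = _append_row(
        out.names,
        {
            "usage_id": out.next_usage_id(),
            "concept_id": int(concept_id),
            "full_name": str(full_name),
            "author": str(author),
        },
    )
    return out


def set_accepted_name(checklist: TaxonList, concept_id: int, usage_id: int) -> TaxonList:
    """Promote an existing synonym of the concept to be its accepted name.

    The former accepted name stays with the concept as a synonym.  Promoting
    a name of another concept is rejected (move it first with
    :func:`change_concept`); promoting the current accepted name is rejected
    as a probable caller mistake rather than silently doing nothing.
    """
    row = checklist.concept_row(concept_id)
    target = checklist.names[checklist.names["usage_id"] == int(usage_id)]
    if target.empty:
        raise EditError(f"usage {usage_id} does not exist")
    owner = int(target.iloc[0]["concept_id"])
    if owner != int(concept_id):
        raise EditError(
            f"usage {usage_id} belongs to concept {owner}, not {concept_id}; use change_concept first"
        )
    if int(row["accepted_name_id"]) == int(usage_id):
        raise EditError(f"usage {usage_id} is already the accepted name of concept {concept_id}")
    out = checklist.copy()
    mask = out.concepts["concept_id"] == int(concept_id)
    out.concepts.loc[mask, "accepted_name_id"] = int(usage_id)
    return out


def change_concept(checklist: TaxonList, usage_id: int, target_concept_id: int) -> TaxonList:
    """Move a synonym to another concept, preserving the name's identity.

    Accepted names never move; the name keeps its usage_id, spelling and
    authority — only the concept link changes.
    """
    rows = checklist.names[checklist.names["usage_id"] == int(usage_id)]
    if rows.empty:
        raise EditError(f"usage {usage_id} does not exist")
    current = int(rows.iloc[0]["concept_id"])
    concept = checklist.concept_row(current)
    if int(concept["accepted_name_id"]) == int(usage_id):
        raise EditError(
            f"usage {usage_id} is the accepted name of concept {current}; set a new accepted name first"
        )
    if int(target_concept_id) not in checklist.concept_ids():
        raise EditError(f"target concept {target_concept_id} does not exist")
    if int(target_concept_id) == current:
        raise EditError(f"usage {usage_id} already belongs to concept {target_concept_id}")
    out = checklist.copy()
    out.names.loc[out.names["usage_id"] == int(usage_id), "concept_id"] = int(target_concept_id)
    return out


def _ancestors(checklist: TaxonList, concept_id: int) -> list[int]:
    parent_of = dict(
        zip(
            checklist.concepts["concept_id"].dropna().astype(int),
            checklist.concepts["parent_id"],
        )
    )
    chain, current, seen = [], concept_id, set()
    while True:
        parent = parent_of.get(current)
        if parent is None or pd.isna(parent):
            return chain
        parent = int(parent)
        if parent in seen:  # pre-existing cycle; stop rather than loop
            return chain
        seen.add(parent)
        chain.append(parent)
        current = parent


def add_parent(checklist: TaxonList, child_ids: Iterable[int], parent_id: int) -> TaxonList:
    """Attach children to a parent concept, enforcing ranks and acyclicity.

    Cycle detection is explicit: unranked concepts are exempt from rank
    checks and could otherwise form loops.
    """
    child_ids = [int(c) for c in child_ids]
    if int(parent_id) not in checklist.concept_ids():
        raise EditError(f"parent concept {parent_id} does not exist")
    for cid in child_ids:
        if cid not in checklist.concept_ids():
            raise EditError(f"child concept {cid} does not exist")
        if cid == int(parent_id) or cid in _ancestors(checklist, int(parent_id)):
            raise EditError(f"attaching {cid} under {parent_id} would create a cycle")
        child_rank = checklist.concept_row(cid)["rank"]
        if child_rank:
            _check_rank_under_parent(checklist, str(child_rank), int(parent_id))
    out = checklist.copy()
    mask = out.concepts["concept_id"].isin(child_ids)
    out.concepts.loc[mask, "parent_id"] = int(parent_id)
    return out


def add_level(checklist: TaxonList, rank_label: str, position: int) -> TaxonList:
    """Insert a new rank into the ladder at ``position`` (0 = lowest).

    Insertion between existing ranks can never break the strict ordering of
    pairs that were already valid, because relative order of existing labels
    is preserved.
    """
    rank_label = str(rank_label)
    if rank_label in checklist.ranks:
        raise EditError(f"rank '{rank_label}' is already on the ladder")
    if not 0 <= int(position) <= len(checklist.ranks):
        raise EditError(f"position {position} outside 0..{len(checklist.ranks)}")
    out = checklist.copy()
    out.ranks.insert(int(position), rank_label)
    return out


def set_traits(checklist: TaxonList, concept_id: int, values: Mapping[str, object]) -> TaxonList:
    """Upsert the trait record of a concept; new variables extend the schema."""
    if int(concept_id) not in checklist.concept_ids():
        raise EditError(f"concept {concept_id} does not exist")
    if not values:
        raise EditError("no trait values given")
    out = checklist.copy()
    for var in values:
        if var == "concept_id":
            raise EditError("'concept_id' is the trait-table key, not a variable")
        if var not in out.traits.columns:
            out.traits[var] = "" if isinstance(values[var], str) else pd.NA
    mask = out.traits["concept_id"] == int(concept_id)
    if mask.any():
        for var, value in values.items():
            out.traits.loc[mask, var] = value
    else:
        row = {"concept_id": int(concept_id), **values}
        out.traits = _append_row(out.traits, row)
    return out


def add_view(checklist: TaxonList, author: str, year: int | None = None, title: str = "", **extra: object) -> tuple[TaxonList, int]:
    """Register a new taxon view (bibliographic reference); returns its id."""
    out = checklist.copy()
    vid = out.next_view_id()
    for col in extra:
        if col not in out.views.columns:
            out.views[col] = ""
    out.views = _append_row(
        out.views,
        {"view_id": vid, "author": str(author), "year": pd.NA if year is None else int(year), "title": str(title), **extra},
    )
    return out, vid


def set_view(checklist: TaxonList, concept_ids: Iterable[int], view_id: int) -> TaxonList:
    """Point concepts at an existing taxon view."""
    concept_ids = [int(c) for c in concept_ids]
    if int(view_id) not in checklist.view_ids():
        raise EditError(f"view {view_id} does not exist")
    for cid in concept_ids:
        if cid not in checklist.concept_ids():
            raise EditError(f"concept {cid} does not exist")
    out = checklist.copy()
    mask = out.concepts["concept_id"].isin(concept_ids)
    out.concepts.loc[mask, "view_id"] = int(view_id)
    return out


__all__ = [
    "EditError",
    "add_concept",
    "add_synonym",
    "set_accepted_name",
    "change_concept",
    "add_parent",
    "add_level",
    "set_traits",
    "add_view",
    "set_view",
]
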