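"""Validity rules for checklists and the ``clean`` repair operation.

A checklist is *valid* when ten closed rules all hold: unique identifiers
(V1, V2), unique name/author combinations (V3), no orphaned rows (V4, V5,
V7, V10), a coherent accepted name per concept (V6), ranks drawn from the
ladder (V8) and parents strictly above children on the ladder (V9).

``validate`` never raises on broken input — it reports every violation in a
deterministic order so reports diff cleanly under version control.  ``clean``
repairs only the referential (orphan-class) defects; duplicated combinations
and rank-order breaches require an editorial decision and are left reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import TaxonList, normalize_text

RULE_CODES = (
    "V1_DUP_USAGE_ID",
    "V2_DUP_CONCEPT_ID",
    "V3_DUP_COMBINATION",
    "V4_ORPHANED_NAME",
    "V5_ORPHANED_TRAIT",
    "V6_MISSING_ACCEPTED",
    "V7_MISSING_PARENT",
    "V8_UNKNOWN_RANK",
    "V9_RANK_ORDER",
    "V10_DANGLING_VIEW",
)


@dataclass(frozen=True)
class Violation:
    """One broken rule with the ids of the offending rows."""

    rule_code: str
    offending_ids: tuple[int, ...]
    message: str


def _dup_groups(series: pd.Series) -> list[int]:
    counts = series.dropna().astype(int).value_counts()
    return sorted(int(v) for v in counts[counts > 1].index)


def validate(checklist: TaxonList) -> list[Violation]:
    """Check all ten rules and return every violation found.

    Output is sorted by (rule code, first offending id); an empty list means
    the checklist is valid.
    """
    out: list[Violation] = []
    names, concepts = checklist.names, checklist.concepts
    concept_ids = checklist.concept_ids()
    usage_ids_series = names["usage_id"].dropna().astype(int)
    view_ids = checklist.view_ids()

    for uid in _dup_groups(names["usage_id"]):
        out.append(Violation("V1_DUP_USAGE_ID", (uid,), f"usage_id {uid} occurs more than once"))

    for cid in _dup_groups(concepts["concept_id"]):
        out.append(Violation("V2_DUP_CONCEPT_ID", (cid,), f"concept_id {cid} occurs more than once"))

    # V3: same combination = same normalized full_name + author.
    if len(names):
        keys = names["full_name"].map(normalize_text) + "\x1f" + names["author"].map(normalize_text)
        for key, group in names.groupby(keys):
            if len(group) > 1:
                ids = tuple(sorted(int(u) for u in group["usage_id"].dropna()))
                combo = key.replace("\x1f", " / ")
                out.append(Violation("V3_DUP_COMBINATION", ids, f"combination '{combo}' used by usage_ids {list(ids)}"))

    orphan_names = names[~names["concept_id"].isin(list(concept_ids))]
    for _, row in orphan_names.iterrows():
        uid = int(row["usage_id"]) if not pd.isna(row["usage_id"]) else -1
        out.append(Violation("V4_ORPHANED_NAME", (uid,), f"name {uid} references missing concept {row['concept_id']}"))

    orphan_traits = checklist.traits[~checklist.traits["concept_id"].isin(list(concept_ids))]
    for _, row in orphan_traits.iterrows():
        cid = int(row["concept_id"]) if not pd.isna(row["concept_id"]) else -1
        out.append(Violation("V5_ORPHANED_TRAIT", (cid,), f"trait record references missing concept {cid}"))

    # V6: accepted_name_id must exist and belong to this very concept.
    name_owner = dict(zip(usage_ids_series, names.loc[usage_ids_series.index, "concept_id"].astype(int)))
    for _, row in concepts.iterrows():
        cid = int(row["concept_id"]) if not pd.isna(row["concept_id"]) else -1
        aid = row["accepted_name_id"]
        if pd.isna(aid) or int(aid) not in name_owner or name_owner[int(aid)] != cid:
            out.append(
                Violation("V6_MISSING_ACCEPTED", (cid,), f"concept {cid} lacks a coherent accepted name (accepted_name_id={aid})")
            )

    with_parent = concepts[concepts["parent_id"].notna()]
    for _, row in with_parent.iterrows():
        if int(row["parent_id"]) not in concept_ids:
            cid = int(row["concept_id"])
            out.append(Violation("V7_MISSING_PARENT", (cid,), f"concept {cid} points to missing parent {int(row['parent_id'])}"))

    ladder = {label: i for i, label in enumerate(checklist.ranks)}
    ranked = concepts[concepts["rank"].astype(bool)]
    for _, row in ranked.iterrows():
        if str(row["rank"]) not in ladder:
            cid = int(row["concept_id"])
            out.append(Violation("V8_UNKNOWN_RANK", (cid,), f"concept {cid} carries rank '{row['rank']}' not on the ladder"))

    # V9: both ranks present and known -> parent strictly higher.
    rank_of = dict(zip(concepts["concept_id"].dropna().astype(int), concepts["rank"]))
    for _, row in with_parent.iterrows():
        child_rank = str(row["rank"]) if row["rank"] else ""
        pid = int(row["parent_id"])
        parent_rank = str(rank_of.get(pid, "") or "")
        if child_rank in ladder and parent_rank in ladder and ladder[parent_rank] <= ladder[child_rank]:
            cid = int(row["concept_id"])
            out.append(
                Violation(
                    "V9_RANK_ORDER",
                    (cid, pid),
                    f"child {cid} ({child_rank}) is not strictly below parent {pid} ({parent_rank})",
                )
            )

    with_view = concepts[concepts["view_id"].notna()]
    for _, row in with_view.iterrows():
        if int(row["view_id"]) not in view_ids:
            cid = int(row["concept_id"])
            out.append(Violation("V10_DANGLING_VIEW", (cid,), f"concept {cid} references missing view {int(row['view_id'])}"))

    rule_order = {code: i for i, code in enumerate(RULE_CODES)}
    out.sort(key=lambda v: (rule_order[v.rule_code], v.offending_ids[0]))
    return out


def is_valid(checklist: TaxonList) -> bool:
    return not validate(checklist)


def clean(checklist: TaxonList) -> TaxonList:
    """Remove or null orphaned references until the list is referentially sound.

    Iterates to a fixed point: drops names and trait records that reference
    missing concepts, nulls parent and view references to missing rows, drops
    concepts that have no name rows at all, and re-points an accepted-name
    reference to the concept's lowest usage_id when the pointer is broken but
    names survive.  Duplicated combinations/ids and rank-order violations are
    deliberately not touched — fixing them means choosing between taxonomies.
    """
    out = checklist.copy()
    while True:
        changed = False
        concept_ids = out.concept_ids()
        view_ids = out.view_ids()

        keep = out.names["concept_id"].isin(list(concept_ids))
        if not keep.all():
            out.names = out.names[keep].reset_index(drop=True)
            changed = True

        keep = out.traits["concept_id"].isin(list(concept_ids))
        if not keep.all():
            out.traits = out.traits[keep].reset_index(drop=True)
            changed = True

        bad_parent = out.concepts["parent_id"].notna() & ~out.concepts["parent_id"].isin(list(concept_ids))
        if bad_parent.any():
            out.concepts.loc[bad_parent, "parent_id"] = pd.NA
            changed = True

        bad_view = out.concepts["view_id"].notna() & ~out.concepts["view_id"].isin(list(view_ids))
        if bad_view.any():
            out.concepts.loc[bad_view, "view_id"] = pd.NA
            changed = True

        # Concepts without any name cannot have an accepted name: drop them.
        named = set(out.names["concept_id"].dropna().astype(int))
        nameless = out.concepts["concept_id"].notna() & ~out.concepts["concept_id"].isin(list(named))
        if nameless.any():
            out.concepts = out.concepts[~nameless].reset_index(drop=True)
            changed = True

        # Broken accepted pointer with surviving names: re-point to the lowest
        # usage_id of the concept (deterministic, documented repair).
        owner = dict(
            zip(out.names["usage_id"].dropna().astype(int), out.names["concept_id"].dropna().astype(int))
        )
        for idx, row in out.concepts.iterrows():
            cid = int(row["concept_id"])
            aid = row["accepted_name_id"]
            if not pd.isna(aid) and owner.get(int(aid)) == cid:
                continue
            own = out.names.loc[out.names["concept_id"] == cid, "usage_id"].dropna().astype(int)
            if len(own):
                out.concepts.loc[idx, "accepted_name_id"] = int(own.min())
                changed = True

        if not changed:
            return out


__all__ = ["Violation", "RULE_CODES", "validate", "is_valid", "clean"]
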