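"""Quality-assurance utilities: controlled defect injection and random edits.

The validity engine is only trustworthy if each rule fires on exactly the
defect it names.  :func:`inject_defect` takes a valid checklist and breaks
precisely one rule, so the validator can be exercised rule by rule over many
random lists.  :func:`random_edit` draws one editing operation (sometimes a
deliberately illegal one) so the edit layer's accept-implies-valid /
reject-implies-untouched contract can be hammered at scale.
"""

from __future__ import annotations

import random
from typing import Callable

import pandas as pd

from . import edit as _edit
from .model import TaxaTablesError, TaxonList
from .validation import RULE_CODES


def _pick_row(rng: random.Random, df: pd.DataFrame) -> pd.Series:
    return df.iloc[rng.randrange(len(df))]


def _fresh_name(checklist: TaxonList, rng: random.Random) -> str:
    existing = set(checklist.names["full_name"])
    while True:
        candidate = f"Zzinventus fabricatus{rng.randrange(10**6)}"
        if candidate not in existing:
            return candidate


def _append(df: pd.DataFrame, row: dict) -> pd.DataFrame:
    new = {col: row.get(col, pd.NA if str(df[col].dtype) == "Int64" else "") for col in df.columns}
    return pd.concat([df, pd.DataFrame([new]).astype(df.dtypes.to_dict())], ignore_index=True)


def inject_defect(checklist: TaxonList, rule_code: str, rng: random.Random) -> TaxonList:
    """Return a copy of a valid checklist breaking exactly ``rule_code``.

    Requires a structurally rich list (hierarchy, ranks, at least one view
    and two concepts), as produced by the fixture generator.
    """
    if rule_code not in RULE_CODES:
        raise TaxaTablesError(f"unknown rule code {rule_code}")
    out = checklist.copy()
    concepts, names = out.concepts, out.names

    if rule_code == "V1_DUP_USAGE_ID":
        row = _pick_row(rng, names)
        out.names = _append(
            names,
            {
                "usage_id": int(row["usage_id"]),
                "concept_id": int(row["concept_id"]),
                "full_name": _fresh_name(out, rng),
                "author": "Qq.",
            },
        )
    elif rule_code == "V2_DUP_CONCEPT_ID":
        row = _pick_row(rng, concepts)
        out.concepts = pd.concat([concepts, row.to_frame().T.astype(concepts.dtypes.to_dict())], ignore_index=True)
    elif rule_code == "V3_DUP_COMBINATION":
        row = _pick_row(rng, names)
        out.names = _append(
            names,
            {
                "usage_id": out.next_usage_id(),
                "concept_id": int(row["concept_id"]),
                "full_name": str(row["full_name"]),
                "author": str(row["author"]),
            },
        )
    elif rule_code == "V4_ORPHANED_NAME":
        out.names = _append(
            names,
            {
                "usage_id": out.next_usage_id(),
                "concept_id": out.next_concept_id() + 1000,
                "full_name": _fresh_name(out, rng),
                "author": "Qq.",
            },
        )
    elif rule_code == "V5_ORPHANED_TRAIT":
        out.traits = _append(out.traits, {"concept_id": out.next_concept_id() + 1000})
    elif rule_code == "V6_MISSING_ACCEPTED":
        victim = _pick_row(rng, concepts)
        cid = int(victim["concept_id"])
        foreign = names[names["concept_id"] != cid]
        stolen = _pick_row(rng, foreign)
        out.concepts.loc[out.concepts["concept_id"] == cid, "accepted_name_id"] = int(stolen["usage_id"])
    elif rule_code == "V7_MISSING_PARENT":
        victim = _pick_row(rng, concepts)
        out.concepts.loc[out.concepts["concept_id"] == int(victim["concept_id"]), "parent_id"] = (
            out.next_concept_id() + 1000
        )
    elif rule_code == "V8_UNKNOWN_RANK":
        leaves = _leaf_concepts(out)
        victim = leaves[rng.randrange(len(leaves))]
        out.concepts.loc[out.concepts["concept_id"] == victim, "rank"] = "cohors_incognita"
    elif rule_code == "V9_RANK_ORDER":
        # a ranked leaf whose parent carries a rank: make the ranks equal
        by_id = dict(zip(concepts["concept_id"].astype(int), concepts["rank"]))
        parent_of = {
            int(r["concept_id"]): int(r["parent_id"])
            for _, r in concepts.iterrows()
            if not pd.isna(r["parent_id"])
        }
        candidates = [
            cid
            for cid in _leaf_concepts(out)
            if cid in parent_of and by_id.get(cid) and by_id.get(parent_of[cid])
        ]
        if not candidates:
            raise TaxaTablesError("fixture has no ranked leaf under a ranked parent")
        victim = candidates[rng.randrange(len(candidates))]
        out.concepts.loc[out.concepts["concept_id"] == victim, "rank"] = by_id[parent_of[victim]]
    elif rule_code == "V10_DANGLING_VIEW":
        victim = _pick_row(rng, concepts)
        out.concepts.loc[out.concepts["concept_id"] == int(victim["concept_id"]), "view_id"] = (
            out.next_view_id() + 1000
        )
    return out


def _leaf_concepts(checklist: TaxonList) -> list[int]:
    parents = set(checklist.concepts["parent_id"].dropna().astype(int))
    return sorted(set(checklist.concepts["concept_id"].astype(int)) - parents)


#: Edit kinds drawn by :func:`random_edit`; "bad_" variants must be rejected.
EDIT_KINDS = (
    "add_concept",
    "bad_add_concept_dup",
    "add_synonym",
    "bad_add_synonym_dup",
    "bad_add_synonym_unknown",
    "swap_accepted",
    "bad_swap_foreign",
    "bad_swap_already_accepted",
    "move_synonym",
    "bad_move_accepted",
    "reparent_species",
    "bad_parent_cycle",
    "bad_parent_rank",
    "add_level",
    "bad_add_level_dup",
    "set_traits",
    "bad_set_traits_unknown",
    "add_and_set_view",
)


def random_edit(checklist: TaxonList, rng: random.Random) -> tuple[str, Callable[[TaxonList], TaxonList]]:
    """Draw one applicable edit; returns (kind, thunk).

    Kinds prefixed ``bad_`` violate a precondition on purpose and must raise
    :class:`~taxatables.edit.EditError`; all others must succeed and leave
    the list valid.  The thunk always returns the resulting checklist.
    """
    names, concepts = checklist.names, checklist.concepts
    accepted_ids = set(concepts["accepted_name_id"].dropna().astype(int))
    synonym_rows = names[~names["usage_id"].isin(list(accepted_ids))]
    by_rank = {
        rank: list(concepts.loc[concepts["rank"] == rank, "concept_id"].astype(int))
        for rank in ("species", "genus", "family")
    }

    kinds = [k for k in EDIT_KINDS if _kind_applicable(k, checklist, synonym_rows, by_rank)]
    kind = kinds[rng.randrange(len(kinds))]

    if kind == "add_concept":
        name = _fresh_name(checklist, rng)
        genus = rng.choice(by_rank["genus"])
        return kind, lambda tl: _edit.add_concept(tl, [(name, "Nov.")], rank="species", parent_id=genus)[0]
    if kind == "bad_add_concept_dup":
        row = _pick_row(rng, names)
        pair = (str(row["full_name"]), str(row["author"]))
        return kind, lambda tl: _edit.add_concept(tl, [pair])[0]
    if kind == "add_synonym":
        cid = int(_pick_row(rng, concepts)["concept_id"])
        name = _fresh_name(checklist, rng)
        return kind, lambda tl: _edit.add_synonym(tl, cid, name, "Syn.")
    if kind == "bad_add_synonym_dup":
        row = _pick_row(rng, names)
        cid = int(_pick_row(rng, concepts)["concept_id"])
        return kind, lambda tl: _edit.add_synonym(tl, cid, str(row["full_name"]), str(row["author"]))
    if kind == "bad_add_synonym_unknown":
        missing = checklist.next_concept_id() + 500
        return kind, lambda tl: _edit.add_synonym(tl, missing, _fresh_name(checklist, rng), "Syn.")
    if kind == "swap_accepted":
        row = _pick_row(rng, synonym_rows)
        cid, uid = int(row["concept_id"]), int(row["usage_id"])
        return kind, lambda tl: _edit.set_accepted_name(tl, cid, uid)
    if kind == "bad_swap_foreign":
        row = _pick_row(rng, names)
        others = concepts[concepts["concept_id"] != int(row["concept_id"])]
        cid = int(_pick_row(rng, others)["concept_id"])
        return kind, lambda tl: _edit.set_accepted_name(tl, cid, int(row["usage_id"]))
    if kind == "bad_swap_already_accepted":
        row = _pick_row(rng, concepts)
        return kind, lambda tl: _edit.set_accepted_name(tl, int(row["concept_id"]), int(row["accepted_name_id"]))
    if kind == "move_synonym":
        row = _pick_row(rng, synonym_rows)
        others = concepts[concepts["concept_id"] != int(row["concept_id"])]
        target = int(_pick_row(rng, others)["concept_id"])
        return kind, lambda tl: _edit.change_concept(tl, int(row["usage_id"]), target)
    if kind == "bad_move_accepted":
        uid = int(rng.choice(sorted(accepted_ids)))
        owner = int(names.loc[names["usage_id"] == uid, "concept_id"].iloc[0])
        others = concepts[concepts["concept_id"] != owner]
        target = int(_pick_row(rng, others)["concept_id"])
        return kind, lambda tl: _edit.change_concept(tl, uid, target)
    if kind == "reparent_species":
        cid = rng.choice(by_rank["species"])
        genus = rng.choice(by_rank["genus"])
        return kind, lambda tl: _edit.add_parent(tl, [cid], genus)
    if kind == "bad_parent_cycle":
        cid = int(_pick_row(rng, concepts)["concept_id"])
        return kind, lambda tl: _edit.add_parent(tl, [cid], cid)
    if kind == "bad_parent_rank":
        genus = rng.choice(by_rank["genus"])
        species = rng.choice(by_rank["species"])
        return kind, lambda tl: _edit.add_parent(tl, [genus], species)
    if kind == "add_level":
        label = f"gradus{rng.randrange(10**6)}"
        position = rng.randrange(len(checklist.ranks) + 1)
        return kind, lambda tl: _edit.add_level(tl, label, position)
    if kind == "bad_add_level_dup":
        label = rng.choice(checklist.ranks)
        return kind, lambda tl: _edit.add_level(tl, label, 0)
    if kind == "set_traits":
        cid = int(_pick_row(rng, concepts)["concept_id"])
        value = rng.choice(["herb", "tree", "liana", "reed_plant"])
        return kind, lambda tl: _edit.set_traits(tl, cid, {"life_form": value})
    if kind == "bad_set_traits_unknown":
        missing = checklist.next_concept_id() + 500
        return kind, lambda tl: _edit.set_traits(tl, missing, {"life_form": "herb"})
    # add_and_set_view
    cids = [int(_pick_row(rng, concepts)["concept_id"])]

    def _thunk(tl: TaxonList) -> TaxonList:
        tl2, vid = _edit.add_view(tl, author="Qq.", year=2001, title="Synthetic view")
        return _edit.set_view(tl2, cids, vid)

    return "add_and_set_view", _thunk


def _kind_applicable(kind: str, checklist: TaxonList, synonym_rows: pd.DataFrame, by_rank: dict) -> bool:
    needs_synonym = kind in ("swap_accepted", "move_synonym")
    if needs_synonym and synonym_rows.empty:
        return False
    if kind in ("add_concept", "reparent_species", "bad_parent_rank") and (
        not by_rank["genus"] or (kind != "add_concept" and not by_rank["species"])
    ):
        return False
    if kind in ("bad_swap_foreign", "move_synonym", "bad_move_accepted") and len(checklist.concepts) < 2:
        return False
    if kind == "bad_add_level_dup" and not checklist.ranks:
        return False
    return len(checklist.names) > 0 and len(checklist.concepts) > 0


__all__ = ["inject_defect", "random_edit", "EDIT_KINDS"]
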