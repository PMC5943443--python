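"""Readers and writers for checklists.

Four routes in and out of a :class:`~taxatables.model.TaxonList`:

* :func:`read_flat_table` — build a list from a flat synonymy table (one row
  per usage name, an accepted flag per concept), the way most checklists are
  exchanged as CSV.
* :func:`read_turboveg` — import a Turboveg species list (DBF), optionally
  with its companion attribute table (``ecodbase``).  Turboveg keeps names
  and concepts in a single flat table and supports neither taxon views nor
  hierarchy, so the import creates none.
* :func:`write_archive` / :func:`read_archive` — the native persistence
  format: a zip of four CSV tables plus a JSON metadata member carrying the
  rank ladder, column order and dtypes, so round trips are value-exact.
* :func:`backup` / :func:`load_last` — date-stamped archive snapshots
  (``<base>_<YYYY-MM-DD>[_k].zip``); ``load_last`` restores the newest one
  by parsing filenames, never file mtimes.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
import zipfile
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import dbf as _dbf
from .model import (
    CONCEPT_COLUMNS,
    NAME_COLUMNS,
    TRAIT_COLUMNS,
    VIEW_COLUMNS,
    TaxaTablesError,
    TaxonList,
    normalize_text,
)
from .validation import validate

logger = logging.getLogger("taxatables")

ARCHIVE_VERSION = 1
_TABLES = ("names", "concepts", "views", "traits")


class FlatImportError(TaxaTablesError):
    """A flat synonymy table broke an import invariant (rows are 1-based)."""


class TurbovegImportError(TaxaTablesError):
    """A Turboveg species list could not be imported."""


class ArchiveError(TaxaTablesError):
    """A native archive is missing members, wrong version, or invalid."""


class BackupError(TaxaTablesError):
    """No restorable backup found, or a backup could not be written."""


# ---------------------------------------------------------------------------
# Flat synonymy tables
# ---------------------------------------------------------------------------

_FLAT_KNOWN = (
    "taxon_concept_id",
    "taxon_usage_id",
    "full_name",
    "author",
    "is_accepted",
    "rank",
    "parent_concept_id",
)


def _as_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "t", "yes", "y")
    return bool(value) and not pd.isna(value)


def read_flat_table(
    rows: pd.DataFrame | Sequence[Mapping] | Sequence[str],
    ranks: Sequence[str] | None = None,
) -> TaxonList:
    """Build a checklist from a flat synonymy table.

    ``rows`` may be a DataFrame, a sequence of mappings with the
    ``taxon_concept_id`` / ``full_name`` / ``is_accepted`` columns, or a bare
    sequence of accepted-name strings (each becomes its own concept).  Any
    column outside the known set becomes a trait variable, populated from the
    accepted row of each concept.  ``ranks`` supplies the rank ladder
    (lowest first) and is required whenever a ``rank`` column is used.

    Violations are import errors naming 1-based data row numbers.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = list(rows)
        if rows and isinstance(rows[0], str):
            rows = [
                {"taxon_concept_id": i + 1, "full_name": name, "author": "", "is_accepted": True}
                for i, name in enumerate(rows)
            ]
        rows = pd.DataFrame(list(rows))
    df = rows.copy().reset_index(drop=True)
    if df.empty:
        return TaxonList(ranks=list(ranks) if ranks else [])
    for required in ("taxon_concept_id", "full_name", "is_accepted"):
        if required not in df.columns:
            raise FlatImportError(f"missing required column '{required}'")
    if "author" not in df.columns:
        df["author"] = ""
    df["author"] = df["author"].map(normalize_text)
    df["full_name"] = df["full_name"].map(normalize_text)
    df["_row"] = df.index + 1
    df["_accepted"] = df["is_accepted"].map(_as_bool)

    # one accepted row per concept
    for cid, group in df.groupby("taxon_concept_id"):
        n_acc = int(group["_accepted"].sum())
        if n_acc != 1:
            rows_str = list(group.loc[group["_accepted"], "_row"]) if n_acc else list(group["_row"])
            raise FlatImportError(
                f"concept {cid} has {n_acc} accepted rows (rows {rows_str}); exactly one required"
            )

    # duplicate combinations
    combos = df.groupby(["full_name", "author"])["_row"].apply(list)
    dups = combos[combos.map(len) > 1]
    if len(dups):
        raise FlatImportError(f"duplicated combination {dups.index[0]} in rows {dups.iloc[0]}")

    # usage ids: unique where present, auto-assigned otherwise
    if "taxon_usage_id" in df.columns:
        uid = pd.to_numeric(df["taxon_usage_id"], errors="coerce").astype("Int64")
    else:
        uid = pd.Series([pd.NA] * len(df), dtype="Int64")
    present = uid.dropna().astype(int)
    dup_uids = present[present.duplicated()]
    if len(dup_uids):
        raise FlatImportError(f"duplicated taxon_usage_id {int(dup_uids.iloc[0])}")
    next_free = (int(present.max()) + 1) if len(present) else 1
    filled = []
    for v in uid:
        if pd.isna(v):
            filled.append(next_free)
            next_free += 1
        else:
            filled.append(int(v))
    df["_usage_id"] = pd.array(filled, dtype="Int64")

    concept_ids = set(pd.to_numeric(df["taxon_concept_id"]).astype(int))
    ladder = list(ranks) if ranks else []
    if "rank" in df.columns:
        used = {normalize_text(r) for r in df["rank"] if normalize_text(r)}
        if used and not ladder:
            raise FlatImportError("a 'rank' column requires a rank ladder (ranks=...)")
        unknown = used - set(ladder)
        if unknown:
            raise FlatImportError(f"ranks {sorted(unknown)} not on the supplied ladder")

    names = pd.DataFrame(
        {
            "usage_id": df["_usage_id"],
            "concept_id": pd.to_numeric(df["taxon_concept_id"]).astype("Int64"),
            "full_name": df["full_name"],
            "author": df["author"],
        }
    )

    accepted = df[df["_accepted"]].set_index("taxon_concept_id", drop=False)
    concept_rows = []
    trait_columns = [c for c in df.columns if c not in _FLAT_KNOWN and not c.startswith("_")]
    trait_rows = []
    for cid in sorted(concept_ids):
        arow = accepted.loc[int(cid)]
        parent = pd.NA
        if "parent_concept_id" in df.columns:
            raw = arow["parent_concept_id"]
            if not pd.isna(raw) and str(raw).strip() != "":
                parent = int(raw)
                if parent not in concept_ids:
                    raise FlatImportError(
                        f"row {int(arow['_row'])}: parent concept {parent} not present in the table"
                    )
        rank = normalize_text(arow["rank"]) if "rank" in df.columns else ""
        concept_rows.append(
            {
                "concept_id": int(cid),
                "accepted_name_id": int(arow["_usage_id"]),
                "parent_id": parent,
                "rank": rank,
                "view_id": pd.NA,
            }
        )
        values = {
            c: arow[c]
            for c in trait_columns
            if not pd.isna(arow[c]) and str(arow[c]).strip() != ""
        }
        if values:
            trait_rows.append({"concept_id": int(cid), **values})

    traits = pd.DataFrame(trait_rows) if trait_rows else pd.DataFrame(columns=list(TRAIT_COLUMNS))
    out = TaxonList(
        names=names,
        concepts=pd.DataFrame(concept_rows),
        traits=traits,
        ranks=ladder,
    )
    problems = validate(out)
    if problems:
        raise FlatImportError("imported table is not a valid checklist: " + "; ".join(v.message for v in problems))
    return out


# ---------------------------------------------------------------------------
# Turboveg species lists (DBF)
# ---------------------------------------------------------------------------

DEFAULT_TURBOVEG_MAP = {
    "species_nr": "SPECIES_NR",
    "name": "ABBREVIAT",
    "author": "AUTHOR",
    "synonym": "SYNONYM",
    "valid_nr": "VALID_NR",
}


def read_turboveg(
    species_table: str | Path,
    attribute_table: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
    encoding: str = "latin-1",
    strict: bool = False,
) -> TaxonList:
    """Import a Turboveg-dialect species list into a checklist.

    Rows whose ``valid_nr`` equals their own ``species_nr`` (or with no
    synonym marker at all) are accepted names and become taxon concepts,
    identified by their ``species_nr``.  Synonym rows attach to the concept
    of their ``valid_nr``; when the synonym flag and ``valid_nr`` disagree,
    ``valid_nr`` wins because it is the pointer that carries the structure
    (the conflict is logged).  Synonyms whose ``valid_nr`` resolves to no
    accepted row are dropped with a warning, or rejected with
    ``strict=True``.  Attribute-table rows keyed by an accepted
    ``species_nr`` become trait records; others are ignored with a warning.
    """
    cmap = dict(DEFAULT_TURBOVEG_MAP)
    if column_map:
        cmap.update(column_map)
    species = _dbf.read_dbf(species_table, encoding=encoding)
    for role in ("species_nr", "name"):
        if cmap[role] not in species.columns:
            raise TurbovegImportError(f"species table lacks mapped column {cmap[role]} ({role})")

    nr_col, name_col = cmap["species_nr"], cmap["name"]
    author_col, syn_col, valid_col = cmap["author"], cmap["synonym"], cmap["valid_nr"]
    extra_cols = [c for c in species.columns if c not in (nr_col, name_col, author_col, syn_col, valid_col)]

    accepted_nrs: set[int] = set()
    rows = []
    for _, row in species.iterrows():
        nr = row[nr_col]
        if pd.isna(nr):
            raise TurbovegImportError(f"species row with empty {nr_col}")
        nr = int(nr)
        valid_nr = row[valid_col] if valid_col in species.columns and not pd.isna(row.get(valid_col)) else None
        flag = bool(row[syn_col]) if syn_col in species.columns and not pd.isna(row.get(syn_col)) else None
        if valid_nr is not None:
            is_accepted = int(valid_nr) == nr
            if flag is not None and flag == is_accepted:
                logger.warning(
                    "species %s: synonym flag conflicts with %s=%s; trusting the pointer", nr, valid_col, valid_nr
                )
        else:
            is_accepted = not flag
            valid_nr = nr if is_accepted else None
        rows.append((nr, row, is_accepted, None if valid_nr is None else int(valid_nr)))
        if is_accepted:
            accepted_nrs.add(nr)

    dangling = sorted(nr for nr, _, acc, valid in rows if not acc and (valid is None or valid not in accepted_nrs))
    if dangling:
        msg = f"synonyms with unresolvable valid_nr: species_nr {dangling}"
        if strict:
            raise TurbovegImportError(msg)
        logger.warning("%s; dropped", msg)

    name_rows, concept_rows = [], []
    for nr, row, is_accepted, valid_nr in rows:
        if not is_accepted and valid_nr not in accepted_nrs:
            continue
        record = {
            "usage_id": nr,
            "concept_id": nr if is_accepted else valid_nr,
            "full_name": normalize_text(row[name_col]),
            "author": normalize_text(row[author_col]) if author_col in species.columns else "",
        }
        for col in extra_cols:
            record[col.lower()] = "" if pd.isna(row[col]) else row[col]
        name_rows.append(record)
        if is_accepted:
            concept_rows.append(
                {"concept_id": nr, "accepted_name_id": nr, "parent_id": pd.NA, "rank": "", "view_id": pd.NA}
            )

    trait_rows = []
    if attribute_table is not None:
        attrs = _dbf.read_dbf(attribute_table, encoding=encoding)
        if nr_col not in attrs.columns:
            raise TurbovegImportError(f"attribute table lacks key column {nr_col}")
        for _, row in attrs.iterrows():
            nr = row[nr_col]
            if pd.isna(nr) or int(nr) not in accepted_nrs:
                logger.warning("attribute row keyed by non-accepted species_nr %s ignored", nr)
                continue
            values = {
                c.lower(): row[c]
                for c in attrs.columns
                if c != nr_col and not pd.isna(row[c]) and str(row[c]).strip() != ""
            }
            if values:
                trait_rows.append({"concept_id": int(nr), **values})

    out = TaxonList(
        names=pd.DataFrame(name_rows) if name_rows else pd.DataFrame(columns=list(NAME_COLUMNS)),
        concepts=pd.DataFrame(concept_rows) if concept_rows else pd.DataFrame(columns=list(CONCEPT_COLUMNS)),
        traits=pd.DataFrame(trait_rows) if trait_rows else pd.DataFrame(columns=list(TRAIT_COLUMNS)),
    )
    problems = validate(out)
    if problems:
        raise TurbovegImportError(
            "imported species list is not a valid checklist: " + "; ".join(v.message for v in problems)
        )
    return out


# ---------------------------------------------------------------------------
# Native archive (zip of CSV tables + metadata)
# ---------------------------------------------------------------------------

def _frame_to_csv(df: pd.DataFrame) -> str:
    return df.to_csv(index=False)


def _restore_frame(text: str, columns: list[str], dtypes: dict[str, str]) -> pd.DataFrame:
    df = pd.read_csv(StringIO(text), dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        # header-only frames of zero columns serialize as an empty string
        df = pd.DataFrame({c: pd.Series([], dtype=object) for c in columns})
    for col in columns:
        dtype = dtypes.get(col, "object")
        series = df[col]
        if dtype == "Int64":
            df[col] = pd.to_numeric(series.replace("", None)).astype("Int64")
        elif dtype in ("int64", "float64"):
            df[col] = pd.to_numeric(series.replace("", None)).astype(dtype)
        elif dtype == "boolean":
            df[col] = series.replace("", None).map({"True": True, "False": False, None: pd.NA}).astype("boolean")
        else:
            df[col] = series.astype(object)
    return df


def write_archive(checklist: TaxonList, path: str | Path) -> Path:
    """Persist a valid checklist as a zip of four CSV tables + metadata."""
    problems = validate(checklist)
    if problems:
        raise ArchiveError("refusing to archive an invalid checklist: " + "; ".join(v.message for v in problems))
    path = Path(path)
    meta = {
        "format_version": ARCHIVE_VERSION,
        "ranks": list(checklist.ranks),
        "tables": {
            table: {
                "columns": list(getattr(checklist, table).columns),
                "dtypes": {c: str(getattr(checklist, table)[c].dtype) for c in getattr(checklist, table).columns},
            }
            for table in _TABLES
        },
    }
    # fixed member timestamps: identical lists produce byte-identical archives
    def _member(name: str) -> zipfile.ZipInfo:
        info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
        info.compress_type = zipfile.ZIP_DEFLATED
        return info

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(_member("metadata.json"), json.dumps(meta, indent=1))
        for table in _TABLES:
            zf.writestr(_member(f"{table}.csv"), _frame_to_csv(getattr(checklist, table)))
    return path


def read_archive(path: str | Path) -> TaxonList:
    """Restore a checklist from an archive; the result must validate."""
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            members = set(zf.namelist())
            if "metadata.json" not in members:
                raise ArchiveError(f"{path}: missing metadata.json")
            meta = json.loads(zf.read("metadata.json"))
            if meta.get("format_version") != ARCHIVE_VERSION:
                raise ArchiveError(f"{path}: unsupported format version {meta.get('format_version')}")
            frames = {}
            for table in _TABLES:
                member = f"{table}.csv"
                if member not in members:
                    raise ArchiveError(f"{path}: missing member {member}")
                spec = meta["tables"][table]
                frames[table] = _restore_frame(zf.read(member).decode("utf-8"), spec["columns"], spec["dtypes"])
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"{path}: not a readable archive ({exc})") from None
    out = TaxonList(ranks=meta["ranks"], **frames)
    problems = validate(out)
    if problems:
        raise ArchiveError(f"{path}: archive content is invalid: " + "; ".join(v.message for v in problems))
    return out


# ---------------------------------------------------------------------------
# Date-stamped backups
# ---------------------------------------------------------------------------

_BACKUP_RE = re.compile(r"^(?P<base>.+)_(?P<date>\d{4}-\d{2}-\d{2})(?:_(?P<suffix>\d+))?\.zip$")


def backup(checklist: TaxonList, base_path: str | Path, stamp: _dt.date | None = None) -> Path:
    """Write a date-stamped archive snapshot next to ``base_path``.

    The first backup of a day is ``<base>_<YYYY-MM-DD>.zip``; further
    same-day backups get ``_1``, ``_2``, … suffixes.  ``stamp`` overrides
    the date for reproducible tests.
    """
    base_path = Path(base_path)
    directory = base_path.parent if str(base_path.parent) else Path(".")
    directory.mkdir(parents=True, exist_ok=True)
    stamp = stamp or _dt.date.today()
    day = stamp.isoformat()
    candidate = directory / f"{base_path.name}_{day}.zip"
    k = 0
    while candidate.exists():
        k += 1
        candidate = directory / f"{base_path.name}_{day}_{k}.zip"
    return write_archive(checklist, candidate)


def latest_backup(directory: str | Path, base_name: str) -> Path:
    """The newest backup of ``base_name``: max date, then max suffix."""
    directory = Path(directory)
    best: tuple[str, int] | None = None
    best_path: Path | None = None
    for entry in directory.glob(f"{base_name}_*.zip"):
        match = _BACKUP_RE.match(entry.name)
        if not match or match.group("base") != base_name:
            continue
        key = (match.group("date"), int(match.group("suffix") or 0))
        if best is None or key > best:
            best, best_path = key, entry
    if best_path is None:
        raise BackupError(f"no backup of '{base_name}' found in {directory}")
    return best_path


def load_last(directory: str | Path, base_name: str) -> TaxonList:
    """Restore the newest backup of ``base_name`` in ``directory``."""
    return read_archive(latest_backup(directory, base_name))


__all__ = [
    "FlatImportError",
    "TurbovegImportError",
    "ArchiveError",
    "BackupError",
    "DEFAULT_TURBOVEG_MAP",
    "ARCHIVE_VERSION",
    "read_flat_table",
    "read_turboveg",
    "write_archive",
    "read_archive",
    "backup",
    "latest_backup",
    "load_last",
]
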