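# Methods

## The data model

A checklist is modelled as four column-oriented tables held in one
`TaxonList` object, mirroring how relational databases store taxonomy:

* `names(usage_id, concept_id, full_name, author, …)` — every application of
  a name.  Identity of a name is its *combination*: the normalized
  (whitespace-collapsed, case-sensitive) pair (full_name, author).  Case is
  deliberately significant because letter case is meaningful in botanical
  combinations; authority abbreviations are **not** canonicalized ("L." and
  "Linnaeus" are different strings), which is out of scope here.
* `concepts(concept_id, accepted_name_id, parent_id, rank, view_id, …)` —
  the taxon concepts.  `accepted_name_id` must point at a name row that
  itself points back at the concept; this double link is what separates
  "a name" from "the taxon currently designated by that name".
* `views(view_id, author, year, title, …)` — bibliographic references fixing
  a concept's circumscription.  Unreferenced views are permitted.
* `traits(concept_id, <one column per variable>)` — at most one record per
  concept; coverage of all concepts is not required.

All tables accept user-defined extra columns.  Id columns are nullable
pandas `Int64`; in text columns the empty string (never NA) denotes an
absent value — one convention for the whole package, chosen so CSV archives
round-trip without an NA-vs-empty ambiguity.

Hierarchy is optional.  A `parent_id` pointer plus a *rank ladder* — an
ordered list of rank labels, lowest first, supplied by the user — give the
list a taxonomy; a concept may be unranked, in which case it is exempt from
rank-order checking but not from parent-existence checking.

## Validity rules

`validate()` checks ten closed rules and returns every violation (never an
exception), ordered by (rule, first offending id) so reports are diffable:

V1 duplicated `usage_id` · V2 duplicated `concept_id` · V3 duplicated
combination · V4 name pointing at a missing concept · V5 trait record
pointing at a missing concept · V6 incoherent accepted-name pointer ·
V7 missing parent · V8 rank not on the ladder · V9 child's rank not
*strictly* below its parent's (checked only when both ranks are present and
known — "at least one level lower" means equality also violates) ·
V10 missing view.

This is a closed rule set by design: anything it does not flag is considered
valid.

`clean()` restores referential soundness by iterating to a fixed point:
orphaned names and trait records are dropped, parent and view pointers to
missing rows are nulled, concepts with no surviving name are removed, and a
broken accepted-name pointer on a concept that still has names is re-pointed
to the concept's lowest `usage_id`.  That last repair is a design choice:
dropping such a concept would discard recoverable information, while any
other target would be arbitrary; the lowest usage id is deterministic and,
for lists built through this package's editors, is the original accepted
name.  `clean()` deliberately does **not** resolve duplicated ids or
combinations (V1–V3) or rank-order breaches (V9): choosing which duplicate
survives or which rank is wrong is an editorial decision, so those stay
reported.

## Editing contract

Every editor is copy-or-raise: the input object is never mutated, and a
rejected edit raises before any output exists.  Preconditions encode
curatorial practice — a new accepted name must already be a synonym of its
concept; only synonyms may move between concepts (the moved name keeps its
usage id, spelling and authority); parent assignment checks both rank order
and, explicitly, acyclicity, because unranked concepts could otherwise form
loops that rank checking never sees.  Promoting the current accepted name
again is an error rather than a no-op, to surface caller confusion.
Inserting a rank into the ladder can never invalidate existing pairs, since
relative order of existing labels is preserved — the validator is still
re-run in tests to confirm it.

## Querying

`subset()` takes a structured query — (table, column, operator, value) with
operators `equals` (case-sensitive), `contains` (case-insensitive,
substring), `less_than`, `greater_than`, `in_set` — instead of arbitrary
host-language expressions, trading power for portability to the command
line and for testability; conjunctions are compositions of `subset` calls.
A matched name or trait record selects its concept.  `keep_children` closes
the selection over all descendants, `keep_parents` over the **full**
ancestor chain (not just direct parents), so selecting one species can
display its complete lineage.  The output keeps all names, traits and
referenced views of the selected concepts plus the entire rank ladder, and
is always valid; with `keep_parents=False` a surviving child's parent
pointer may leave the selection, in which case it is nulled.

The integer-id lookup in `summary_concept` is exact; the text lookup is a
case-insensitive substring scan over every usage name, mirroring how
curators search interactively.  The count of "traits" in `summary_list` is
the number of trait *variables* (columns), not of concepts carrying
records — the other reading of that ambiguous quantity is recoverable as
`len(list.traits)`.

## Import and persistence

**Flat synonymy tables** need one accepted row per concept id; usage ids
are unique where given and auto-assigned (max+1) otherwise; extra columns
become trait variables populated from each concept's accepted row.  A
`rank` column requires an explicit ladder argument, because a flat table
does not encode rank order.  All import failures name 1-based row numbers.

**Turboveg species lists** are flat DBF tables in which `VALID_NR` points a
synonym at its accepted row.  Default column mapping
`{SPECIES_NR, ABBREVIAT, AUTHOR, SYNONYM, VALID_NR}` is overridable because
installations vary; text encoding defaults to latin-1 since DBF headers are
unreliable.  When the synonym flag and the pointer disagree, the pointer
wins (it carries the structure) and the conflict is logged.  Synonyms whose
pointer resolves to no accepted row are dropped with a warning, or rejected
under `strict=True`.  The dialect supports neither hierarchy nor taxon
views, so the importer creates none; attribute-table (`ecodbase`) rows keyed
by an accepted `SPECIES_NR` become trait records, others are logged and
ignored.  The DBF codec itself is a minimal dBASE-III reader/writer
(character, numeric, logical fields) — exactly the subset the dialect uses.

**Archives** are zips of four CSV tables plus `metadata.json` (format
version, rank ladder, column order, per-column dtypes).  Round trips are
required to be value-exact, not byte-exact, but member timestamps are fixed
so identical lists do produce byte-identical archives.  Reading validates
the content and refuses invalid archives; writing refuses invalid lists.

**Backups** are archives named `<base>_<YYYY-MM-DD>.zip`, with `_1`, `_2`, …
suffixes for further same-day snapshots.  `load_last` picks max date, then
max suffix (no suffix sorts below `_1`), by parsing filenames — file mtimes
are ignored for portability.  The date stamp can be injected for
reproducible tests.

## Synthetic data

`generate_fixture(FixtureSpec(...))` builds a seed-deterministic checklist:
species under genera under families, names assembled from syllable tables so
they are pronounceable, unique and obviously not authoritative taxonomy.
Defaults — 2 families, 4 genera, 20 species, synonym probability 0.3 per
species, one three-state `life_form` trait, one view — give a small list
with every structural feature present (hierarchy, synonymy, traits, views);
synonym occurrence is Bernoulli per species, so the synonym total over many
seeds is binomial, which the tests check.  The generator raises when the
requested counts exhaust the unique-name space.

What it emulates: the relational shape, synonymy density and three-level
hierarchy of a curated flora.  What it does not: real nomenclature,
homonyms, authority variants, infraspecific ranks, multiple conflicting
views per concept, or misspellings.  Passing tests therefore demonstrate
structural and algorithmic correctness, not robustness to the textual noise
of real-world lists.

`easplist_mini()` is a hand-coded three-concept miniature (Cyperaceae →
*Cyperus* → *C. papyrus* L., concept id 206, synonym *Papyrus antiquorum*
Willd., one synthetic view).  Id 206 is fixed because the worked examples
refer to it; the other ids are arbitrary.

## Verification set-up and problem sizes

The acceptance campaigns run at desk scale, chosen to finish in minutes on
one core while still exercising every code path: 100 random checklists per
validity rule (1,000 injections), 1,000 random edits, 200 archive round
trips with sizes from a handful up to ~1,000 concepts, 20 Turboveg
partition-recovery round trips, exhaustive substring queries (every
length ≥ 4 substring of every name, ~19,000 closure checks over three
26-concept lists) against an independent brute-force reachability oracle,
and 500 clean() recoveries.  Defect injection breaks exactly one rule at a
time; the validator must report exactly that rule, which guards against both
missed and spurious detections.

## Known limitations

* No nomenclatural parsing: names are strings; genus/epithet structure is
  not interpreted.
* No fuzzy matching or spell-checking; duplicate detection is exact after
  whitespace normalization.
* Concept merging/splitting and undo history beyond backups are not
  provided.
* Turboveg files are read, never written in Turboveg's own directory layout
  (the fixture writer emits the two-table dialect only).
* Mixed-type user columns in the tables round-trip through archives as
  text.
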