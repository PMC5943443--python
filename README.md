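# taxatables

Floristic checklists — the species lists behind vegetation-plot databases —
are usually exchanged as flat tables in which a name, a taxon, and the
opinion that circumscribes the taxon are collapsed into one row.  That makes
synonymy untraceable: when a historical record says *Papyrus antiquorum*
Willd. and today's flora says *Cyperus papyrus* L., a flat list can only
overwrite one with the other.

`taxatables` keeps the distinction explicit.  A checklist is four linked
tables:

| table      | one row is…                                                  |
|------------|--------------------------------------------------------------|
| `names`    | a **taxon usage name**: combination + authority, accepted or synonym |
| `concepts` | a **taxon concept**: pointer to its accepted name, optional parent, rank and view |
| `views`    | a **taxon view**: the reference fixing a concept's circumscription |
| `traits`   | per-concept attributes (life form, conservation status, …)   |

plus a user-defined **rank ladder** (e.g. species < genus < family) against
which parent–child links are checked.  Every concept has exactly one
accepted name; a name belongs to exactly one concept; moving a name between
concepts preserves its identity, including the authority.

On top of the model the package provides:

* a **validity engine** — ten closed rules (duplicated ids, duplicated
  combinations, orphaned names/traits/parents/views, broken accepted-name
  pointers, unknown ranks, rank-order inversions), reported deterministically,
  plus `clean()` to repair the referential defects;
* **safe editing** — `add_concept`, `add_synonym`, `set_accepted_name`,
  `change_concept`, `add_parent`, `add_level`, traits and views; every
  accepted edit provably yields a valid list, every rejected edit leaves the
  input untouched;
* **hierarchy-aware querying** — structured `subset()` queries with
  `keep_children` / `keep_parents` closure, ancestor/descendant traversal,
  accepted-name and synonym lookup;
* **I/O** — flat synonymy CSVs, Turboveg species lists (DBF, with the
  `ecodbase` attribute table), a native zip-of-CSV archive with value-exact
  round trips, and date-stamped backups with `load_last()` restore;
* a **fixture generator** producing seed-deterministic, always-valid
  synthetic checklists for testing.

For who: curators of floristic and vegetation-plot databases who need to
clean, query and version species lists reproducibly, and developers who
need realistic checklist structures in tests.

## Worked example

The bundled miniature checklist (`easplist_mini()`) holds the lineage
family Cyperaceae → genus *Cyperus* → species *Cyperus papyrus* L.
(concept id 206) with one synonym and one taxon view:

```python
from taxatables import (easplist_mini, set_traits, summarize_concept,
                        subset, SubsetQuery, summary_list, validate)

chk = easplist_mini()
chk = set_traits(chk, 206, {"life_form": "reed_plant"})

summary_list(chk)
# SummaryStats(n_names=4, n_concepts=3, n_trait_variables=1, n_views=1,
#              has_parent_child=True, rank_labels=('species', 'genus', 'family'))

s = summarize_concept(chk, 206)
s.accepted_name   # ('Cyperus papyrus', 'L.')
s.rank            # 'species'
s.parent          # ('Cyperus', 'L.')
s.synonyms        # (('Papyrus antiquorum', 'Willd.'),)
s.view            # 'Editorial Committee (2010) Checklist of eastern African sedges (synthetic reference)'

lineage = subset(chk, SubsetQuery("names", "full_name", "contains", "papyrus"),
                 keep_parents=True)
sorted(lineage.concept_ids())   # [1, 2, 206]  — papyrus plus genus and family
validate(lineage)               # []           — subsets are always valid
```

The numbers read as: 4 usage names covering 3 taxon concepts, one trait
variable, one reference; the substring query matches the papyrus concept and
`keep_parents` pulls in its full lineage (3 concepts), which still passes
all validity rules.

The same flow from the shell:

```console
$ taxatables fixtures mini mini.zip
$ taxatables summary mini.zip
names	4
concepts	3
trait_variables	0
views	1
parent_child	true
ranks	species,genus,family
$ taxatables subset mini.zip papyrus.zip --table names --column full_name \
      --op contains --value papyrus --keep-parents
papyrus.zip	3 concepts	4 names
$ taxatables validate papyrus.zip && echo OK
OK
```

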