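# Methods

## The data model

The store is a schema-free key-value model with a fixed object skeleton: a
**project** owns **actions**, **entities**, **templates** and project-level
**modules**; actions and entities own modules and **messages**; actions own
a **data registry**. Metadata payloads (module contents) are arbitrary
string-keyed nested mappings — the semi-structured compromise between a
rigid relational schema (which cannot follow an evolving experiment) and a
free-for-all (which cannot be queried or shared). Templates provide the
implicit schema: a module created from a template is a deep-copy snapshot,
never a link, so the recorded state of equipment or a protocol at the time
of an action can never be mutated retroactively by editing the template.
Conversely there is deliberately *no* referential integrity between actions
and entities: a dangling entity reference is kept verbatim. This trades
validation for flexibility and leaves provenance discipline to the user and
to version control.

## Identifiers and attributes

Identifiers double as file and directory names, so the accepted grammar is
the portable-filename subset `[A-Za-z0-9._-]{1,128}` excluding `.` and
`..`. They are case-sensitive and unique per collection (an action and an
entity may share a name; two actions may not).

Common attributes are `tags` and `users` (sets of non-empty strings, stored
as sorted YAML lists so files are deterministic but compared unordered),
`location` and `type` (free text or absent — `type` is not constrained to a
vocabulary, since typical values like "recording" or "surgery" are
conventions, not a closed set), `datetime` (timezone-naive ISO-8601 at up
to microsecond resolution; timezone-aware input is converted to UTC and the
offset dropped — the storage format takes no position on zones), and, on
actions only, `entities` (a list of syntactically valid identifiers, not
checked for existence).

## Storage

The default backend maps records onto a directory tree of YAML files
(`actions/<id>/attributes.yaml`, `<owner>/modules/<name>.yaml`, …). Choices
that were genuinely open:

- **Project marker.** `expipe.yaml` at the root (with a format-version
  field) distinguishes a project from an arbitrary directory; a directory
  is a project iff this file exists and parses.
- **Deterministic serialization.** Block-style YAML, insertion-ordered
  keys, 2-space indent, UTF-8, LF, trailing newline, no anchors. Equal
  contents always produce byte-identical files, so re-saving unchanged
  metadata never dirties a Git/GIN working copy, and the
  set-attribute-to-its-current-value operation is a byte-wise no-op.
- **Safe subset only.** Reading uses the safe YAML loader — hand-edited
  files are expected and must never be able to execute code.
- **Quantities.** A mapping with exactly the keys `value` and `unit` is a
  quantity leaf; any other mapping is plain nesting. `Quantity` subclasses
  `dict`, so deserialized quantities compare equal to the plain mapping and
  round-trip equality holds without a parallel type system.
- **Atomic writes.** Temp-file-and-rename; a crash cannot leave a
  half-written metadata file in a version-controlled tree.
- **Data registry placement.** Stored under the reserved `data` key inside
  the owning action's `attributes.yaml` (one fewer file; the registry is an
  action property). Relative locators resolve under `actions/<id>/data/`;
  locators that would escape that folder via `..` are rejected at
  registration so the data folder remains trackable as a unit; absolute
  paths and URI-like strings are stored and returned verbatim.
- **Messages.** Files named by their normalized timestamp
  (`YYYYMMDDTHHMMSS.ffffff.yaml`, `-1`/`-2`… on collision): sortable,
  unique, content-free names, and lexicographic order equals chronological
  order. Messages are immutable; editing is delete-and-re-add, matching
  lab-notebook semantics.
- **Tolerance.** Files and directories violating the identifier grammar
  (e.g. `.git`, editor droppings) are ignored with a warning, never errors,
  so the tree coexists with version-control metadata.
- **Project-level `attributes.yaml`.** Created empty for uniformity with
  actions and entities.

All persistence flows through a small abstract storage contract
(`init/read/write/delete/list/exists` keyed by kind, owner and id). An
in-memory implementation of the same contract serves as the conformance
reference: property tests replay random operation sequences against both
backends and require identical observable outcomes (values or error
classes). The filesystem tree contains no absolute paths and is
relocatable.

The API layer does **no in-memory caching**: every attribute read goes back
to the store. At desk scale (hundreds to a few thousand actions) this costs
nothing measurable and guarantees correctness with hand-edited files and
multiple handles on one root. Deletion is provided (it does not cascade to
references, consistent with relaxed integrity); iteration order of every
collection is lexicographic for reproducible listings and exports.

## Exploration and export

`build_index` flattens each action's common attributes into one row
(multi-valued fields `;`-joined in sorted order; `;` was chosen as a
comma-free join character, which assumes tags/users/ids themselves contain
no `;` — identifiers cannot, and tag conventions should not). Module
*contents* are not flattened — only counts appear; deep metadata queries
are custom-script territory by design. A corrupt metadata file yields a row
with the parse error in a trailing `note` column instead of aborting the
index. `QuerySpec` criteria combine conjunctively; `*_any` fields use
set-intersection, `tags_all` set-inclusion, datetime bounds are inclusive
and actions without a datetime never match a bounded query; an inverted
interval is an error, not an empty result. CSV export is RFC-4180 with
header, UTF-8, LF; export → parse → export is a byte-level fixed point.

## The synthetic-project generator

`generate_project(FixtureSpec(...))` builds randomized project trees
through the public API only, returning a ground-truth manifest that doubles
as the oracle for every property test (query results, counts, listings).
Defaults model a small rodent-electrophysiology project: 4 subjects, 12
actions, 3 templates, tag/user pools of realistic size, ~50–70 %
probabilities for tags/modules/messages/data, module nesting depth ≤ 3.
Action and message timestamps are drawn from a fixed two-year window
(2019–2020) so date-range queries have non-degenerate selectivity; the wall
clock is never consulted, and a single `random.Random(seed)` drives
everything, so a given spec yields a byte-identical tree. Data payloads are
single-line placeholder text files — the generator emulates the metadata
structure of real projects, not their payloads, recording hardware
idiosyncrasies, or concurrent multi-user access; passing tests therefore
validate the metadata machinery, not payload handling.

## Verification sizes

The test suite and `scripts/acceptance.py` run the headline checks at these
sizes (chosen to give the randomized properties real coverage while keeping
a laptop run in seconds): 100 template/module snapshot-isolation trials;
1000 serialization round-trips plus hypothesis-generated cases; 20
generated projects of 30 actions with 240 random queries checked against an
independent brute-force manifest scan; 500 backend-conformance operation
sequences of 12 operations each; CSV contract on all 20 generated projects.

## Known limitations

- No file locking or concurrent multi-writer safety; last write wins.
- No schema validation of module contents against community terminologies.
- The `;` join in the index is lossy for values containing `;`.
- Only a global (per-user) CLI configuration scope exists.
- Cloud/NoSQL-service backends are out of scope; the storage contract and
  the in-memory reference exist so one could be conformance-tested in.
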