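# Methods

## The data model

`eventstore` separates what a recording *is* from what can be *searched*
about it. The payload — an EEG run, or any byte sequence — is archived
verbatim as a blob attached to one row of DATASETS and always retrieved
whole; there are no partial blob reads. Everything queryable is exploded
into dedicated tables at store time: EVENTS and EVENT_TYPES for time
markers, ATTRIBUTES for path-anchored values lifted out of the container,
TAGS for free annotations, the value/stream tables for auxiliary data, and
TRANSFORMS for provenance strings. Nineteen tables make up the schema
(bundled as `src/eventstore/schema.sql`, idempotent DDL); five of them
(COMMENTS, CONTACTS, DEVICES, ELEMENTS, SUBJECTS) are deliberately minimal
— identity, entity linkage, description — and reachable only through the
generic `put_rows`/`get_rows` interface, because nothing in the model
constrains them further.

Identity is by random version-4 UUIDs (128 bits, stored as lowercase
hyphenated strings) so records from independent databases can be merged
without key conflicts. A dataset's logical identity is the triple
(namespace, name, version), unique database-wide; storing an existing
(namespace, name) either fails (`is_unique=True`, the default) or takes
the next consecutive version. Name matching for versioning is
case-sensitive exact.

Tags, attributes, and data maps reference entities as (uuid, table-name)
pairs, so *any* row — a dataset, an event, an event type, a stream item, a
collection — can be annotated. Collections are stored as membership rows
plus one root row with a NULL entity, so that an empty collection still
exists and is itself taggable.

### Events, certainty, and event types

An event has a start and end time in **seconds from the start of its
dataset** (instantaneous markers have start = end) and a certainty in
[0, 1]. Certainty is a first-class column because events increasingly come
from detection algorithms with a confidence attached; hardware markers get
exactly 1.0, and any value outside [0, 1] is rejected at validation. Event
types live in their own table so that a label such as `target_onset` maps
to one UUID across a whole collection: `store_dataset` accepts the type
UUIDs returned by previous stores and reuses a type whenever its label
matches, creating new rows only for unseen labels.

### Modalities

A modality is the procedure that explodes a container:

* **SIMPLE** archives bytes and explodes nothing (annotations can still be
  added later);
* **EEG** expects an EEGLAB-style structure. Latencies use the container's
  1-based sample convention, so an event at latency *L* with sampling rate
  *fs* occurs at (L − 1)/fs seconds — the first sample is time zero. EEG
  events are instantaneous with certainty 1. Channel-location fields
  become dataset attributes at `/chanlocs/<index>/<field>` (1-based
  index); every event field other than `type` and `latency` is treated as
  a modifier and becomes an event attribute at `/event/<field>`, numeric
  values in the numeric column and everything else stringified. The
  original-event (`urevent`) list is stored as EVENTS rows flagged by a
  `/urevent` = 1 attribute rather than a dedicated table; event and
  urevent lists are stored independently, not cross-linked.
* **GENERIC** expects element/event/feature/metadata sections; events
  carry explicit start/end/certainty (certainty defaults to 1.0), element
  records go to ELEMENTS, and feature/metadata records become dataset
  attributes at `/<section>/<index>/<key>`.

Handlers are code and cannot live in the database: `register_modality`
persists the MODALITIES row and wires the handler into the registering
connection's dispatch table; other connections must register the handler
again before storing datasets of that modality (retrieval never needs it).

Payload serialization goes through a codec keyed by modality: EEG
containers are MAT-files (EEGLAB field layout), GENERIC containers
canonical JSON, SIMPLE raw bytes. The MAT writer pins the format's 116-byte
text header (which normally embeds a wall-clock timestamp) so that equal
containers serialize to identical bytes.

## Query semantics

`get_rows` filters one table by the conjunction of column qualifications,
tag groups, and attribute groups. Design choices that the model left open:

* **Regex dialect and anchoring.** Patterns use Python's `re` syntax and
  are applied with `re.match`, i.e. anchored at the start and unanchored at
  the end: `eeg.*` (or just `eeg`) matches names *starting with* `eeg`.
  This makes the common prefix query natural for hierarchical tags
  (`/Context/.*`).
* **UUID columns** accept only exact values or lists, never patterns;
  numeric columns match by exact equality (range queries are out of
  scope).
* **Attribute groups** mirror tag groups: a member matches an attribute if
  it matches the attribute's *path* or its *stringified value*
  (`str(float(x))` for doubles, the string itself otherwise).
* **Stable order.** Results are sorted by ascending primary-key UUID. The
  order is arbitrary but total and deterministic, which makes `limit k` a
  prefix of `limit k+1` and gives cursors disjoint, exhaustive batches via
  keyset pagination (`pk > last_key`), with no server-side result
  materialization.
* **Limit 0** returns the empty row template (the same structure
  `get_template` gives), `ALL`/`inf` returns everything.
* Qualifications are compiled to SQL (`IN` lists, `EXISTS` subqueries, and
  two registered SQL functions for regex and attribute matching), so
  filtering happens in the engine; the pure-Python matching functions
  (`match_strings`, `match_tag_groups`) define the reference semantics and
  are what the SQL functions call. The test suite checks the compiled path
  against a brute-force evaluator written independently of both.

Payload (BLOB-declared) columns are invisible to the query surface —
templates, `get_rows`, and `put_rows` never see them — so queries return
metadata only and blobs move exclusively through
`retrieve_dataset`/`retrieve_datadef`.

## Auxiliary data

The five formats split along two axes: numeric vs XML, and single value vs
time-stamped stream, plus EXTERNAL for opaque blobs. Streams store one row
per column. A uniform stream at `fs` Hz reconstructs timestamps as
`i / fs` (exact in double precision, `i` from 0); a non-uniform stream
stores explicit strictly-increasing timestamps and records sampling rate
−1. Timestamps are relative to the start of the data itself, not of any
dataset it may later be mapped to. Numeric stream columns are packed as
little-endian float64, giving element-exact round trips on the embedded
backend, which has no native array type. Epoched data can be stored as
columns with sampling rate 1, yielding timestamps 0, 1, 2, …

## Provenance

`normalize_transform` canonicalizes a command template: placeholder words
are replaced by UUIDs, then whitespace runs collapse to single blanks and
blanks adjacent to the delimiters `( ) , [ ] { }` are removed, iterated to
a fixed point so the function is idempotent. Lookups are exact-string:
fuzzy or expression-parsing lookup is out of scope. One produced entity
holds one transform row (its UUID is the primary key); the same string may
be recorded for several produced entities and lookups return them all.

## Transactions and backends

Every public operation is one transaction: a re-entrant context manager
opens `BEGIN IMMEDIATE` at the outermost level and commits or rolls back
as a whole, so a store that fails halfway through its explosion leaves
every table untouched. The test suite verifies this by injecting faults at
the single statement choke point every write goes through.

The implemented backend is embedded SQLite — a single file per database,
zero-install, persistent across processes, with multiple simultaneous
connections mediated by the engine's locking. `DatabaseConfig` carries the
host/credential/backend fields of a client-server deployment as part of
the interface, but `backend="client-server"` raises
`UnsupportedBackendError` in this build; the data model is independent of
that choice. `delete_database` refuses to run while the calling process
holds an open connection (fail-fast over silently invalidating handles);
closing a handle twice is an error, like every other operation on a closed
handle.

## Synthetic containers

The generator emulates the *structure* of curated EEG collections: the
defaults (32 channels, 30 000 frames at 128 Hz, 154 events over a 2-type
vocabulary) mirror a typical archived EEGLAB dataset. Latencies are
uniform over the recording, every vocabulary type is used at least once
(so the unique-type count is exact by construction), each event carries a
configurable number of numeric modifier fields, and generic containers mix
instantaneous and extended events with certainties either all 1.0 or
uniform on [0, 1]. Randomness uses numpy's PCG64 with explicit seeding, so
a (spec, seed) pair reproduces the identical container anywhere. What the
generator does **not** emulate: realistic EEG spectra, artifacts, channel
correlation, or meaningful event semantics — passing tests demonstrate
structural and transactional fidelity of the store, not signal-processing
validity on real recordings.

Unit tests run on deliberately small problem sizes (hundreds of frames,
tens of events); the acceptance script uses 100 random blobs, 20
containers, 500 randomized queries against a ~60-dataset database, and a
ten-dataset reuse loop — sizes chosen so the full suite replays in
seconds while still exercising every path.

## Known limitations

* Modality handlers do not persist; each connection must register
  user-defined handlers before storing datasets of that modality.
* No HED-schema validation of tag strings: tags are opaque paths and any
  hierarchy semantics live in the queries users write.
* No replication, user management, permissions, or streamed blob access.
* The open-connection guard on `delete_database` sees only the current
  process.
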