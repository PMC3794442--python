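# eventstore

A relational store for **event-rich multichannel time series** — EEG and
similar physiological or behavioral recordings in which the signal itself is
only half the story, and the scientific value lives in the thousands of
annotated time markers layered on top of it.

`eventstore` archives each recording (a *dataset*) whole, as an opaque
binary blob that always round-trips byte-exactly, while **exploding** its
searchable structure into relational tables:

* **events** — time markers with a start time and end time in seconds from
  the start of the dataset, a *certainty* in [0, 1] (hardware-inserted
  markers have certainty 1; algorithmically detected events may not), and a
  **event type**: a UUID-identified label shared across datasets so "the
  same" event is identifiable when mining a whole collection;
* **tags** — free-floating strings, plain (`EyeTrack`) or hierarchical
  paths (`/Context/Indoors/Simulator/Driving`), attachable to any entity;
* **attributes** — typed values (double or string) anchored at a structure
  path such as `/event/target_dist` or `/chanlocs/3/X`;
* **auxiliary data definitions** in five formats (numeric values, numeric
  streams, XML values, XML streams, external blobs), associated with any
  entities through many-to-many *data maps*, with uniform streams carrying
  timestamps `i / fs` reconstructed from the sampling rate;
* **transforms** — normalized command strings mapped to the dataset they
  produced, giving a provenance cache: look a string up before recomputing,
  and regex-search for an input UUID to find everything derived from it.

How a container is exploded is decided by its **modality**: `SIMPLE`
(archive only), `EEG` (an EEGLAB-style structure: `event`, `urevent`,
`chanlocs`), `GENERIC` (element/event/feature/metadata sections with
explicit event times and certainties), or a user-registered handler.

Searching is **SQL-free**: a `QuerySpec` combines column qualifications
(direct value, list of choices, or start-anchored regular expressions) with
tag groups and attribute groups — every group must match (AND), and within
a group one member suffices (OR). Results come back in a stable order and
can be paged through named keyset cursors. Every public operation runs as
one atomic transaction on an embedded single-file SQL database.

## Worked example

```python
from pathlib import Path
import eventstore as es

cfg = es.DatabaseConfig(name="dbdemo", base_dir=Path("."))
es.create_database(cfg)
conn = es.connect(cfg)

# a synthetic 32-channel recording: 154 events over a 2-type vocabulary
spec = es.SyntheticSpec(n_channels=32, n_frames=30_000, srate=128.0,
                        n_events=154, n_event_types=2, seed=7)
eeg, truth = es.generate_eeg(spec)

uuid, type_uuids = es.store_dataset(
    conn, es.DatasetRecord(name="eeg_data", data=eeg),
    es.StoreOptions(tags=["EyeTrack", "VisualTarget", "AudioLeft"]))
print("event types created:", len(type_uuids))

events = es.get_rows(conn, es.QuerySpec(
    table="events", column_quals={"event_dataset_uuid": uuid}))
print("events exploded:", len(events))
print("first event time (s):", min(r["event_start_time"] for r in events))

hits = es.get_rows(conn, es.QuerySpec(
    table="datasets",
    tag_groups=["EyeTrack", ["VisualTarget", "Audio.*"]], regexp=True))
print("datasets matching tag query:", len(hits))

s = es.normalize_transform("pop_eegfilt(EEG, 1.0, 0, [], 0)", {"EEG": uuid})
es.store_transform(conn, uuid, s)
print("cache hit:", es.lookup_transform(conn, s)[0].transform_uuid == uuid)
conn.close()
```

Output:

```
event types created: 2
events exploded: 308
first event time (s): 1.953125
datasets matching tag query: 1
cache hit: True
```

The 154 generated events explode into 308 EVENTS rows because the
container's original-event (`urevent`) list is stored alongside, flagged by
a `/urevent` attribute. Both event types were created fresh (the type map
was empty); re-storing further datasets with
`StoreOptions(event_type_uuids=type_uuids)` reuses them instead of
duplicating the vocabulary. The tag query demands an `EyeTrack` tag AND
(`VisualTarget` OR any tag starting with `Audio`), which the dataset
satisfies.

The same operations are available from the shell:

```bash
eventstore --dir . createdb dbdemo
eventstore --dir . synth --channels 32 --frames 30000 --events 154 --types 2 -o data/
eventstore --dir . store dbdemo data/eeg_data_ch1.mat --name eeg_data --tag EyeTrack
eventstore --dir . query dbdemo datasets --tags EyeTrack --limit 10
```

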