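-- Relational schema for the event store.  Idempotent: every statement uses
-- IF NOT EXISTS so the script can be re-applied to an existing database.
--
-- Conventions:
--   * every table's primary key is a 128-bit UUID stored as a lowercase
--     hyphenated string in the column <singular>_uuid;
--   * columns declared BLOB hold opaque payloads and are invisible to the
--     structured query layer (templates / get_rows / put_rows);
--   * (entity_uuid, entity_class) pairs reference a row of any table, where
--     entity_class is the lowercase table name.

CREATE TABLE IF NOT EXISTS datasets (
    dataset_uuid            TEXT PRIMARY KEY,
    dataset_session_uuid    TEXT,
    dataset_namespace       TEXT NOT NULL DEFAULT 'mobbed',
    dataset_name            TEXT NOT NULL,
    dataset_version         INTEGER NOT NULL CHECK (dataset_version >= 1),
    dataset_contact_uuid    TEXT,
    dataset_creation_date   TEXT,
    dataset_description     TEXT,
    dataset_parent_uuid     TEXT,
    dataset_modality_uuid   TEXT,
    dataset_oid             INTEGER,
    data                    BLOB,
    UNIQUE (dataset_namespace, dataset_name, dataset_version)
);

CREATE TABLE IF NOT EXISTS events (
    event_uuid          TEXT PRIMARY KEY,
    event_dataset_uuid  TEXT NOT NULL,
    event_type_uuid     TEXT NOT NULL,
    event_start_time    REAL NOT NULL CHECK (event_start_time >= 0),
    event_end_time      REAL NOT NULL CHECK (event_end_time >= event_start_time),
    event_certainty     REAL NOT NULL CHECK (event_certainty >= 0 AND event_certainty <= 1),
    event_position      INTEGER
);

CREATE TABLE IF NOT EXISTS event_types (
    event_type_uuid         TEXT PRIMARY KEY,
    event_type              TEXT NOT NULL,
    event_type_description  TEXT
);

CREATE TABLE IF NOT EXISTS tags (
    tag_uuid         TEXT PRIMARY KEY,
    tag_name         TEXT NOT NULL CHECK (tag_name <> ''),
    tag_entity_uuid  TEXT NOT NULL,
    tag_entity_class TEXT NOT NULL,
    UNIQUE (tag_name, tag_entity_uuid)
);

CREATE TABLE IF NOT EXISTS attributes (
    attribute_uuid          TEXT PRIMARY KEY,
    attribute_entity_uuid   TEXT NOT NULL,
    attribute_entity_class  TEXT NOT NULL,
    attribute_path          TEXT NOT NULL,
    attribute_numeric_value REAL,
    attribute_value         TEXT,
    CHECK ((attribute_numeric_value IS NULL) <> (attribute_value IS NULL))
);

CREATE TABLE IF NOT EXISTS datadefs (
    datadef_uuid          TEXT PRIMARY KEY,
    datadef_format        TEXT NOT NULL CHECK (datadef_format IN
        ('NUMERIC_VALUE', 'NUMERIC_STREAM', 'XML_VALUE', 'XML_STREAM', 'EXTERNAL')),
    datadef_sampling_rate REAL NOT NULL DEFAULT -1,
    datadef_description   TEXT,
    datadef_oid           INTEGER,
    datadef_data          BLOB
);

CREATE TABLE IF NOT EXISTS datamaps (
    datamap_uuid          TEXT PRIMARY KEY,
    datamap_datadef_uuid  TEXT NOT NULL,
    datamap_entity_uuid   TEXT NOT NULL,
    datamap_entity_class  TEXT NOT NULL,
    datamap_path          TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS numeric_values (
    numeric_value_uuid         TEXT PRIMARY KEY,
    numeric_value_datadef_uuid TEXT NOT NULL,
    numeric_value_position     INTEGER NOT NULL,
    numeric_value              REAL NOT NULL
);

CREATE TABLE IF NOT EXISTS numeric_streams (
    numeric_stream_uuid         TEXT PRIMARY KEY,
    numeric_stream_datadef_uuid TEXT NOT NULL,
    numeric_stream_position     INTEGER NOT NULL,
    numeric_stream_time         REAL NOT NULL,
    numeric_stream_data         BLOB NOT NULL
);

CREATE TABLE IF NOT EXISTS xml_values (
    xml_value_uuid         TEXT PRIMARY KEY,
    xml_value_datadef_uuid TEXT NOT NULL,
    xml_value_position     INTEGER NOT NULL,
    xml_value              TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS xml_streams (
    xml_stream_uuid         TEXT PRIMARY KEY,
    xml_stream_datadef_uuid TEXT NOT NULL,
    xml_stream_position     INTEGER NOT NULL,
    xml_stream_time         REAL NOT NULL,
    xml_stream_value        TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS collections (
    collection_entry_uuid   TEXT PRIMARY KEY,
    collection_uuid         TEXT NOT NULL,
    collection_entity_uuid  TEXT,
    collection_entity_class TEXT
);

CREATE TABLE IF NOT EXISTS transforms (
    transform_uuid        TEXT PRIMARY KEY,
    transform_string      TEXT NOT NULL CHECK (transform_string <> ''),
    transform_description TEXT
);

CREATE TABLE IF NOT EXISTS modalities (
    modality_uuid        TEXT PRIMARY KEY,
    modality_name        TEXT NOT NULL UNIQUE,
    modality_description TEXT
);

-- Secondary tables: the data model gives no column detail beyond identity and
-- entity linkage, so these stay minimal and are reachable through the generic
-- put_rows / get_rows interface.

CREATE TABLE IF NOT EXISTS comments (
    comment_uuid         TEXT PRIMARY KEY,
    comment_entity_uuid  TEXT,
    comment_entity_class TEXT,
    comment_value        TEXT
);

CREATE TABLE IF NOT EXISTS contacts (
    contact_uuid        TEXT PRIMARY KEY,
    contact_name        TEXT,
    contact_description TEXT
);

CREATE TABLE IF NOT EXISTS devices (
    device_uuid         TEXT PRIMARY KEY,
    device_name         TEXT,
    device_description  TEXT
);

CREATE TABLE IF NOT EXISTS elements (
    element_uuid         TEXT PRIMARY KEY,
    element_dataset_uuid TEXT,
    element_label        TEXT,
    element_position     INTEGER,
    element_description  TEXT
);

CREATE TABLE IF NOT EXISTS subjects (
    subject_uuid        TEXT PRIMARY KEY,
    subject_description TEXT
);

CREATE INDEX IF NOT EXISTS idx_events_dataset ON events (event_dataset_uuid);
CREATE INDEX IF NOT EXISTS idx_tags_entity ON tags (tag_entity_uuid);
CREATE INDEX IF NOT EXISTS idx_attributes_entity ON attributes (attribute_entity_uuid);
CREATE INDEX IF NOT EXISTS idx_transforms_string ON transforms (transform_string);
CREATE INDEX IF NOT EXISTS idx_numeric_streams_def
    ON numeric_streams (numeric_stream_datadef_uuid, numeric_stream_time);
CREATE INDEX IF NOT EXISTS idx_xml_streams_def
    ON xml_streams (xml_stream_datadef_uuid, xml_stream_time);
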