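"""Whole-dataset storage and retrieval.

A dataset is one single-modality recording.  Its payload is archived
verbatim as an opaque blob while the modality handler explodes events and
metadata into searchable tables.  Identity is the triple (namespace, name,
version), unique database-wide; repeated stores of the same (namespace,
name) either fail (``is_unique=True``, the default) or take the next
version number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Union

from . import synthetic as _syn
from .modalities import EEGStruct, GenericStruct
from .schema_core import (
    Connection,
    DEFAULT_PARENT_UUID,
    EntityRef,
    NotFoundError,
    UniquenessError,
    ValidationError,
    new_uuid,
    utcnow_iso,
)

__all__ = [
    "DatasetRecord",
    "StoreOptions",
    "store_dataset",
    "retrieve_dataset",
    "next_version",
]


@dataclass
class DatasetRecord:
    """One recording: identity, lineage, modality, and opaque payload.

    ``data`` may be raw bytes or a container structure (:class:`EEGStruct`
    or :class:`GenericStruct`); structures are serialized through the
    modality codec before archiving.  Unset fields get the store defaults:
    namespace ``'mobbed'``, contact ``'System'``, the fixed default parent
    UUID, modality ``'EEG'``.
    """

    name: str
    data: Any = None
    namespace: str = "mobbed"
    modality: Optional[str] = None
    description: str = ""
    session_uuid: Optional[str] = None
    contact_uuid: Optional[str] = None
    parent_uuid: Optional[str] = None
    dataset_uuid: Optional[str] = None
    version: Optional[int] = None
    creation_date: Optional[str] = None
    oid: Optional[int] = None


@dataclass
class StoreOptions:
    """Keyword options of a store: uniqueness, tags to attach, and the
    event-type UUIDs to reuse so the same label maps to the same type
    across datasets."""

    is_unique: bool = True
    tags: list[str] = field(default_factory=list)
    event_type_uuids: list[str] = field(default_factory=list)


# -- modality codecs --------------------------------------------------------
# encode: container -> bytes; decode: bytes -> container.  SIMPLE archives
# raw bytes untouched.

_CODECS = {
    "EEG": (_syn.eeg_to_bytes, _syn.eeg_from_bytes, EEGStruct),
    "GENERIC": (_syn.generic_to_bytes, _syn.generic_from_bytes, GenericStruct),
}


def _to_blob_and_struct(modality: str, data: Any) -> tuple[bytes, Any]:
    if modality in _CODECS:
        encode, decode, cls = _CODECS[modality]
        if isinstance(data, cls):
            return encode(data), data
        if isinstance(data, (bytes, bytearray)):
            return bytes(data), decode(bytes(data))
        raise ValidationError(
            f"{modality} payload must be bytes or {cls.__name__}, "
            f"got {type(data).__name__}"
        )
    if not isinstance(data, (bytes, bytearray)):
        raise ValidationError(
            f"{modality} payload must be raw bytes, got {type(data).__name__}"
        )
    return bytes(data), None


def _default_contact_uuid(conn: Connection) -> Optional[str]:
    cur = conn._raw_execute(
        "SELECT contact_uuid FROM contacts WHERE contact_name = 'System'"
    )
    row = cur.fetchone()
    return row[0] if row else None


def next_version(conn: Connection, namespace: str, name: str) -> int:
    """The version the next store of (namespace, name) would take:
    1 + the maximum existing version, or 1 if none exists.  Matching is
    case-sensitive exact."""
    cur = conn._raw_execute(
        "SELECT MAX(dataset_version) FROM datasets "
        "WHERE dataset_namespace = ? AND dataset_name = ?",
        (namespace, name),
    )
    row = cur.fetchone()
    return 1 if row[0] is None else int(row[0]) + 1


def store_dataset(
    conn: Connection,
    record: DatasetRecord,
    options: Optional[StoreOptions] = None,
) -> tuple[str, list[str]]:
    """Store one dataset atomically: archive the payload, explode its
    events/metadata via the modality handler, and attach any tags.

    Returns the new dataset UUID and the reusable event-type UUID list —
    the input ``options.event_type_uuids`` extended with the types created
    during this store.
    """
    options = options or StoreOptions()
    if not record.name:
        raise ValidationError("dataset name must be non-empty")
    if record.data is None:
        raise ValidationError("dataset payload is required")

    modality_name = record.modality or "EEG"
    modality_uuid = conn.modality_uuid(modality_name)  # unknown -> NotFoundError
    handler = conn.modality_handlers.get(modality_name)
    if handler is None:
        raise ValidationError(
            f"no explosion handler registered on this connection for "
            f"modality {modality_name!r}"
        )
    blob, struct = _to_blob_and_struct(modality_name, record.data)

    # resolve the reusable type map (uuid list -> name->uuid) before writing
    known: dict[str, str] = {}
    for uid in options.event_type_uuids:
        cur = conn._raw_execute(
            "SELECT event_type FROM event_types WHERE event_type_uuid = ?", (uid,)
        )
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"unknown event type uuid {uid}")
        known[row[0]] = uid

    dataset_uuid = record.dataset_uuid or new_uuid()
    with conn.transaction():
        existing = next_version(conn, record.namespace, record.name)
        if existing > 1 and options.is_unique:
            raise UniquenessError(
                f"dataset ({record.name!r}, {record.namespace!r}) already "
                f"exists and is_unique is set"
            )
        version = record.version or existing
        conn.insert_row(
            "datasets",
            {
                "dataset_uuid": dataset_uuid,
                "dataset_session_uuid": record.session_uuid,
                "dataset_namespace": record.namespace,
                "dataset_name": record.name,
                "dataset_version": version,
                "dataset_contact_uuid": record.contact_uuid
                or _default_contact_uuid(conn),
                "dataset_creation_date": record.creation_date or utcnow_iso(),
                "dataset_description": record.description,
                "dataset_parent_uuid": record.parent_uuid or DEFAULT_PARENT_UUID,
                "dataset_modality_uuid": modality_uuid,
                "data": blob,
            },
        )
        conn._raw_execute(
            "UPDATE datasets SET dataset_oid = rowid WHERE dataset_uuid = ?",
            (dataset_uuid,),
        )
        _, type_map = handler(conn, dataset_uuid, struct, known)
        if options.tags:
            from .annotation_meta import add_tags

            add_tags(conn, EntityRef(dataset_uuid, "datasets"), options.tags)

    new_uuids = [u for u in type_map.values() if u not in set(options.event_type_uuids)]
    return dataset_uuid, list(options.event_type_uuids) + sorted(new_uuids)


def retrieve_dataset(conn: Connection, uuid: str) -> DatasetRecord:
    """Retrieve a whole dataset: every DATASETS column plus the payload,
    byte-identical to what was stored (no partial blob reads)."""
    cur = conn._raw_execute(
        "SELECT dataset_uuid, dataset_session_uuid, dataset_namespace, "
        "dataset_name, dataset_version, dataset_contact_uuid, "
        "dataset_creation_date, dataset_description, dataset_parent_uuid, "
        "dataset_modality_uuid, dataset_oid, data "
        "FROM datasets WHERE dataset_uuid = ?",
        (uuid,),
    )
    row = cur.fetchone()
    if row is None:
        raise NotFoundError(f"no dataset with uuid {uuid}")
    modality_name = None
    cur = conn._raw_execute(
        "SELECT modality_name FROM modalities WHERE modality_uuid = ?", (row[9],)
    )
    mrow = cur.fetchone()
    if mrow is not None:
        modality_name = mrow[0]
    return DatasetRecord(
        dataset_uuid=row[0],
        session_uuid=row[1],
        namespace=row[2],
        name=row[3],
        version=row[4],
        contact_uuid=row[5],
        creation_date=row[6],
        description=row[7] or "",
        parent_uuid=row[8],
        modality=modality_name,
        oid=row[10],
        data=bytes(row[11]) if row[11] is not None else None,
    )
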