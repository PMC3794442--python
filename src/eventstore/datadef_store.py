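"""Auxiliary data definitions, stream explosion, and data maps.

A *data definition* holds auxiliary data in one of five formats —
NUMERIC_VALUE (a vector of doubles), NUMERIC_STREAM (time-stamped vectors
of doubles), XML_VALUE (XML strings), XML_STREAM (time-stamped XML
strings), EXTERNAL (an opaque blob) — created independently of any dataset
and associated with entities many-to-many through data maps.

Non-EXTERNAL data is exploded into the matching value/stream table so it is
searchable; streams store one row per column.  A uniform stream sampled at
``fs`` Hz has timestamps ``i / fs`` (i from 0) — time in seconds relative
to the start of the data itself, spaced by the reciprocal of the sampling
rate; a non-uniform stream instead carries explicit strictly-increasing
timestamps and records a sampling rate of -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np

from .schema_core import (
    Connection,
    EntityRef,
    NotFoundError,
    ValidationError,
    new_uuid,
)

__all__ = [
    "FORMATS",
    "DataDefRecord",
    "DataMapRecord",
    "create_datadef",
    "retrieve_datadef",
    "map_datadef",
    "retrieve_mapped",
    "maps_for_entity",
]

FORMATS = ("NUMERIC_VALUE", "NUMERIC_STREAM", "XML_VALUE", "XML_STREAM",
           "EXTERNAL")


@dataclass
class DataDefRecord:
    """One auxiliary data item.

    ``sampling_rate`` is in Hz for uniform streams and -1 otherwise;
    ``timestamps`` (seconds from the start of the data) are given instead
    of a rate for non-uniform streams.
    """

    format: str
    data: Any = None
    sampling_rate: float = -1.0
    timestamps: Optional[Sequence[float]] = None
    description: str = ""
    datadef_uuid: Optional[str] = None


@dataclass(frozen=True)
class DataMapRecord:
    datamap_uuid: str
    datadef_uuid: str
    entity: EntityRef
    path: str


def _validate(record: DataDefRecord) -> None:
    if record.format not in FORMATS:
        raise ValidationError(
            f"unknown format {record.format!r}; expected one of {FORMATS}"
        )
    is_stream = record.format in ("NUMERIC_STREAM", "XML_STREAM")
    has_rate = record.sampling_rate is not None and record.sampling_rate > 0
    has_stamps = record.timestamps is not None
    if is_stream:
        if has_rate == has_stamps:
            raise ValidationError(
                "a stream needs exactly one of a positive sampling_rate or "
                "explicit timestamps"
            )
        if has_stamps:
            ts = np.asarray(record.timestamps, dtype=np.float64)
            if ts.ndim != 1 or (len(ts) > 1 and not np.all(np.diff(ts) > 0)):
                raise ValidationError("timestamps must be strictly increasing")
    elif has_stamps:
        raise ValidationError(f"{record.format} does not take timestamps")
    if record.data is None:
        raise ValidationError("data payload is required")


def _stream_times(record: DataDefRecord, n_cols: int) -> list[float]:
    if record.timestamps is not None:
        ts = [float(t) for t in record.timestamps]
        if len(ts) != n_cols:
            raise ValidationError(
                f"{len(ts)} timestamps for {n_cols} stream columns"
            )
        return ts
    return [i / float(record.sampling_rate) for i in range(n_cols)]


def create_datadef(conn: Connection, record: DataDefRecord) -> str:
    """Store a data definition and explode non-EXTERNAL payloads into the
    matching value/stream table (one row per column for streams).  The
    definition is not yet associated with any entity."""
    _validate(record)
    uid = record.datadef_uuid or new_uuid()
    rate = float(record.sampling_rate) if (
        record.sampling_rate and record.sampling_rate > 0) else -1.0
    blob = None
    if record.format == "EXTERNAL":
        if not isinstance(record.data, (bytes, bytearray)):
            raise ValidationError("EXTERNAL payload must be bytes")
        blob = bytes(record.data)
    with conn.transaction():
        conn.insert_row(
            "datadefs",
            {
                "datadef_uuid": uid,
                "datadef_format": record.format,
                "datadef_sampling_rate": rate,
                "datadef_description": record.description,
                "datadef_data": blob,
            },
        )
        conn._raw_execute(
            "UPDATE datadefs SET datadef_oid = rowid WHERE datadef_uuid = ?",
            (uid,),
        )
        if record.format == "NUMERIC_VALUE":
            vec = np.atleast_1d(np.asarray(record.data, dtype=np.float64))
            if vec.ndim != 1:
                raise ValidationError("NUMERIC_VALUE takes a scalar or vector")
            for i, v in enumerate(vec):
                conn.insert_row(
                    "numeric_values",
                    {"numeric_value_uuid": new_uuid(),
                     "numeric_value_datadef_uuid": uid,
                     "numeric_value_position": i,
                     "numeric_value": float(v)},
                )
        elif record.format == "NUMERIC_STREAM":
            mat = np.atleast_2d(np.asarray(record.data, dtype=np.float64))
            times = _stream_times(record, mat.shape[1])
            for i in range(mat.shape[1]):
                conn.insert_row(
                    "numeric_streams",
                    {"numeric_stream_uuid": new_uuid(),
                     "numeric_stream_datadef_uuid": uid,
                     "numeric_stream_position": i,
                     "numeric_stream_time": times[i],
                     "numeric_stream_data": mat[:, i].tobytes()},
                )
        elif record.format == "XML_VALUE":
            values = [record.data] if isinstance(record.data, str) else list(record.data)
            for i, xml in enumerate(values):
                conn.insert_row(
                    "xml_values",
                    {"xml_value_uuid": new_uuid(),
                     "xml_value_datadef_uuid": uid,
                     "xml_value_position": i,
                     "xml_value": str(xml)},
                )
        elif record.format == "XML_STREAM":
            values = list(record.data)
            times = _stream_times(record, len(values))
            for i, xml in enumerate(values):
                conn.insert_row(
                    "xml_streams",
                    {"xml_stream_uuid": new_uuid(),
                     "xml_stream_datadef_uuid": uid,
                     "xml_stream_position": i,
                     "xml_stream_time": times[i],
                     "xml_stream_value": str(xml)},
                )
    return uid


def retrieve_datadef(conn: Connection, uuid: str) -> DataDefRecord:
    """Reconstitute a data definition: element-exact for numeric formats,
    byte-/string-exact for EXTERNAL and XML.  Stream columns are
    reassembled in ascending timestamp order regardless of storage order."""
    cur = conn._raw_execute(
        "SELECT datadef_format, datadef_sampling_rate, datadef_description, "
        "datadef_data FROM datadefs WHERE datadef_uuid = ?",
        (uuid,),
    )
    row = cur.fetchone()
    if row is None:
        raise NotFoundError(f"no data definition with uuid {uuid}")
    fmt, rate, description, blob = row
    record = DataDefRecord(format=fmt, sampling_rate=rate,
                           description=description or "", datadef_uuid=uuid)
    if fmt == "EXTERNAL":
        record.data = bytes(blob) if blob is not None else b""
    elif fmt == "NUMERIC_VALUE":
        cur = conn._raw_execute(
            "SELECT numeric_value FROM numeric_values "
            "WHERE numeric_value_datadef_uuid = ? ORDER BY numeric_value_position",
            (uuid,),
        )
        record.data = np.array([r[0] for r in cur.fetchall()], dtype=np.float64)
    elif fmt == "NUMERIC_STREAM":
        cur = conn._raw_execute(
            "SELECT numeric_stream_time, numeric_stream_data FROM numeric_streams "
            "WHERE numeric_stream_datadef_uuid = ? ORDER BY numeric_stream_time",
            (uuid,),
        )
        rows = cur.fetchall()
        record.timestamps = [r[0] for r in rows]
        cols = [np.frombuffer(r[1], dtype=np.float64) for r in rows]
        record.data = (np.stack(cols, axis=1) if cols
                       else np.empty((0, 0), dtype=np.float64))
    elif fmt == "XML_VALUE":
        cur = conn._raw_execute(
            "SELECT xml_value FROM xml_values WHERE xml_value_datadef_uuid = ? "
            "ORDER BY xml_value_position",
            (uuid,),
        )
        record.data = [r[0] for r in cur.fetchall()]
    elif fmt == "XML_STREAM":
        cur = conn._raw_execute(
            "SELECT xml_stream_time, xml_stream_value FROM xml_streams "
            "WHERE xml_stream_datadef_uuid = ? ORDER BY xml_stream_time",
            (uuid,),
        )
        rows = cur.fetchall()
        record.timestamps = [r[0] for r in rows]
        record.data = [r[1] for r in rows]
    return record


def map_datadef(conn: Connection, datadef_uuid: str, entity: EntityRef,
                path: str) -> str:
    """Associate a data definition with an entity at a structure path.
    One definition may map to many entities and vice versa; the same pair
    may be mapped at several paths."""
    cur = conn._raw_execute(
        "SELECT 1 FROM datadefs WHERE datadef_uuid = ?", (datadef_uuid,)
    )
    if cur.fetchone() is None:
        raise NotFoundError(f"no data definition with uuid {datadef_uuid}")
    conn.require_entity(entity)
    uid = new_uuid()
    with conn.transaction():
        conn.insert_row(
            "datamaps",
            {
                "datamap_uuid": uid,
                "datamap_datadef_uuid": datadef_uuid,
                "datamap_entity_uuid": entity.entity_uuid,
                "datamap_entity_class": entity.entity_class,
                "datamap_path": path,
            },
        )
    return uid


def retrieve_mapped(
    conn: Connection, maps: Sequence[DataMapRecord]
) -> list[tuple[str, Any]]:
    """Resolve data maps to (path, payload) pairs, order-preserving."""
    out: list[tuple[str, Any]] = []
    for m in maps:
        record = retrieve_datadef(conn, m.datadef_uuid)
        out.append((m.path, record.data))
    return out


def maps_for_entity(conn: Connection, entity: EntityRef) -> list[DataMapRecord]:
    """All data maps attached to *entity*, in stable (UUID) order."""
    cur = conn._raw_execute(
        "SELECT datamap_uuid, datamap_datadef_uuid, datamap_path FROM datamaps "
        "WHERE datamap_entity_uuid = ? AND datamap_entity_class = ? "
        "ORDER BY datamap_uuid",
        (entity.entity_uuid, entity.entity_class),
    )
    return [DataMapRecord(u, d, entity, p) for u, d, p in cur.fetchall()]
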