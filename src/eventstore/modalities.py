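"""Modality registry and the built-in container explosion handlers.

A *modality* names the procedure that decomposes a dataset's container into
searchable rows while the payload itself stays archived as an opaque blob:

* ``SIMPLE``  — archive only; no events or metadata are exploded.
* ``EEG``     — an EEGLAB-style structure: the ``event``, ``urevent`` and
  ``chanlocs`` fields are exploded into EVENTS, EVENT_TYPES and ATTRIBUTES.
* ``GENERIC`` — a structure with ``element`` / ``event`` / ``feature`` /
  ``metadata`` sections whose events carry explicit start/end times and a
  certainty in [0, 1].

Users can add a modality by supplying a handler with the same calling
convention; a MODALITIES row is created and datasets of that modality
dispatch to the handler at store time.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Any, Callable, Optional

import numpy as np

from .schema_core import (
    Connection,
    EntityRef,
    NotFoundError,
    UniquenessError,
    ValidationError,
    new_uuid,
)

__all__ = [
    "EEGStruct",
    "GenericStruct",
    "map_event_types",
    "explode_eeg",
    "explode_generic",
    "explode_simple",
    "register_modality",
    "BUILTIN_HANDLERS",
]


# ---------------------------------------------------------------------------
# Container structures

@dataclass
class EEGStruct:
    """An EEGLAB-like recording container.

    ``data`` is channels x frames; ``srate`` is the sampling rate in Hz.
    Events carry a ``type`` (string or numeric code) and a 1-based sample
    ``latency``; any further keys are treated as event modifiers.
    ``chanlocs`` holds one dict of location fields per channel.
    """

    data: np.ndarray
    srate: float
    event: list[dict[str, Any]] = field(default_factory=list)
    urevent: list[dict[str, Any]] = field(default_factory=list)
    chanlocs: list[dict[str, Any]] = field(default_factory=list)

    def validate(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise ValidationError("EEG data must be a channels x frames matrix")
        if self.srate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.chanlocs and len(self.chanlocs) != data.shape[0]:
            raise ValidationError(
                f"chanlocs length {len(self.chanlocs)} does not match "
                f"{data.shape[0]} data channels"
            )
        n_frames = data.shape[1]
        for ev in list(self.event) + list(self.urevent):
            lat = ev.get("latency")
            if lat is None or not (1 <= float(lat) <= n_frames):
                raise ValidationError(
                    f"event latency {lat!r} outside data range [1, {n_frames}]"
                )

    @property
    def n_frames(self) -> int:
        return int(np.asarray(self.data).shape[1])


@dataclass
class GenericStruct:
    """A generic container with element/event/feature/metadata sections.

    Event records carry ``type``, ``start_time`` and ``end_time`` in seconds
    from the start of the data, and an optional ``certainty`` in [0, 1]
    (defaulting to 1, the value of a hardware-inserted marker).
    """

    element: list[dict[str, Any]] = field(default_factory=list)
    event: list[dict[str, Any]] = field(default_factory=list)
    feature: list[dict[str, Any]] = field(default_factory=list)
    metadata: list[dict[str, Any]] = field(default_factory=list)

    def validate(self) -> None:
        for ev in self.event:
            start = float(ev.get("start_time", 0.0))
            end = float(ev.get("end_time", start))
            certainty = float(ev.get("certainty", 1.0))
            if start < 0 or end < start:
                raise ValidationError(
                    f"event times start={start} end={end} are invalid"
                )
            if not 0.0 <= certainty <= 1.0:
                raise ValidationError(
                    f"certainty {certainty} outside [0, 1]"
                )


# ---------------------------------------------------------------------------
# Event types

def map_event_types(
    type_names: list[str], known: Optional[dict[str, str]] = None
) -> tuple[dict[str, str], list[str]]:
    """Resolve event-type names to shared UUIDs, reusing known ones.

    Returns the extended name->uuid map and the UUIDs created for names not
    previously known.  Numeric type codes must already be stringified by the
    caller; each distinct name maps to exactly one UUID.
    """
    extended = dict(known or {})
    created: list[str] = []
    for name in type_names:
        if name not in extended:
            uid = new_uuid()
            extended[name] = uid
            created.append(uid)
    return extended, created


def _persist_event_types(conn: Connection, type_map: dict[str, str],
                         created: list[str]) -> None:
    created_set = set(created)
    for name, uid in type_map.items():
        if uid in created_set:
            conn.insert_row(
                "event_types",
                {"event_type_uuid": uid, "event_type": name,
                 "event_type_description": None},
            )


def _stringify_type(value: Any) -> str:
    if isinstance(value, str):
        return value
    if isinstance(value, numbers.Integral):
        return str(int(value))
    return str(value)


def _write_attribute(conn: Connection, entity: EntityRef, path: str,
                     value: Any) -> None:
    numeric, text = None, None
    if isinstance(value, numbers.Real) and not isinstance(value, bool):
        numeric = float(value)
    else:
        text = str(value)
    conn.insert_row(
        "attributes",
        {
            "attribute_uuid": new_uuid(),
            "attribute_entity_uuid": entity.entity_uuid,
            "attribute_entity_class": entity.entity_class,
            "attribute_path": path,
            "attribute_numeric_value": numeric,
            "attribute_value": text,
        },
    )


def _write_event(conn: Connection, dataset_uuid: str, type_uuid: str,
                 start: float, end: float, certainty: float,
                 position: Optional[int]) -> str:
    if not 0.0 <= certainty <= 1.0:
        raise ValidationError(f"certainty {certainty} outside [0, 1]")
    if start < 0 or end < start:
        raise ValidationError(f"event times start={start} end={end} invalid")
    uid = new_uuid()
    conn.insert_row(
        "events",
        {
            "event_uuid": uid,
            "event_dataset_uuid": dataset_uuid,
            "event_type_uuid": type_uuid,
            "event_start_time": start,
            "event_end_time": end,
            "event_certainty": certainty,
            "event_position": position,
        },
    )
    return uid


# ---------------------------------------------------------------------------
# Explosion handlers

#: Event keys that are structural rather than modifiers.
_EEG_CORE_KEYS = {"type", "latency"}
_GENERIC_CORE_KEYS = {"type", "start_time", "end_time", "certainty"}


def explode_eeg(
    conn: Connection,
    dataset_uuid: str,
    eeg: EEGStruct,
    known: Optional[dict[str, str]] = None,
) -> tuple[list[str], dict[str, str]]:
    """Explode an EEG container into EVENTS / EVENT_TYPES / ATTRIBUTES rows.

    Latencies use the container's 1-based sample convention, so an event at
    latency L and sampling rate fs occurs at (L - 1)/fs seconds; EEG events
    are instantaneous (start == end) with certainty 1.  Channel location
    fields become dataset attributes at ``/chanlocs/<index>/<field>`` (index
    1-based) and non-structural event fields become event attributes at
    ``/event/<field>``.  Original (ur)events are stored as events flagged by
    a ``/urevent`` attribute.
    """
    eeg.validate()
    names = [_stringify_type(ev["type"]) for ev in eeg.event]
    names += [_stringify_type(ev["type"]) for ev in eeg.urevent]
    type_map, created = map_event_types(names, known)
    event_uuids: list[str] = []
    with conn.transaction():
        _persist_event_types(conn, type_map, created)
        for lst, is_ur in ((eeg.event, False), (eeg.urevent, True)):
            for pos, ev in enumerate(lst):
                t = (float(ev["latency"]) - 1.0) / eeg.srate
                uid = _write_event(
                    conn, dataset_uuid, type_map[_stringify_type(ev["type"])],
                    t, t, 1.0, pos,
                )
                ref = EntityRef(uid, "events")
                if is_ur:
                    _write_attribute(conn, ref, "/urevent", 1)
                else:
                    event_uuids.append(uid)
                for key, value in ev.items():
                    if key not in _EEG_CORE_KEYS:
                        _write_attribute(conn, ref, f"/event/{key}", value)
        ds_ref = EntityRef(dataset_uuid, "datasets")
        for idx, loc in enumerate(eeg.chanlocs, start=1):
            for fld, value in loc.items():
                _write_attribute(conn, ds_ref, f"/chanlocs/{idx}/{fld}", value)
    return event_uuids, type_map


def explode_generic(
    conn: Connection,
    dataset_uuid: str,
    g: GenericStruct,
    known: Optional[dict[str, str]] = None,
) -> tuple[list[str], dict[str, str]]:
    """Explode a generic container: events keep their explicit start/end
    times and certainties; element records go to ELEMENTS; feature and
    metadata records become dataset attributes keyed by section path."""
    g.validate()
    names = [_stringify_type(ev.get("type", "")) for ev in g.event]
    type_map, created = map_event_types(names, known)
    event_uuids: list[str] = []
    with conn.transaction():
        _persist_event_types(conn, type_map, created)
        for pos, ev in enumerate(g.event):
            start = float(ev.get("start_time", 0.0))
            end = float(ev.get("end_time", start))
            certainty = float(ev.get("certainty", 1.0))
            uid = _write_event(
                conn, dataset_uuid, type_map[_stringify_type(ev.get("type", ""))],
                start, end, certainty, pos,
            )
            event_uuids.append(uid)
            ref = EntityRef(uid, "events")
            for key, value in ev.items():
                if key not in _GENERIC_CORE_KEYS:
                    _write_attribute(conn, ref, f"/event/{key}", value)
        for pos, rec in enumerate(g.element):
            conn.insert_row(
                "elements",
                {
                    "element_uuid": new_uuid(),
                    "element_dataset_uuid": dataset_uuid,
                    "element_label": str(rec.get("label", f"element_{pos}")),
                    "element_position": pos,
                    "element_description": str(rec.get("description", "")),
                },
            )
        ds_ref = EntityRef(dataset_uuid, "datasets")
        for section, records in (("feature", g.feature), ("metadata", g.metadata)):
            for pos, rec in enumerate(records):
                for key, value in rec.items():
                    _write_attribute(conn, ds_ref, f"/{section}/{pos}/{key}", value)
    return event_uuids, type_map


def explode_simple(
    conn: Connection,
    dataset_uuid: str,
    payload: Any = None,
    known: Optional[dict[str, str]] = None,
) -> tuple[list[str], dict[str, str]]:
    """SIMPLE modality archives the payload without exploding anything;
    tags, attributes and data maps can still be attached afterwards."""
    return [], dict(known or {})


BUILTIN_HANDLERS: dict[str, Callable] = {
    "SIMPLE": explode_simple,
    "EEG": explode_eeg,
    "GENERIC": explode_generic,
}


def register_modality(conn: Connection, name: str, handler: Callable) -> str:
    """Register a user modality: adds a MODALITIES row and wires *handler*
    into this connection's dispatch table.

    The handler is called as ``handler(conn, dataset_uuid, container,
    known_type_map)`` and must return ``(event_uuids, type_map)``.
    Handlers are code, so they are registered per connection; the
    MODALITIES row itself persists.
    """
    try:
        conn.modality_uuid(name)
    except NotFoundError:
        pass
    else:
        raise UniquenessError(f"modality {name!r} already registered")
    uid = new_uuid()
    with conn.transaction():
        conn.insert_row(
            "modalities",
            {"modality_uuid": uid, "modality_name": name,
             "modality_description": "user-registered modality"},
        )
    conn.modality_handlers[name] = handler
    return uid
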