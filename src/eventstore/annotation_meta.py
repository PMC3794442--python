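"""Tags, attributes, and collections — semi-structured metadata on any entity.

Tags are free-floating strings, plain (``'EyeTrack'``) or hierarchical
paths (``'/Context/Indoors/Simulator/Driving'``), attached to any row of
any table; prefix/regex semantics live entirely in the query layer, storage
never rewrites a name.  Attributes are typed values (double or string)
anchored at a structure path such as ``'/event/target_dist'`` — the place
the value occupied in the original container.  Collections are arbitrary
groupings of entities and are themselves taggable.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Any, Optional, Sequence, Union

from .schema_core import (
    Connection,
    EntityRef,
    ValidationError,
    new_uuid,
)

__all__ = [
    "TagRecord",
    "AttributeRecord",
    "add_tags",
    "add_attribute",
    "create_collection",
    "collection_members",
]


@dataclass(frozen=True)
class TagRecord:
    tag_uuid: str
    name: str
    entity: EntityRef


@dataclass(frozen=True)
class AttributeRecord:
    attribute_uuid: str
    entity: EntityRef
    path: str
    numeric_value: Optional[float] = None
    string_value: Optional[str] = None


def add_tags(conn: Connection, entity: EntityRef,
             names: Sequence[str]) -> list[str]:
    """Attach tags to an existing entity; one TAGS row per name.

    Re-adding an existing (name, entity) pair is a no-op that returns the
    existing UUID, so tagging is idempotent.  Comparison is case-sensitive
    exact.
    """
    conn.require_entity(entity)
    uuids: list[str] = []
    with conn.transaction():
        for name in names:
            if not name:
                raise ValidationError("tag name must be non-empty")
            cur = conn._raw_execute(
                "SELECT tag_uuid FROM tags WHERE tag_name = ? AND "
                "tag_entity_uuid = ?",
                (name, entity.entity_uuid),
            )
            row = cur.fetchone()
            if row is not None:
                uuids.append(row[0])
                continue
            uid = new_uuid()
            conn.insert_row(
                "tags",
                {
                    "tag_uuid": uid,
                    "tag_name": name,
                    "tag_entity_uuid": entity.entity_uuid,
                    "tag_entity_class": entity.entity_class,
                },
            )
            uuids.append(uid)
    return uuids


def add_attribute(conn: Connection, entity: EntityRef, path: str,
                  value: Union[float, str]) -> str:
    """Attach one attribute to an existing entity.

    Doubles go to the numeric column, everything else is stored as a
    string (complex values can be encoded as XML strings).  Multiple rows
    per (entity, path) are allowed — channel attributes naturally repeat
    per index.
    """
    conn.require_entity(entity)
    if not path.startswith("/"):
        raise ValidationError(f"attribute path {path!r} must start with '/'")
    numeric, text = None, None
    if isinstance(value, numbers.Real) and not isinstance(value, bool):
        numeric = float(value)
    elif isinstance(value, str):
        text = value
    else:
        raise ValidationError(
            f"attribute value must be a double or a string, got {type(value)!r}"
        )
    uid = new_uuid()
    with conn.transaction():
        conn.insert_row(
            "attributes",
            {
                "attribute_uuid": uid,
                "attribute_entity_uuid": entity.entity_uuid,
                "attribute_entity_class": entity.entity_class,
                "attribute_path": path,
                "attribute_numeric_value": numeric,
                "attribute_value": text,
            },
        )
    return uid


def create_collection(conn: Connection,
                      members: Sequence[EntityRef]) -> str:
    """Group entities (possibly spanning tables) under one collection UUID.

    Writes one membership row per member plus a root row so an empty
    collection still exists and can itself carry tags, attributes, and
    data maps.  Fails atomically if any member is dangling.
    """
    collection_uuid = new_uuid()
    with conn.transaction():
        for member in members:
            conn.require_entity(member)
        conn.insert_row(
            "collections",
            {
                "collection_entry_uuid": new_uuid(),
                "collection_uuid": collection_uuid,
                "collection_entity_uuid": None,
                "collection_entity_class": None,
            },
        )
        for member in members:
            conn.insert_row(
                "collections",
                {
                    "collection_entry_uuid": new_uuid(),
                    "collection_uuid": collection_uuid,
                    "collection_entity_uuid": member.entity_uuid,
                    "collection_entity_class": member.entity_class,
                },
            )
    return collection_uuid


def collection_members(conn: Connection, collection_uuid: str) -> list[EntityRef]:
    """Members of a collection, excluding the root row."""
    cur = conn._raw_execute(
        "SELECT collection_entity_uuid, collection_entity_class FROM collections "
        "WHERE collection_uuid = ? AND collection_entity_uuid IS NOT NULL "
        "ORDER BY collection_entry_uuid",
        (collection_uuid,),
    )
    return [EntityRef(u, c) for u, c in cur.fetchall()]
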