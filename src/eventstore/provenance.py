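"""Transform-string provenance cache.

A transform maps a normalized command string — the computation that
produced a dataset — to the UUID of the produced entity.  Looking a string
up before recomputing turns the table into a cache: a hit returns the
already-computed dataset, a miss means "recompute".  Because input dataset
UUIDs are substituted into the string, a regex search for strings
containing a UUID (through :func:`~eventstore.query_engine.get_rows`)
finds every dataset derived from it — forward provenance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .schema_core import (
    Connection,
    EntityRef,
    ValidationError,
    )

__all__ = [
    "TransformRecord",
    "normalize_transform",
    "store_transform",
    "lookup_transform",
]


@dataclass(frozen=True)
class TransformRecord:
    transform_uuid: str  # UUID of the produced entity
    transform_string: str
    description: str = ""


_DELIMS = "(),[]{}"
_STRIP_BEFORE = re.compile(r"\s+([" + re.escape(_DELIMS) + r"])")
_STRIP_AFTER = re.compile(r"([" + re.escape(_DELIMS) + r"])\s+")
_RUNS = re.compile(r"\s+")


def normalize_transform(template: str, substitutions: Mapping[str, str]) -> str:
    """Produce the canonical transform string for a command template.

    Placeholders (whole words) are replaced by their UUIDs, then blanks
    adjacent to the delimiters ``( ) , [ ] { }`` are removed and remaining
    whitespace runs collapse to single spaces.  Deterministic and
    idempotent, so equal inputs always yield byte-identical strings.
    """
    out = template
    for placeholder, uid in substitutions.items():
        pattern = r"\b" + re.escape(placeholder) + r"\b"
        if not re.search(pattern, out):
            raise ValidationError(
                f"placeholder {placeholder!r} does not occur in the template"
            )
        out = re.sub(pattern, uid, out)
    out = _RUNS.sub(" ", out.strip())
    # iterate until fixed point: stripping can juxtapose new delimiter pairs
    while True:
        stripped = _STRIP_AFTER.sub(r"\1", _STRIP_BEFORE.sub(r"\1", out))
        if stripped == out:
            return stripped
        out = stripped


def store_transform(conn: Connection, produced_uuid: str,
                    transform_string: str, description: str = "") -> str:
    """Record that *transform_string* produced the entity *produced_uuid*.

    The produced entity must already exist (it is normally a dataset).
    The same string may be stored for several produced entities; lookups
    return them all.
    """
    if not transform_string:
        raise ValidationError("transform string must be non-empty")
    conn.require_entity(EntityRef(produced_uuid, "datasets"))
    with conn.transaction():
        conn.insert_row(
            "transforms",
            {
                "transform_uuid": produced_uuid,
                "transform_string": transform_string,
                "transform_description": description,
            },
        )
    return produced_uuid


def lookup_transform(conn: Connection,
                     transform_string: str) -> list[TransformRecord]:
    """All transforms whose string equals the query exactly; an empty list
    is a cache miss ("recompute")."""
    cur = conn._raw_execute(
        "SELECT transform_uuid, transform_string, transform_description "
        "FROM transforms WHERE transform_string = ? ORDER BY transform_uuid",
        (transform_string,),
    )
    return [TransformRecord(u, s, d or "") for u, s, d in cur.fetchall()]
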