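"""SQL-free structured search, generic row writes, and paged cursors.

A query is a :class:`QuerySpec`: column qualifications plus tag groups and
attribute groups.  Matching semantics:

* string columns match directly, by membership in a list of choices, or —
  with ``regexp`` on — by any of a list of regular expressions.  Patterns
  are anchored at the start of the string (``'eeg.*'`` matches names that
  *start with* ``eeg``) and use Python's ``re`` dialect;
* UUID columns accept only exact values or lists, never patterns;
* numeric columns match by exact equality;
* every tag group must match (AND across groups) and within a group at
  least one member must match some tag of the entity (OR within a group);
  attribute groups work the same way, with a member matching either the
  attribute's path or its stringified value (``str(float)`` for doubles).

Results come back in a stable total order — ascending primary-key UUID —
which also drives keyset-paginated cursors: batches are disjoint and their
concatenation equals the full result set.
"""

from __future__ import annotations

import numbers
import re
from dataclasses import dataclass, field as dc_field
from typing import Any, Optional, Sequence, Union

from .schema_core import (
    Connection,
    QueryError,
    UniquenessError,
    new_uuid,
)

__all__ = [
    "ALL",
    "QuerySpec",
    "CursorState",
    "get_template",
    "match_strings",
    "match_tag_groups",
    "get_rows",
    "put_rows",
    "open_cursor",
    "fetch_next",
]

#: Sentinel for an unbounded result set.
ALL = "all"

Qual = Union[str, float, int, Sequence]
Group = Union[str, Sequence[str]]


@dataclass
class QuerySpec:
    """A declarative row filter over one table.

    ``limit`` is a non-negative integer, or :data:`ALL` (equivalently
    ``float('inf')``) for every matching row; limit 0 returns the empty
    row template.
    """

    table: str
    limit: Union[int, float, str] = ALL
    column_quals: dict[str, Qual] = dc_field(default_factory=dict)
    tag_groups: list[Group] = dc_field(default_factory=list)
    attribute_groups: list[Group] = dc_field(default_factory=list)
    regexp: bool = False

    def __post_init__(self) -> None:
        self.table = self.table.lower()
        if self.limit == float("inf"):
            self.limit = ALL
        if self.limit != ALL and (not isinstance(self.limit, int) or self.limit < 0):
            raise QueryError(f"limit must be a non-negative integer or ALL, "
                             f"got {self.limit!r}")


@dataclass
class CursorState:
    """Keyset-pagination state of an open cursor."""

    name: str
    spec: QuerySpec
    fetch_size: int
    last_key: Optional[str] = None
    returned: int = 0
    exhausted: bool = False


# ---------------------------------------------------------------------------
# Pure matching semantics (reference implementation, also used inside SQL
# through registered functions)

def _members(qual: Qual) -> list:
    if isinstance(qual, (list, tuple)):
        return list(qual)
    return [qual]


def _regex_match(pattern: str, cell: str) -> bool:
    try:
        return re.match(pattern, cell) is not None
    except re.error as exc:
        raise QueryError(f"invalid pattern {pattern!r}: {exc}") from exc


def match_strings(cell: str, qual: Qual, regexp: bool = False) -> bool:
    """Does a stored string satisfy a qualification?

    Direct value -> equality; list -> membership; with ``regexp`` on each
    member is a start-anchored regular expression and any may match.
    """
    members = _members(qual)
    if regexp:
        return any(_regex_match(str(m), cell) for m in members)
    return any(cell == m for m in members)


def match_tag_groups(entity_tags: set[str], groups: Sequence[Group],
                     regexp: bool = False) -> bool:
    """AND across groups, OR within a group: every group must have at least
    one member matching at least one of the entity's tags."""
    for group in groups:
        members = _members(group)
        if not any(
            match_strings(tag, member, regexp)
            for tag in entity_tags
            for member in members
        ):
            return False
    return True


def stringify_attribute_value(numeric: Optional[float],
                              text: Optional[str]) -> str:
    """The string an attribute's value presents to group matching."""
    return text if text is not None else str(float(numeric))


def _attr_member_match(path: str, numeric: Optional[float],
                       text: Optional[str], member: str,
                       regexp: bool) -> bool:
    value = stringify_attribute_value(numeric, text)
    if regexp:
        return _regex_match(member, path) or _regex_match(member, value)
    return path == member or value == member


# ---------------------------------------------------------------------------
# Templates

def get_template(conn: Connection, table: str) -> dict[str, None]:
    """An empty row structure whose fields correspond 1-to-1 to the
    table's (non-payload) columns."""
    return {col: None for col in conn.columns(table)}


# ---------------------------------------------------------------------------
# get_rows

def _ensure_sql_functions(conn: Connection) -> None:
    conn._check_open()
    if getattr(conn, "_query_functions_ready", False):
        return

    def sql_regex(pattern: str, cell: Any) -> int:
        if cell is None:
            return 0
        return 1 if _regex_match(pattern, str(cell)) else 0

    def sql_attr_member(path, numeric, text, member, regexp) -> int:
        return 1 if _attr_member_match(path, numeric, text, member,
                                       bool(regexp)) else 0

    conn._sqlite.create_function("es_regex", 2, sql_regex)
    conn._sqlite.create_function("es_attr_member", 5, sql_attr_member)
    conn._query_functions_ready = True


def _is_uuid_column(name: str) -> bool:
    return name.endswith("_uuid")


def _entity_key_column(conn: Connection, table: str) -> str:
    """Column holding the UUID that tags/attributes/maps reference.

    For collections that is the collection's own identifier, which spans
    its membership rows rather than keying one of them.
    """
    return "collection_uuid" if table == "collections" else conn.pk_column(table)


def _column_condition(table: str, col: str, decl: str, qual: Qual,
                      regexp: bool, params: list) -> str:
    members = _members(qual)
    if not members:
        return "0"
    text_like = decl not in ("REAL", "INTEGER")
    if regexp and text_like and not _is_uuid_column(col):
        conds = []
        for m in members:
            conds.append(f"es_regex(?, {table}.{col})")
            params.append(str(m))
        return "(" + " OR ".join(conds) + ")"
    marks = ", ".join("?" for _ in members)
    for m in members:
        if isinstance(m, bool) or not isinstance(m, (str, numbers.Real)):
            raise QueryError(f"unsupported qualification value {m!r}")
        params.append(m)
    return f"{table}.{col} IN ({marks})"


def _group_conditions(spec: QuerySpec, entity_key: str, params: list) -> list[str]:
    conds = []
    for group in spec.tag_groups:
        members = _members(group)
        if not members:
            continue
        member_conds = []
        for m in members:
            if spec.regexp:
                member_conds.append("es_regex(?, tag_name)")
            else:
                member_conds.append("tag_name = ?")
            params.append(str(m))
        conds.append(
            f"EXISTS (SELECT 1 FROM tags WHERE tag_entity_uuid = "
            f"{spec.table}.{entity_key} AND ({' OR '.join(member_conds)}))"
        )
    for group in spec.attribute_groups:
        members = _members(group)
        if not members:
            continue
        member_conds = []
        for m in members:
            member_conds.append(
                "es_attr_member(attribute_path, attribute_numeric_value, "
                "attribute_value, ?, ?)"
            )
            params.extend([str(m), 1 if spec.regexp else 0])
        conds.append(
            f"EXISTS (SELECT 1 FROM attributes WHERE attribute_entity_uuid = "
            f"{spec.table}.{entity_key} AND ({' OR '.join(member_conds)}))"
        )
    return conds


def _run_query(conn: Connection, spec: QuerySpec,
               after_key: Optional[str] = None,
               max_rows: Optional[int] = None) -> list[dict[str, Any]]:
    _ensure_sql_functions(conn)
    cols = conn.columns(spec.table)
    types = conn.column_types(spec.table)
    pk = conn.pk_column(spec.table)
    params: list = []
    conds: list[str] = []
    for col, qual in spec.column_quals.items():
        if col not in cols:
            raise QueryError(f"unknown column {col!r} in table {spec.table!r}")
        conds.append(_column_condition(spec.table, col, types[col], qual,
                                       spec.regexp, params))
    conds.extend(_group_conditions(spec, _entity_key_column(conn, spec.table),
                                   params))
    if after_key is not None:
        conds.append(f"{spec.table}.{pk} > ?")
        params.append(after_key)
    where = " AND ".join(conds) if conds else "1=1"
    sql = (f"SELECT {', '.join(cols)} FROM {spec.table} "
           f"WHERE {where} ORDER BY {pk} ASC")
    if max_rows is not None:
        sql += " LIMIT ?"
        params.append(max_rows)
    cur = conn._raw_execute(sql, tuple(params))
    return [dict(zip(cols, row)) for row in cur.fetchall()]


def get_rows(conn: Connection, spec: QuerySpec) -> list[dict[str, Any]]:
    """Rows of ``spec.table`` satisfying the column qualifications AND all
    tag groups AND all attribute groups, truncated at the limit, in stable
    ascending primary-key order.  Payload blobs are never returned."""
    if spec.limit == 0:
        return [get_template(conn, spec.table)]
    max_rows = None if spec.limit == ALL else int(spec.limit)
    return _run_query(conn, spec, max_rows=max_rows)


# ---------------------------------------------------------------------------
# put_rows

def put_rows(conn: Connection, table: str,
             rows: Sequence[dict[str, Any]]) -> list[str]:
    """Create or update rows of one table, atomically over the batch.

    A row without its primary-key UUID is inserted under a fresh UUID; a
    row whose primary key already exists updates that row.  Unknown
    columns or type mismatches fail the whole batch.
    """
    cols = conn.columns(table)
    types = conn.column_types(table)
    pk = conn.pk_column(table)
    uuids: list[str] = []
    with conn.transaction():
        for row in rows:
            for col, value in row.items():
                if col not in cols:
                    raise QueryError(
                        f"unknown column {col!r} in table {table!r}"
                    )
                if value is None:
                    continue
                if types[col] in ("REAL", "INTEGER"):
                    if isinstance(value, bool) or not isinstance(value, numbers.Real):
                        raise QueryError(
                            f"column {col!r} expects a number, got {value!r}"
                        )
                elif not isinstance(value, str):
                    raise QueryError(
                        f"column {col!r} expects a string, got {value!r}"
                    )
            key = row.get(pk)
            if key is not None:
                cur = conn._raw_execute(
                    f"SELECT 1 FROM {table} WHERE {pk} = ?", (key,)
                )
                exists = cur.fetchone() is not None
            else:
                key, exists = new_uuid(), False
            if exists:
                updates = {c: v for c, v in row.items() if c != pk}
                if updates:
                    assigns = ", ".join(f"{c} = ?" for c in updates)
                    conn._raw_execute(
                        f"UPDATE {table} SET {assigns} WHERE {pk} = ?",
                        tuple(updates.values()) + (key,),
                    )
            else:
                values = dict(row)
                values[pk] = key
                conn.insert_row(table, values)
            uuids.append(key)
    return uuids


# ---------------------------------------------------------------------------
# Cursors

def open_cursor(conn: Connection, spec: QuerySpec, name: str,
                fetch_size: int) -> tuple[list[dict[str, Any]], CursorState]:
    """Open a named cursor over a row query and return the first batch.

    Batches hold at most ``fetch_size`` rows in the stable key order;
    an exhausted cursor keeps returning empty batches.
    """
    if fetch_size <= 0:
        raise QueryError("fetch_size must be positive")
    if name in conn.cursors:
        raise UniquenessError(f"cursor {name!r} is already open")
    if spec.limit == 0:
        raise QueryError("cursors require a row query (limit > 0)")
    state = CursorState(name=name, spec=spec, fetch_size=fetch_size)
    conn.cursors[name] = state
    return _advance(conn, state), state


def fetch_next(conn: Connection, name: str) -> list[dict[str, Any]]:
    """The next batch of an open cursor (empty when exhausted)."""
    conn._check_open()
    state = conn.cursors.get(name)
    if state is None:
        raise QueryError(f"unknown cursor {name!r}")
    return _advance(conn, state)


def _advance(conn: Connection, state: CursorState) -> list[dict[str, Any]]:
    if state.exhausted:
        return []
    spec = state.spec
    remaining = (None if spec.limit == ALL
                 else max(int(spec.limit) - state.returned, 0))
    if remaining == 0:
        state.exhausted = True
        return []
    n = state.fetch_size if remaining is None else min(state.fetch_size, remaining)
    batch = _run_query(conn, spec, after_key=state.last_key, max_rows=n)
    if batch:
        pk = conn.pk_column(spec.table)
        state.last_key = batch[-1][pk]
        state.returned += len(batch)
    if len(batch) < n:
        state.exhausted = True
    return batch
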