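"""Independent brute-force query evaluator used as the oracle for get_rows.

Implements the documented semantics directly on full in-memory table dumps:
column qualifications (equality / membership / start-anchored regex on
string columns), AND across tag and attribute groups with OR within a
group, stable ascending primary-key order, and limit truncation.  It shares
no code with the SQL-generating query engine it checks.
"""

from __future__ import annotations

import re
from typing import Any, Optional, Sequence


def _as_list(x):
    return list(x) if isinstance(x, (list, tuple)) else [x]


def _member_matches(cell: str, member, regexp: bool) -> bool:
    if regexp:
        return re.match(str(member), cell) is not None
    return cell == member


def _attr_string(numeric, text) -> str:
    return text if text is not None else str(float(numeric))


def brute_force_query(
    table_rows: list[dict[str, Any]],
    pk: str,
    column_types: dict[str, str],
    tags_by_entity: dict[str, set],
    attrs_by_entity: dict[str, list],
    column_quals: dict,
    tag_groups: Sequence,
    attribute_groups: Sequence,
    regexp: bool,
    limit: Optional[int],
    entity_key: Optional[str] = None,
) -> list[str]:
    """Primary keys of the matching rows, in stable ascending order."""
    entity_key = entity_key or pk
    selected = []
    for row in table_rows:
        ok = True
        for col, qual in column_quals.items():
            cell = row[col]
            members = _as_list(qual)
            is_string = column_types[col] not in ("REAL", "INTEGER")
            use_regex = regexp and is_string and not col.endswith("_uuid")
            if cell is None:
                ok = False
            elif use_regex:
                ok = any(_member_matches(str(cell), m, True) for m in members)
            else:
                ok = any(cell == m for m in members)
            if not ok:
                break
        if not ok:
            continue
        entity_tags = tags_by_entity.get(row[entity_key], set())
        for group in tag_groups:
            members = _as_list(group)
            if not members:
                continue
            if not any(
                _member_matches(tag, m, regexp)
                for tag in entity_tags
                for m in members
            ):
                ok = False
                break
        if not ok:
            continue
        entity_attrs = attrs_by_entity.get(row[entity_key], [])
        for group in attribute_groups:
            members = _as_list(group)
            if not members:
                continue
            if not any(
                _member_matches(path, m, regexp)
                or _member_matches(_attr_string(num, text), m, regexp)
                for path, num, text in entity_attrs
                for m in members
            ):
                ok = False
                break
        if ok:
            selected.append(row[pk])
    selected.sort()
    if limit is not None:
        selected = selected[:limit]
    return selected


def dump_for_oracle(conn, table: str):
    """Pull the raw inputs the oracle needs straight from the tables."""
    cols = conn.columns(table)
    pk = conn.pk_column(table)
    cur = conn._raw_execute(f"SELECT {', '.join(cols)} FROM {table}")
    rows = [dict(zip(cols, r)) for r in cur.fetchall()]
    tags_by_entity: dict[str, set] = {}
    for name, uid in conn._raw_execute(
        "SELECT tag_name, tag_entity_uuid FROM tags"
    ).fetchall():
        tags_by_entity.setdefault(uid, set()).add(name)
    attrs_by_entity: dict[str, list] = {}
    for path, num, text, uid in conn._raw_execute(
        "SELECT attribute_path, attribute_numeric_value, attribute_value, "
        "attribute_entity_uuid FROM attributes"
    ).fetchall():
        attrs_by_entity.setdefault(uid, []).append((path, num, text))
    return rows, pk, conn.column_types(table), tags_by_entity, attrs_by_entity
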