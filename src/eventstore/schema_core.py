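"""Database lifecycle, connections, and the shared transactional contract.

The store keeps event-rich multichannel recordings (EEG and similar) as
opaque blobs while exploding their events, channel metadata, tags,
attributes, auxiliary streams, and provenance strings into relational
tables so they can be searched without SQL.

Every public operation of the package executes as a single atomic
transaction on one :class:`Connection`: either all of its writes commit or
none do.  The embedded backend is a single-file SQLite database, so a
database persists independently of the client process.
"""

from __future__ import annotations

import datetime as _dt
import re
import sqlite3
import threading
import uuid as _uuid
from collections import Counter
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterator, Optional

__all__ = [
    "EventStoreError",
    "CreationError",
    "DatabaseConnectionError",
    "ClosedConnectionError",
    "UnsupportedBackendError",
    "ValidationError",
    "UniquenessError",
    "NotFoundError",
    "QueryError",
    "DatabaseConfig",
    "Connection",
    "EntityRef",
    "ModalityRecord",
    "BUILTIN_MODALITIES",
    "DEFAULT_PARENT_UUID",
    "new_uuid",
    "seed_uuid_generator",
    "create_database",
    "delete_database",
    "connect",
    "close",
]


# ---------------------------------------------------------------------------
# Errors

class EventStoreError(Exception):
    """Base class for all errors raised by the store."""


class CreationError(EventStoreError):
    """Database creation failed (e.g. name collision)."""


class DatabaseConnectionError(EventStoreError):
    """The database could not be reached or does not exist."""


class ClosedConnectionError(EventStoreError):
    """An operation was attempted on a closed connection handle."""


class UnsupportedBackendError(EventStoreError):
    """The requested backend is not available in this build."""


class ValidationError(EventStoreError):
    """An input record violates a domain invariant."""


class UniquenessError(EventStoreError):
    """A uniqueness constraint (e.g. name/namespace/version) was violated."""


class NotFoundError(EventStoreError):
    """A referenced row does not exist."""


class QueryError(EventStoreError):
    """A query specification referenced an unknown table, column, or cursor."""


# ---------------------------------------------------------------------------
# UUIDs
#
# All primary keys are random (version-4) 128-bit UUIDs stored as lowercase
# hyphenated strings, so records from multiple sources can be merged without
# key conflicts.  An optional seeded generator makes whole runs reproducible.

_uuid_lock = threading.Lock()
_uuid_rng: Optional[Any] = None  # numpy Generator when seeded


def seed_uuid_generator(seed: Optional[int]) -> None:
    """Make subsequently generated UUIDs deterministic (``None`` restores
    the default os-entropy source)."""
    global _uuid_rng
    if seed is None:
        _uuid_rng = None
        return
    import numpy as np

    _uuid_rng = np.random.default_rng(seed)


def new_uuid() -> str:
    """Return a fresh version-4 UUID as a lowercase hyphenated string."""
    with _uuid_lock:
        if _uuid_rng is None:
            return str(_uuid.uuid4())
        raw = bytes(_uuid_rng.bytes(16))
    return str(_uuid.UUID(bytes=raw, version=4))


UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
)

#: Parent UUID assigned to datasets stored without an explicit parent.
DEFAULT_PARENT_UUID = "591df7dd-ce3e-47f8-bea5-6a632c6fcccb"

#: Modalities present in every fresh database.
BUILTIN_MODALITIES = ("SIMPLE", "EEG", "GENERIC")


# ---------------------------------------------------------------------------
# Configuration and domain types

@dataclass(frozen=True)
class DatabaseConfig:
    """Identifies a database and how to reach it.

    The embedded backend maps ``name`` to the file ``<base_dir>/<name>.db``
    and ignores ``host`` and credentials.  A client-server backend is part
    of the interface but not implemented in this build.
    """

    name: str
    host: str = "localhost"
    user: Optional[str] = None
    password: Optional[str] = None
    backend: str = "embedded"
    base_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("database name must be non-empty")
        if self.backend not in ("embedded", "client-server"):
            raise ValidationError(f"unknown backend {self.backend!r}")

    @property
    def path(self) -> Path:
        base = Path(self.base_dir) if self.base_dir is not None else Path.cwd()
        return base / f"{self.name}.db"


@dataclass(frozen=True)
class EntityRef:
    """A (uuid, table-name) pair pointing at a row of any schema table."""

    entity_uuid: str
    entity_class: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "entity_class", self.entity_class.lower())


@dataclass(frozen=True)
class ModalityRecord:
    modality_uuid: str
    name: str
    description: str = ""


def _require_embedded(config: DatabaseConfig) -> None:
    if config.backend != "embedded":
        raise UnsupportedBackendError(
            "only the embedded (single-file) backend is available in this build"
        )


def _ddl() -> str:
    return resources.files("eventstore").joinpath("schema.sql").read_text()


# open-connection accounting so delete_database can fail fast
_open_connections: Counter = Counter()
_conn_lock = threading.Lock()


# ---------------------------------------------------------------------------
# Connection

class Connection:
    """An open handle to one database.

    Multiple simultaneous handles to the same database are permitted; each
    public operation runs as one transaction through
    :meth:`transaction`.  After :meth:`close`, every operation raises
    :class:`ClosedConnectionError`.
    """

    def __init__(self, config: DatabaseConfig):
        _require_embedded(config)
        path = config.path
        if not path.exists():
            raise DatabaseConnectionError(f"database {config.name!r} does not exist")
        self.config = config
        self._sqlite = sqlite3.connect(str(path), isolation_level=None, timeout=30.0)
        self._sqlite.execute("PRAGMA busy_timeout = 30000")
        self._sqlite.execute("PRAGMA foreign_keys = ON")
        self._open = True
        self._txn_depth = 0
        self._column_cache: dict[str, list[tuple[str, str]]] = {}
        self.cursors: dict[str, Any] = {}  # query_engine.CursorState by name
        # name -> explosion handler; seeded with the built-in modalities
        from . import modalities as _modalities

        self.modality_handlers: dict[str, Callable] = dict(
            _modalities.BUILTIN_HANDLERS
        )
        with _conn_lock:
            _open_connections[str(path.resolve())] += 1

    # -- low-level ---------------------------------------------------------

    @property
    def is_open(self) -> bool:
        return self._open

    def _check_open(self) -> None:
        if not self._open:
            raise ClosedConnectionError("connection is closed")

    def _raw_execute(self, sql: str, params: tuple = ()) -> sqlite3.Cursor:
        """Single choke point for every SQL statement on this handle."""
        self._check_open()
        return self._sqlite.execute(sql, params)

    @contextmanager
    def transaction(self) -> Iterator[None]:
        """Run the enclosed writes as one atomic unit.

        Re-entrant: nested uses join the outermost transaction, so a public
        operation composed of several primitives still commits or rolls
        back as a whole.
        """
        self._check_open()
        if self._txn_depth == 0:
            self._raw_execute("BEGIN IMMEDIATE")
        self._txn_depth += 1
        try:
            yield
        except BaseException:
            self._txn_depth -= 1
            if self._txn_depth == 0 and self._open:
                self._sqlite.execute("ROLLBACK")
            raise
        else:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self._sqlite.execute("COMMIT")

    def close(self) -> None:
        """Close the handle and release its resources.

        Closing an already-closed handle raises, matching the contract that
        every operation on a closed handle signals an error.
        """
        self._check_open()
        self._open = False
        self._sqlite.close()
        with _conn_lock:
            key = str(self.config.path.resolve())
            _open_connections[key] -= 1
            if _open_connections[key] <= 0:
                del _open_connections[key]

    # -- schema introspection ---------------------------------------------

    def table_names(self) -> list[str]:
        """Names of all schema tables, lowercase, sorted."""
        cur = self._raw_execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%' AND name NOT LIKE '\\_%' ESCAPE '\\'"
        )
        return sorted(r[0] for r in cur.fetchall())

    def _table_info(self, table: str) -> list[tuple[str, str]]:
        table = table.lower()
        if table not in self._column_cache:
            if not re.fullmatch(r"[a-z_][a-z0-9_]*", table) or table not in self.table_names():
                raise QueryError(f"unknown table {table!r}")
            cur = self._raw_execute(f"PRAGMA table_info({table})")
            self._column_cache[table] = [(r[1], (r[2] or "").upper()) for r in cur.fetchall()]
        return self._column_cache[table]

    def columns(self, table: str, include_blobs: bool = False) -> list[str]:
        """Column names of *table*; payload (BLOB) columns are hidden from
        the structured query surface unless explicitly requested."""
        return [
            name
            for name, decl in self._table_info(table)
            if include_blobs or decl != "BLOB"
        ]

    def column_types(self, table: str) -> dict[str, str]:
        return {name: decl for name, decl in self._table_info(table)}

    def pk_column(self, table: str) -> str:
        table = table.lower()
        cur = self._raw_execute(f"PRAGMA table_info({table})")
        for r in cur.fetchall():
            if r[5]:  # pk flag
                return r[1]
        raise QueryError(f"table {table!r} has no primary key")

    # -- generic row helpers ----------------------------------------------

    def insert_row(self, table: str, values: dict[str, Any]) -> None:
        cols = ", ".join(values)
        marks = ", ".join("?" for _ in values)
        try:
            self._raw_execute(
                f"INSERT INTO {table} ({cols}) VALUES ({marks})",
                tuple(values.values()),
            )
        except sqlite3.IntegrityError as exc:
            raise UniquenessError(str(exc)) from exc

    def entity_exists(self, ref: EntityRef) -> bool:
        """True when *ref* points at an existing row.

        For collections the entity UUID is the collection's own identifier,
        which spans its membership rows rather than keying one of them.
        """
        table = ref.entity_class
        if table not in self.table_names():
            raise QueryError(f"unknown entity class {ref.entity_class!r}")
        col = "collection_uuid" if table == "collections" else self.pk_column(table)
        cur = self._raw_execute(
            f"SELECT 1 FROM {table} WHERE {col} = ? LIMIT 1", (ref.entity_uuid,)
        )
        return cur.fetchone() is not None

    def require_entity(self, ref: EntityRef) -> None:
        if not self.entity_exists(ref):
            raise NotFoundError(
                f"no {ref.entity_class} row with uuid {ref.entity_uuid}"
            )

    def modalities(self) -> list[ModalityRecord]:
        cur = self._raw_execute(
            "SELECT modality_uuid, modality_name, modality_description "
            "FROM modalities ORDER BY modality_name"
        )
        return [ModalityRecord(u, n, d or "") for u, n, d in cur.fetchall()]

    def modality_uuid(self, name: str) -> str:
        cur = self._raw_execute(
            "SELECT modality_uuid FROM modalities WHERE modality_name = ?", (name,)
        )
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"unknown modality {name!r}")
        return row[0]


# ---------------------------------------------------------------------------
# Lifecycle operations

def create_database(config: DatabaseConfig) -> None:
    """Create a new database with the full schema.

    The fresh database contains the three built-in modalities (SIMPLE, EEG,
    GENERIC) and a 'System' contact used as the default dataset contact.
    Fails if a database of that name already exists.
    """
    _require_embedded(config)
    path = config.path
    if path.exists():
        raise CreationError(f"database {config.name!r} already exists")
    path.parent.mkdir(parents=True, exist_ok=True)
    db = sqlite3.connect(str(path), isolation_level=None)
    try:
        db.executescript(_ddl())
        db.execute("BEGIN")
        for name in BUILTIN_MODALITIES:
            db.execute(
                "INSERT INTO modalities (modality_uuid, modality_name, "
                "modality_description) VALUES (?, ?, ?)",
                (new_uuid(), name, f"built-in {name} modality"),
            )
        db.execute(
            "INSERT INTO contacts (contact_uuid, contact_name, contact_description)"
            " VALUES (?, 'System', 'default contact')",
            (new_uuid(),),
        )
        db.execute("COMMIT")
    except BaseException:
        db.close()
        path.unlink(missing_ok=True)
        raise
    db.close()


def delete_database(config: DatabaseConfig) -> None:
    """Remove the database and all of its contents.

    Refuses to run while this process holds an open connection to it
    (fail-fast rather than silently invalidating handles).
    """
    _require_embedded(config)
    path = config.path
    if not path.exists():
        raise DatabaseConnectionError(f"database {config.name!r} does not exist")
    with _conn_lock:
        if _open_connections.get(str(path.resolve()), 0) > 0:
            raise EventStoreError(
                f"database {config.name!r} has open connections; close them first"
            )
    path.unlink()
    for suffix in ("-wal", "-shm"):
        Path(str(path) + suffix).unlink(missing_ok=True)


def connect(config: DatabaseConfig) -> Connection:
    """Open a handle to an existing database."""
    return Connection(config)


def close(conn: Connection) -> None:
    """Close *conn* (module-level convenience for :meth:`Connection.close`)."""
    conn.close()


def utcnow_iso() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
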