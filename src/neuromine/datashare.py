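"""Five-table dataset-sharing store for cross-application exchange.

Applications exchange intermediate results (e.g. citation PMID sets) through
a small embedded SQLite database with exactly five tables: user accounts
(group membership), share permissions, dataset definitions, data rows, and
update history.  The creator of a dataset controls its permissions and is
the only writer; read access is granted to individual users, to groups, or
to the public.  Every state change appends one history event carrying the
application, change type, free-text parameters and the row payload, so the
current row set can always be reconstructed by replaying events from the
create.  Deletion is logical (a tombstone plus a delete event), keeping
replay total.  Authentication is a trusted caller-supplied user id.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

PUBLIC = "public"


class AuthorizationError(PermissionError):
    pass


class NotFoundError(KeyError):
    pass


@dataclass(frozen=True)
class DatasetDefinition:
    dataset_id: int
    title: str
    field_names: Tuple[str, ...]
    creator: str
    description: str
    parameters: str


@dataclass(frozen=True)
class UpdateEvent:
    dataset_id: int
    sequence_number: int
    application: str
    change_type: str  # create | update | delete
    parameters: str
    timestamp: str


_SCHEMA = """
CREATE TABLE IF NOT EXISTS user_account (
    user_id TEXT NOT NULL,
    group_id TEXT NOT NULL,
    UNIQUE (user_id, group_id)
);
CREATE TABLE IF NOT EXISTS share_permission (
    dataset_id INTEGER NOT NULL,
    principal TEXT NOT NULL,
    UNIQUE (dataset_id, principal)
);
CREATE TABLE IF NOT EXISTS dataset_definition (
    dataset_id INTEGER PRIMARY KEY AUTOINCREMENT,
    title TEXT NOT NULL,
    field_names TEXT NOT NULL,
    creator TEXT NOT NULL,
    description TEXT NOT NULL DEFAULT '',
    parameters TEXT NOT NULL DEFAULT '',
    deleted INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS data_row (
    dataset_id INTEGER NOT NULL,
    row_index INTEGER NOT NULL,
    "values" TEXT NOT NULL,
    UNIQUE (dataset_id, row_index)
);
CREATE TABLE IF NOT EXISTS update_history (
    dataset_id INTEGER NOT NULL,
    sequence_number INTEGER NOT NULL,
    application TEXT NOT NULL,
    change_type TEXT NOT NULL,
    parameters TEXT NOT NULL DEFAULT '',
    payload TEXT NOT NULL DEFAULT '',
    timestamp TEXT NOT NULL,
    UNIQUE (dataset_id, sequence_number)
);
"""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class ShareStore:
    """One embedded database; methods take the calling user id explicitly."""

    def __init__(self, path: str = ":memory:"):
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- accounts ----------------------------------------------------------

    def add_user(self, user_id: str, groups: Iterable[str] = ()) -> None:
        rows = [(user_id, g) for g in groups] or []
        with self.conn:
            for r in rows:
                self.conn.execute(
                    "INSERT OR IGNORE INTO user_account (user_id, group_id) VALUES (?, ?)",
                    r,
                )

    def groups_of(self, user_id: Optional[str]) -> List[str]:
        if user_id is None:
            return []
        cur = self.conn.execute(
            "SELECT group_id FROM user_account WHERE user_id = ? ORDER BY group_id",
            (user_id,),
        )
        return [r[0] for r in cur]

    # -- datasets ----------------------------------------------------------

    def create_dataset(
        self,
        user: str,
        title: str,
        field_names: Sequence[str],
        rows: Sequence[Sequence],
        application: str,
        parameters: str = "",
        description: str = "",
        timestamp: Optional[str] = None,
    ) -> int:
        field_names = tuple(field_names)
        if not field_names or len(set(field_names)) != len(field_names):
            raise ValueError("field_names must be non-empty and unique")
        self._check_arity(field_names, rows)
        ts = timestamp or _now()
        with self.conn:  # atomic: definition + rows + create event
            cur = self.conn.execute(
                "INSERT INTO dataset_definition "
                "(title, field_names, creator, description, parameters) "
                "VALUES (?, ?, ?, ?, ?)",
                (title, json.dumps(list(field_names)), user, description, parameters),
            )
            ds = cur.lastrowid
            self._insert_rows(ds, rows, start=0)
            self._append_event(ds, application, "create", parameters,
                               {"rows": [list(r) for r in rows], "append": False}, ts)
        return ds

    def get_definition(self, dataset_id: int) -> DatasetDefinition:
        cur = self.conn.execute(
            "SELECT dataset_id, title, field_names, creator, description, parameters, deleted "
            "FROM dataset_definition WHERE dataset_id = ?",
            (dataset_id,),
        )
        row = cur.fetchone()
        if row is None or row[6]:
            raise NotFoundError(f"dataset {dataset_id} not found")
        return DatasetDefinition(row[0], row[1], tuple(json.loads(row[2])),
                                 row[3], row[4], row[5])

    def get_dataset(
        self, user: Optional[str], dataset_id: int
    ) -> Tuple[DatasetDefinition, List[List]]:
        """Definition and rows in row_index order, if *user* may read them."""
        defn = self.get_definition(dataset_id)
        if not self.can_read(user, dataset_id):
            raise AuthorizationError(
                f"user {user!r} may not read dataset {dataset_id}"
            )
        return defn, self._rows(dataset_id)

    def update_dataset(
        self,
        user: str,
        dataset_id: int,
        new_rows: Sequence[Sequence],
        application: str,
        parameters: str = "",
        append: bool = False,
        timestamp: Optional[str] = None,
    ) -> None:
        defn = self.get_definition(dataset_id)
        if user != defn.creator:
            raise AuthorizationError(f"user {user!r} is not the creator")
        self._check_arity(defn.field_names, new_rows)
        ts = timestamp or _now()
        with self.conn:
            if append:
                start = self.conn.execute(
                    "SELECT COALESCE(MAX(row_index) + 1, 0) FROM data_row "
                    "WHERE dataset_id = ?",
                    (dataset_id,),
                ).fetchone()[0]
                self._insert_rows(dataset_id, new_rows, start=start)
            else:
                self.conn.execute(
                    "DELETE FROM data_row WHERE dataset_id = ?", (dataset_id,)
                )
                self._insert_rows(dataset_id, new_rows, start=0)
            self._append_event(dataset_id, application, "update", parameters,
                               {"rows": [list(r) for r in new_rows], "append": append},
                               ts)

    def delete_dataset(
        self,
        user: str,
        dataset_id: int,
        application: str,
        parameters: str = "",
        timestamp: Optional[str] = None,
    ) -> None:
        defn = self.get_definition(dataset_id)
        if user != defn.creator:
            raise AuthorizationError(f"user {user!r} is not the creator")
        with self.conn:
            self.conn.execute(
                "UPDATE dataset_definition SET deleted = 1 WHERE dataset_id = ?",
                (dataset_id,),
            )
            self._append_event(dataset_id, application, "delete", parameters,
                               {"rows": [], "append": False}, timestamp or _now())

    # -- permissions -------------------------------------------------------

    def set_permission(self, user: str, dataset_id: int, principal: str) -> None:
        """Grant read access; idempotent.  Principal is ``user:<id>``,
        ``group:<id>`` or ``public``.  Creator only."""
        defn = self.get_definition(dataset_id)
        if user != defn.creator:
            raise AuthorizationError(f"user {user!r} is not the creator")
        if principal != PUBLIC and not principal.startswith(("user:", "group:")):
            raise ValueError(f"malformed principal {principal!r}")
        with self.conn:
            self.conn.execute(
                "INSERT OR IGNORE INTO share_permission (dataset_id, principal) "
                "VALUES (?, ?)",
                (dataset_id, principal),
            )

    def revoke_permission(self, user: str, dataset_id: int, principal: str) -> None:
        defn = self.get_definition(dataset_id)
        if user != defn.creator:
            raise AuthorizationError(f"user {user!r} is not the creator")
        with self.conn:
            self.conn.execute(
                "DELETE FROM share_permission WHERE dataset_id = ? AND principal = ?",
                (dataset_id, principal),
            )

    def can_read(self, user: Optional[str], dataset_id: int) -> bool:
        defn = self.get_definition(dataset_id)
        if user is not None and user == defn.creator:
            return True
        principals = {
            r[0]
            for r in self.conn.execute(
                "SELECT principal FROM share_permission WHERE dataset_id = ?",
                (dataset_id,),
            )
        }
        if PUBLIC in principals:
            return True
        if user is None:
            return False
        if f"user:{user}" in principals:
            return True
        return any(f"group:{g}" in principals for g in self.groups_of(user))

    # -- history -----------------------------------------------------------

    def history(self, dataset_id: int) -> List[UpdateEvent]:
        cur = self.conn.execute(
            "SELECT dataset_id, sequence_number, application, change_type, "
            "parameters, timestamp FROM update_history WHERE dataset_id = ? "
            "ORDER BY sequence_number",
            (dataset_id,),
        )
        return [UpdateEvent(*r) for r in cur]

    def replay(self, dataset_id: int) -> Tuple[List[List], bool]:
        """Reconstruct (rows, deleted) purely from the event log."""
        cur = self.conn.execute(
            "SELECT change_type, payload FROM update_history WHERE dataset_id = ? "
            "ORDER BY sequence_number",
            (dataset_id,),
        )
        rows: List[List] = []
        deleted = False
        for change_type, payload in cur:
            data = json.loads(payload)
            if change_type == "create":
                rows = [list(r) for r in data["rows"]]
            elif change_type == "update":
                if data["append"]:
                    rows.extend(list(r) for r in data["rows"])
                else:
                    rows = [list(r) for r in data["rows"]]
            elif change_type == "delete":
                deleted = True
        return rows, deleted

    # -- exchange ----------------------------------------------------------

    def export_json(self, user: Optional[str], dataset_id: int) -> str:
        """The cross-application dataset exchange document."""
        defn, rows = self.get_dataset(user, dataset_id)
        doc = {
            "title": defn.title,
            "field_names": list(defn.field_names),
            "rows": rows,
            "creator": defn.creator,
            "parameters": defn.parameters,
            "description": defn.description,
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    def import_json(
        self, doc: str, application: str, timestamp: Optional[str] = None
    ) -> int:
        data = json.loads(doc)
        return self.create_dataset(
            data["creator"],
            data["title"],
            data["field_names"],
            data["rows"],
            application=application,
            parameters=data.get("parameters", ""),
            description=data.get("description", ""),
            timestamp=timestamp,
        )

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _check_arity(field_names: Sequence[str], rows: Sequence[Sequence]) -> None:
        for i, r in enumerate(rows):
            if len(r) != len(field_names):
                raise ValueError(
                    f"row {i} has {len(r)} values, expected {len(field_names)}"
                )

    def _rows(self, dataset_id: int) -> List[List]:
        cur = self.conn.execute(
            'SELECT "values" FROM data_row WHERE dataset_id = ? ORDER BY row_index',
            (dataset_id,),
        )
        return [json.loads(r[0]) for r in cur]

    def _insert_rows(self, dataset_id: int, rows: Sequence[Sequence], start: int) -> None:
        self.conn.executemany(
            'INSERT INTO data_row (dataset_id, row_index, "values") VALUES (?, ?, ?)',
            [(dataset_id, start + i, json.dumps(list(r))) for i, r in enumerate(rows)],
        )

    def _append_event(
        self,
        dataset_id: int,
        application: str,
        change_type: str,
        parameters: str,
        payload: Dict,
        timestamp: str,
    ) -> None:
        seq = self.conn.execute(
            "SELECT COALESCE(MAX(sequence_number) + 1, 1) FROM update_history "
            "WHERE dataset_id = ?",
            (dataset_id,),
        ).fetchone()[0]
        self.conn.execute(
            "INSERT INTO update_history "
            "(dataset_id, sequence_number, application, change_type, parameters, "
            "payload, timestamp) VALUES (?, ?, ?, ?, ?, ?, ?)",
            (dataset_id, seq, application, change_type, parameters,
             json.dumps(payload), timestamp),
        )
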