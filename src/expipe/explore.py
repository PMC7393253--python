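"""Read-only exploration: index, filter, summarize, CSV export.

``build_index`` flattens every action's common attributes into one row per
action (module *contents* stay out of the table — only counts are indexed;
deep metadata queries call for custom scripts over the modules themselves).
Rows can be filtered with a :class:`QuerySpec` and written to RFC-4180 CSV
for downstream tools such as pandas.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, fields as dataclass_fields
from datetime import datetime
from pathlib import Path
from typing import Optional

from .exceptions import ExpipeError, ParseError, StorageError
from .identifiers import format_datetime, normalize_datetime
from .project import Project

__all__ = [
    "ActionIndexRow",
    "QuerySpec",
    "build_index",
    "filter_actions",
    "export_csv",
    "load_csv",
    "summarize",
    "index_to_dataframe",
]

JOIN = ";"  # intra-field separator for multi-valued columns


@dataclass
class ActionIndexRow:
    """One action flattened to scalar columns.

    Multi-valued fields are ``;``-joined in sorted order; absent scalars are
    empty strings.  ``note`` is normally empty and carries a parse-error
    message for actions whose metadata files are corrupt.
    """

    id: str
    type: str = ""
    location: str = ""
    datetime: str = ""
    tags: str = ""
    users: str = ""
    entities: str = ""
    n_modules: int = 0
    n_messages: int = 0
    data_keys: str = ""
    note: str = ""

    @staticmethod
    def columns() -> list[str]:
        return [f.name for f in dataclass_fields(ActionIndexRow)]


def _join(values) -> str:
    return JOIN.join(sorted(values))


def _split(joined: str) -> set[str]:
    return set(joined.split(JOIN)) if joined else set()


def build_index(project: Project) -> list[ActionIndexRow]:
    """One row per action, lexicographic by id; never mutates the project.

    A corrupt attributes file yields a row with the parse error in ``note``
    rather than aborting the whole index.
    """
    rows = []
    for id in project.actions:
        try:
            action = project.actions[id]
            attrs = action._read_attrs()
            dt = attrs.get("datetime")
            rows.append(
                ActionIndexRow(
                    id=id,
                    type=attrs.get("type") or "",
                    location=attrs.get("location") or "",
                    datetime="" if dt is None else format_datetime(normalize_datetime(dt)),
                    tags=_join(attrs.get("tags") or []),
                    users=_join(attrs.get("users") or []),
                    entities=_join(attrs.get("entities") or []),
                    n_modules=len(action.modules),
                    n_messages=len(action.messages),
                    data_keys=_join((attrs.get("data") or {}).keys()),
                )
            )
        except (ParseError, ExpipeError) as exc:
            rows.append(ActionIndexRow(id=id, note=f"parse error: {exc}"))
    return rows


@dataclass
class QuerySpec:
    """Conjunctive filter over the action index.

    An empty spec matches everything; populated criteria AND together.
    ``*_any`` fields match when the action shares at least one value,
    ``tags_all`` requires all listed tags, the datetime bounds are
    inclusive (actions without a datetime never match a bounded query).
    """

    tags_any: Optional[set] = None
    tags_all: Optional[set] = None
    users_any: Optional[set] = None
    entities_any: Optional[set] = None
    datetime_from: Optional[datetime] = None
    datetime_to: Optional[datetime] = None
    type_equals: Optional[str] = None

    def matches(self, row: ActionIndexRow) -> bool:
        if self.datetime_from is not None and self.datetime_to is not None:
            if self.datetime_from > self.datetime_to:
                raise ExpipeError("empty interval: datetime_from is after datetime_to")
        tags = _split(row.tags)
        if self.tags_any is not None and not (tags & set(self.tags_any)):
            return False
        if self.tags_all is not None and not set(self.tags_all) <= tags:
            return False
        if self.users_any is not None and not (_split(row.users) & set(self.users_any)):
            return False
        if self.entities_any is not None and not (
            _split(row.entities) & set(self.entities_any)
        ):
            return False
        if self.datetime_from is not None or self.datetime_to is not None:
            if not row.datetime:
                return False
            dt = normalize_datetime(row.datetime)
            if self.datetime_from is not None and dt < self.datetime_from:
                return False
            if self.datetime_to is not None and dt > self.datetime_to:
                return False
        if self.type_equals is not None and row.type != self.type_equals:
            return False
        return True


def filter_actions(index: list[ActionIndexRow], query: QuerySpec) -> list[str]:
    """Ids of the rows satisfying every populated criterion, index order."""
    if (
        query.datetime_from is not None
        and query.datetime_to is not None
        and query.datetime_from > query.datetime_to
    ):
        raise ExpipeError("empty interval: datetime_from is after datetime_to")
    return [row.id for row in index if query.matches(row)]


def export_csv(index: list[ActionIndexRow], destination: str | os.PathLike) -> None:
    """Write the index as RFC-4180 CSV (header + one row per action).

    UTF-8, LF line endings; fields containing comma, quote or newline are
    quoted, so the file re-parses to the same table.
    """
    text = _render_csv(index)
    try:
        Path(destination).write_text(text, encoding="utf-8", newline="")
    except OSError as exc:
        raise StorageError(f"storage error: cannot write {destination}: {exc}") from exc


def _render_csv(index: list[ActionIndexRow]) -> str:
    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(ActionIndexRow.columns())
    for row in index:
        writer.writerow(
            [getattr(row, col) for col in ActionIndexRow.columns()]
        )
    return buffer.getvalue()


def load_csv(source: str | os.PathLike) -> list[ActionIndexRow]:
    """Parse a CSV written by :func:`export_csv` back into rows."""
    with open(source, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ActionIndexRow.columns():
            raise ParseError(f"unexpected CSV header: {header}")
        rows = []
        for record in reader:
            values = dict(zip(header, record))
            values["n_modules"] = int(values["n_modules"])
            values["n_messages"] = int(values["n_messages"])
            rows.append(ActionIndexRow(**values))
    return rows


def summarize(project: Project) -> dict[str, int]:
    """Whole-project counts: objects, messages and registered data keys."""
    actions = project.actions
    entities = project.entities
    total_messages = sum(len(a.messages) for a in actions.values())
    total_messages += sum(len(e.messages) for e in entities.values())
    total_data_keys = sum(len(a.data) for a in actions.values())
    return {
        "actions": len(actions),
        "entities": len(entities),
        "templates": len(project.templates),
        "project_modules": len(project.modules),
        "messages": total_messages,
        "data_keys": total_data_keys,
    }


def index_to_dataframe(index: list[ActionIndexRow]):
    """The index as a pandas DataFrame (one row per action)."""
    import pandas as pd

    return pd.DataFrame(
        [[getattr(r, c) for c in ActionIndexRow.columns()] for r in index],
        columns=ActionIndexRow.columns(),
    )
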