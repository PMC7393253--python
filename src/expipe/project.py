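"""User-facing object API.

A :class:`Project` is a handle on a project root.  It owns mapping-style
collections of :class:`Action`, :class:`Entity`, :class:`Template` and
project-level :class:`Module` objects.  Every mutation is write-through —
setters persist before returning and reads go back to the store — so two
handles on the same root always observe each other's committed writes, and
files edited by hand in a text editor are picked up on the next access.

Actions and entities share the common attributes ``tags``, ``users``,
``location``, ``type`` and ``datetime``; actions additionally carry an
``entities`` reference list and a ``data`` registry mapping string keys to
payload locators.  Referential integrity between actions and entities is
deliberately relaxed: an action may name entities that do not (or no
longer) exist.
"""

from __future__ import annotations

import copy
import os
import re
from collections.abc import Mapping as MappingABC
from datetime import datetime
from pathlib import Path, PurePosixPath
from typing import Any, Iterator, Mapping, Optional

from .backend import FilesystemBackend, ObjectKind, StorageBackend
from .exceptions import (
    ExpipeError,
    NotAProjectError,
    ObjectExistsError,
    ObjectNotFoundError,
)
from .identifiers import format_datetime, normalize_datetime, validate_identifier

__all__ = [
    "Project",
    "Action",
    "Entity",
    "Module",
    "Template",
    "Message",
    "create_project",
    "get_project",
    "require_project",
    "set_attribute",
    "delete_object",
]

#: attribute fields common to actions and entities, in storage order
COMMON_FIELDS = ("type", "location", "datetime", "tags", "users")
ACTION_ONLY_FIELDS = ("entities",)
_DATA_KEY = "data"  # reserved key in an action's attributes.yaml

_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://")


# ---------------------------------------------------------------------------
# attribute normalization


def _normalize_string_set(value, field: str) -> list[str]:
    if isinstance(value, str):
        raise ExpipeError(f"{field} must be a collection of strings, not a bare string")
    items = set()
    for item in value:
        if not isinstance(item, str) or item == "":
            raise ExpipeError(f"{field} entries must be non-empty strings, got {item!r}")
        items.add(item)
    return sorted(items)


def _normalize_field(field: str, value, kind: ObjectKind):
    if field in ("tags", "users"):
        return _normalize_string_set(value or (), field)
    if field in ("location", "type"):
        if value is not None and not isinstance(value, str):
            raise ExpipeError(f"{field} must be a string or None")
        return value
    if field == "datetime":
        return None if value is None else format_datetime(normalize_datetime(value))
    if field == "entities":
        if kind is not ObjectKind.ACTION:
            raise ExpipeError("attribute not applicable: entities is action-only")
        return [validate_identifier(e) for e in (value or [])]
    raise ExpipeError(f"unknown attribute: {field!r}")


def _empty_attributes(kind: ObjectKind) -> dict[str, Any]:
    attrs: dict[str, Any] = {"type": None, "location": None, "datetime": None,
                             "tags": [], "users": []}
    if kind is ObjectKind.ACTION:
        attrs["entities"] = []
        attrs[_DATA_KEY] = {}
    return attrs


# ---------------------------------------------------------------------------
# collections


class MapView(MappingABC):
    """Read-only mapping view over a collection of stored objects.

    Supports ``in``, ``[]``, ``keys()``, ``values()``, ``items()`` and
    ``len()``; iteration order is lexicographic by identifier.
    """

    def __init__(self, project: "Project", kind: ObjectKind, owner, factory):
        self._project = project
        self._kind = kind
        self._owner = owner
        self._factory = factory

    def _ids(self) -> list[str]:
        return sorted(self._project._backend.list_ids(self._kind, self._owner))

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids())

    def __len__(self) -> int:
        return len(self._ids())

    def __contains__(self, id: object) -> bool:
        return isinstance(id, str) and self._project._backend.record_exists(
            self._kind, self._owner, id
        )

    def __getitem__(self, id: str):
        if id not in self:
            raise ObjectNotFoundError(f"not found: {self._kind.value} {id!r}")
        return self._factory(id)

    def __repr__(self) -> str:
        return f"<{self._kind.value} collection: {self._ids()}>"


# ---------------------------------------------------------------------------
# modules, templates, messages


class Module:
    """A nested key-value metadata record stored as one YAML file.

    ``contents`` reads from the store on every access; assignments (whole
    contents, single key, or a nested key path) persist immediately.
    """

    _kind = ObjectKind.MODULE

    def __init__(self, backend: StorageBackend, owner, name: str):
        self._backend = backend
        self._owner = owner
        self.name = name

    @property
    def contents(self) -> dict[str, Any]:
        return self._backend.read_record(self._kind, self._owner, self.name)

    @contents.setter
    def contents(self, value: Mapping[str, Any]) -> None:
        self._backend.write_record(self._kind, self._owner, self.name, value)

    def __getitem__(self, key: str):
        return self.contents[key]

    def __setitem__(self, key: str, value) -> None:
        self.update_key([key], value)

    def update_key(self, key_path: list[str], value) -> None:
        """Set *value* at a nested key path, creating intermediate mappings.

        Raises :class:`PathConflictError` if an intermediate key already
        holds a non-mapping value.
        """
        from .exceptions import PathConflictError

        if not key_path:
            raise ExpipeError("key_path must be non-empty")
        contents = self.contents
        node = contents
        for key in key_path[:-1]:
            if key not in node:
                node[key] = {}
            elif not isinstance(node[key], dict):
                raise PathConflictError(
                    f"path conflict: {key!r} holds a {type(node[key]).__name__}, not a mapping"
                )
            node = node[key]
        node[key_path[-1]] = value
        self.contents = contents

    def __eq__(self, other) -> bool:
        return isinstance(other, Module) and self.contents == other.contents

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.name!r}>"


class Template(Module):
    """A predefined module blueprint stored at project level.

    Instantiating a template deep-copies (snapshots) its contents into a new
    module; no link is retained, so later edits to either side never affect
    the other.
    """

    _kind = ObjectKind.TEMPLATE


class Message:
    """A timestamped, user-attributed note — a virtual lab-notebook entry.

    Messages are immutable once written; to edit, delete and re-add.
    """

    def __init__(self, id: str, text: str, user: str, datetime: datetime):
        self.id = id
        self.text = text
        self.user = user
        self.datetime = datetime

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Message)
            and (self.text, self.user, self.datetime) == (other.text, other.user, other.datetime)
        )

    def __repr__(self) -> str:
        return f"<Message {self.datetime.isoformat()} {self.user!r}: {self.text!r}>"


def _message_stamp(dt: datetime) -> str:
    return dt.strftime("%Y%m%dT%H%M%S.%f")


# ---------------------------------------------------------------------------
# actions and entities


class _BaseObject:
    """Shared behavior of actions and entities (attributes, modules, messages)."""

    kind: ObjectKind

    def __init__(self, project: "Project", id: str):
        self.project = project
        self.id = id
        self._backend = project._backend
        self._owner = (self.kind, id)

    # -- attributes ------------------------------------------------------

    def _read_attrs(self) -> dict[str, Any]:
        return self._backend.read_record(self.kind, None, self.id)

    def _write_attrs(self, attrs: Mapping[str, Any]) -> None:
        self._backend.write_record(self.kind, None, self.id, attrs)

    def _set_field(self, field: str, value) -> None:
        normalized = _normalize_field(field, value, self.kind)
        attrs = _empty_attributes(self.kind)
        attrs.update(self._read_attrs())
        attrs[field] = normalized
        self._write_attrs(attrs)

    @property
    def tags(self) -> set[str]:
        return set(self._read_attrs().get("tags") or [])

    @tags.setter
    def tags(self, value) -> None:
        self._set_field("tags", value)

    @property
    def users(self) -> set[str]:
        return set(self._read_attrs().get("users") or [])

    @users.setter
    def users(self, value) -> None:
        self._set_field("users", value)

    @property
    def location(self) -> Optional[str]:
        return self._read_attrs().get("location")

    @location.setter
    def location(self, value) -> None:
        self._set_field("location", value)

    @property
    def type(self) -> Optional[str]:
        return self._read_attrs().get("type")

    @type.setter
    def type(self, value) -> None:
        self._set_field("type", value)

    @property
    def datetime(self) -> Optional[datetime]:
        raw = self._read_attrs().get("datetime")
        return None if raw is None else normalize_datetime(raw)

    @datetime.setter
    def datetime(self, value) -> None:
        self._set_field("datetime", value)

    # -- modules ---------------------------------------------------------

    @property
    def modules(self) -> MapView:
        return MapView(
            self.project,
            ObjectKind.MODULE,
            self._owner,
            lambda name: Module(self._backend, self._owner, name),
        )

    def create_module(
        self,
        name: Optional[str] = None,
        contents: Optional[Mapping[str, Any]] = None,
        template: Optional[str] = None,
    ) -> Module:
        return _create_module(self.project, self._owner, name, contents, template)

    def delete_module(self, name: str) -> None:
        self._backend.delete_record(ObjectKind.MODULE, self._owner, name)

    # -- messages --------------------------------------------------------

    @property
    def messages(self) -> MapView:
        return MapView(self.project, ObjectKind.MESSAGE, self._owner, self._load_message)

    def _load_message(self, id: str) -> Message:
        payload = self._backend.read_record(ObjectKind.MESSAGE, self._owner, id)
        return Message(
            id=id,
            text=payload.get("text", ""),
            user=payload.get("user", ""),
            datetime=normalize_datetime(payload["datetime"]),
        )

    def create_message(
        self, text: str, user: str, datetime: Optional[datetime | str] = None
    ) -> Message:
        """Persist a message; the timestamp defaults to the creation time."""
        if not text:
            raise ExpipeError("empty message")
        from datetime import datetime as _dt

        dt = normalize_datetime(datetime) if datetime is not None else _dt.now()
        stamp = _message_stamp(dt)
        id = stamp
        suffix = 0
        while self._backend.record_exists(ObjectKind.MESSAGE, self._owner, id):
            suffix += 1
            id = f"{stamp}-{suffix}"
        payload = {"text": text, "user": user, "datetime": format_datetime(dt)}
        self._backend.write_record(ObjectKind.MESSAGE, self._owner, id, payload)
        return Message(id=id, text=text, user=user, datetime=dt)

    def delete_message(self, id: str) -> None:
        self._backend.delete_record(ObjectKind.MESSAGE, self._owner, id)

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.id!r}>"


class Entity(_BaseObject):
    """A long-lived thing used by actions, e.g. an experimental subject."""

    kind = ObjectKind.ENTITY


class Action(_BaseObject):
    """A timestamped event: an experiment, a surgery, an analysis run."""

    kind = ObjectKind.ACTION

    @property
    def entities(self) -> list[str]:
        return list(self._read_attrs().get("entities") or [])

    @entities.setter
    def entities(self, value) -> None:
        self._set_field("entities", value)

    # -- data registry ---------------------------------------------------

    @property
    def data(self) -> dict[str, str]:
        return dict(self._read_attrs().get(_DATA_KEY) or {})

    def register_data(self, key: str, locator: str) -> None:
        """Map *key* to a payload locator, stored verbatim.

        A locator is either a path relative to the action's ``data`` folder,
        an absolute path, or any opaque string such as a server URI.  The
        target's existence is deliberately unchecked; relative locators that
        would escape the data folder are rejected.
        """
        if not key or not isinstance(key, str):
            raise ExpipeError("data key must be a non-empty string")
        if not locator or not isinstance(locator, str):
            raise ExpipeError("data locator must be a non-empty string")
        if not _URI_RE.match(locator) and not os.path.isabs(locator):
            parts = PurePosixPath(os.path.normpath(locator)).parts
            if parts and parts[0] == "..":
                raise ExpipeError(
                    f"data locator {locator!r} escapes the action's data folder"
                )
        attrs = _empty_attributes(self.kind)
        attrs.update(self._read_attrs())
        data = dict(attrs.get(_DATA_KEY) or {})
        data[key] = locator
        attrs[_DATA_KEY] = data
        self._write_attrs(attrs)

    def data_path(self, key: str) -> Path | str:
        """Resolve a data key to an absolute path.

        Relative locators resolve under ``actions/<id>/data/``; absolute
        paths come back as :class:`~pathlib.Path` unchanged; URI-like
        locators are returned as the stored string.
        """
        data = self.data
        if key not in data:
            raise ObjectNotFoundError(f"data key not found: {key!r}")
        locator = data[key]
        if _URI_RE.match(locator):
            return locator
        if os.path.isabs(locator):
            return Path(locator)
        backend = self._backend
        if isinstance(backend, FilesystemBackend):
            return (backend.data_dir(self.kind, self.id) / locator).absolute()
        return Path(locator)


# ---------------------------------------------------------------------------
# module creation (shared by project / action / entity)


def _create_module(project, owner, name, contents, template) -> Module:
    backend = project._backend
    if template is not None:
        if not backend.record_exists(ObjectKind.TEMPLATE, None, template):
            raise ObjectNotFoundError(f"template not found: {template!r}")
        snapshot = backend.read_record(ObjectKind.TEMPLATE, None, template)
        if contents is not None:
            raise ExpipeError("pass either contents or template, not both")
        contents = copy.deepcopy(snapshot)
        name = name if name is not None else template
    if name is None:
        raise ExpipeError("a module needs a name (or a template to take it from)")
    validate_identifier(name)
    if backend.record_exists(ObjectKind.MODULE, owner, name):
        raise ObjectExistsError(f"module exists: {name!r}")
    backend.write_record(ObjectKind.MODULE, owner, name, contents or {})
    return Module(backend, owner, name)


# ---------------------------------------------------------------------------
# project


class Project:
    """Handle on one project root.

    Collections (``actions``, ``entities``, ``templates``, ``modules``)
    behave as read-only mappings keyed by identifier; creation goes through
    the ``create_*`` methods and everything persists write-through.
    """

    def __init__(self, path: str | os.PathLike, backend: Optional[StorageBackend] = None):
        self.path = Path(path)
        self._backend = backend if backend is not None else FilesystemBackend(self.path)

    # -- collections -----------------------------------------------------

    @property
    def actions(self) -> MapView:
        return MapView(self, ObjectKind.ACTION, None, lambda id: Action(self, id))

    @property
    def entities(self) -> MapView:
        return MapView(self, ObjectKind.ENTITY, None, lambda id: Entity(self, id))

    @property
    def templates(self) -> MapView:
        return MapView(
            self, ObjectKind.TEMPLATE, None, lambda id: Template(self._backend, None, id)
        )

    @property
    def modules(self) -> MapView:
        return MapView(
            self, ObjectKind.MODULE, None, lambda id: Module(self._backend, None, id)
        )

    # -- creation --------------------------------------------------------

    def create_action(self, id: str) -> Action:
        validate_identifier(id)
        if self._backend.record_exists(ObjectKind.ACTION, None, id):
            raise ObjectExistsError(f"action exists: {id!r}")
        self._backend.write_record(ObjectKind.ACTION, None, id,
                                   _empty_attributes(ObjectKind.ACTION))
        return Action(self, id)

    def create_entity(self, id: str) -> Entity:
        validate_identifier(id)
        if self._backend.record_exists(ObjectKind.ENTITY, None, id):
            raise ObjectExistsError(f"entity exists: {id!r}")
        self._backend.write_record(ObjectKind.ENTITY, None, id,
                                   _empty_attributes(ObjectKind.ENTITY))
        return Entity(self, id)

    def create_template(self, name: str, contents: Optional[Mapping[str, Any]] = None) -> Template:
        validate_identifier(name)
        if self._backend.record_exists(ObjectKind.TEMPLATE, None, name):
            raise ObjectExistsError(f"template exists: {name!r}")
        self._backend.write_record(ObjectKind.TEMPLATE, None, name, contents or {})
        return Template(self._backend, None, name)

    def create_module(
        self,
        name: Optional[str] = None,
        contents: Optional[Mapping[str, Any]] = None,
        template: Optional[str] = None,
    ) -> Module:
        return _create_module(self, None, name, contents, template)

    # -- deletion --------------------------------------------------------

    def delete_action(self, id: str) -> None:
        self._backend.delete_record(ObjectKind.ACTION, None, id)

    def delete_entity(self, id: str) -> None:
        """Remove an entity.  References from actions are left dangling —
        integrity between objects is deliberately relaxed."""
        self._backend.delete_record(ObjectKind.ENTITY, None, id)

    def delete_template(self, name: str) -> None:
        self._backend.delete_record(ObjectKind.TEMPLATE, None, name)

    def delete_module(self, name: str) -> None:
        self._backend.delete_record(ObjectKind.MODULE, None, name)

    def __repr__(self) -> str:
        return f"<Project {self.path}>"


# ---------------------------------------------------------------------------
# module-level API


def create_project(path: str | os.PathLike) -> Project:
    """Create a new project at *path* and return its handle."""
    path = Path(path)
    validate_identifier(path.name)
    backend = FilesystemBackend(path)
    backend.init_store()
    return Project(path, backend)


def get_project(path: str | os.PathLike) -> Project:
    """Open an existing project; raises :class:`NotAProjectError` otherwise."""
    backend = FilesystemBackend(path)
    if not backend.is_initialized():
        raise NotAProjectError(f"not an expipe project: {path}")
    return Project(path, backend)


def require_project(path: str | os.PathLike) -> Project:
    """Open the project at *path*, creating it first if it does not exist."""
    backend = FilesystemBackend(path)
    if backend.is_initialized():
        return Project(path, backend)
    p = Path(path)
    if p.exists() and any(p.iterdir()):
        raise NotAProjectError(f"not an expipe project: {path} (non-empty directory)")
    return create_project(path)


def set_attribute(obj: _BaseObject, field: str, value) -> None:
    """Set a common attribute (``tags``/``users``/``location``/``type``/
    ``datetime``/``entities``) on an action or entity by field name."""
    if field not in COMMON_FIELDS + ACTION_ONLY_FIELDS:
        raise ExpipeError(f"unknown attribute: {field!r}")
    obj._set_field(field, value)


def delete_object(project: Project, kind: ObjectKind | str, id: str) -> None:
    """Delete an action, entity, template or project module by kind and id."""
    kind = ObjectKind(kind) if isinstance(kind, str) else kind
    dispatch = {
        ObjectKind.ACTION: project.delete_action,
        ObjectKind.ENTITY: project.delete_entity,
        ObjectKind.TEMPLATE: project.delete_template,
        ObjectKind.MODULE: project.delete_module,
    }
    if kind not in dispatch:
        raise ExpipeError(f"cannot delete objects of kind {kind.value!r}")
    dispatch[kind](id)
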