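"""Storage backends.

The object model is persisted through a small key-value storage contract:
records are addressed by ``(kind, owner, id)`` where *owner* is ``None`` for
top-level records (actions, entities, templates, project modules) and an
``(ObjectKind, id)`` pair for modules/messages attached to an action or
entity.  Record payloads are plain string-keyed mappings.

The default backend maps this contract onto a conventional directory tree of
YAML files::

    root/expipe.yaml                      project marker + format version
    root/attributes.yaml                  project attributes
    root/modules/<name>.yaml              project modules
    root/templates/<name>.yaml            templates
    root/actions/<id>/attributes.yaml
    root/actions/<id>/modules/<name>.yaml
    root/actions/<id>/messages/<stamp>.yaml
    root/actions/<id>/data/**             opaque payload files
    root/entities/<id>/{attributes.yaml, modules/, messages/}

All files are plain UTF-8 text with LF endings and contain no absolute
paths, so a project tree can be moved, synced or version-controlled as-is.
Writes are atomic (temp file + rename): a crash never leaves a half-written
file.  An in-memory backend implements the same contract and serves as the
conformance reference for the filesystem one.
"""

from __future__ import annotations

import copy
import enum
import logging
import os
import tempfile
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Any, Mapping, Optional, Tuple

from .exceptions import (
    ObjectNotFoundError,
    ParseError,
    ProjectExistsError,
    StorageError,
)
from .identifiers import validate_identifier
from .serialize import deserialize_mapping, serialize_mapping

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectKind",
    "StorageBackend",
    "FilesystemBackend",
    "MemoryBackend",
    "PROJECT_MARKER",
    "FORMAT_VERSION",
    "audit_project_tree",
]

PROJECT_MARKER = "expipe.yaml"
FORMAT_VERSION = "1"

Owner = Optional[Tuple["ObjectKind", str]]


class ObjectKind(enum.Enum):
    """The closed set of record kinds in a project."""

    PROJECT = "project"
    ACTION = "action"
    ENTITY = "entity"
    TEMPLATE = "template"
    MODULE = "module"
    MESSAGE = "message"


#: kinds that own sub-records (modules, messages) and a data folder
_CONTAINER_KINDS = (ObjectKind.ACTION, ObjectKind.ENTITY)
_KIND_DIR = {ObjectKind.ACTION: "actions", ObjectKind.ENTITY: "entities"}


def _check_address(kind: ObjectKind, owner: Owner) -> None:
    if kind in (ObjectKind.MODULE, ObjectKind.MESSAGE):
        if owner is not None and owner[0] not in _CONTAINER_KINDS:
            raise StorageError(
                f"invalid record address: {kind.value} cannot be owned by {owner[0].value}"
            )
        if kind is ObjectKind.MESSAGE and owner is None:
            raise StorageError("invalid record address: a message requires an owner")
    elif owner is not None:
        raise StorageError(
            f"invalid record address: {kind.value} records take no owner"
        )


class StorageBackend(ABC):
    """Abstract key-value storage contract.

    Conformance: after ``write_record(k, o, i, p)``, ``read_record(k, o, i)``
    returns a mapping structurally equal to ``p``; ``list_ids(k, o)``
    reflects exactly the set of written, undeleted ids.
    """

    @abstractmethod
    def init_store(self) -> None:
        """Create an empty project store.  Fails if one already exists."""

    @abstractmethod
    def is_initialized(self) -> bool:
        ...

    @abstractmethod
    def read_record(self, kind: ObjectKind, owner: Owner, id: str) -> dict[str, Any]:
        ...

    @abstractmethod
    def write_record(
        self, kind: ObjectKind, owner: Owner, id: str, payload: Mapping[str, Any]
    ) -> None:
        ...

    @abstractmethod
    def delete_record(self, kind: ObjectKind, owner: Owner, id: str) -> None:
        """Remove a record (and, for actions/entities, everything it owns)."""

    @abstractmethod
    def list_ids(self, kind: ObjectKind, owner: Owner = None) -> set[str]:
        ...

    @abstractmethod
    def record_exists(self, kind: ObjectKind, owner: Owner, id: str) -> bool:
        ...


class FilesystemBackend(StorageBackend):
    """YAML-files-in-a-directory-tree backend (the default)."""

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)

    # -- path resolution -------------------------------------------------

    def _record_path(self, kind: ObjectKind, owner: Owner, id: str) -> Path:
        _check_address(kind, owner)
        if kind is ObjectKind.PROJECT:
            return self.root / "attributes.yaml"
        if kind in _CONTAINER_KINDS:
            return self.root / _KIND_DIR[kind] / id / "attributes.yaml"
        if kind is ObjectKind.TEMPLATE:
            return self.root / "templates" / f"{id}.yaml"
        if kind is ObjectKind.MODULE:
            base = self.root if owner is None else self._owner_dir(owner)
            return base / "modules" / f"{id}.yaml"
        # message
        return self._owner_dir(owner) / "messages" / f"{id}.yaml"

    def _owner_dir(self, owner: Tuple[ObjectKind, str]) -> Path:
        kind, oid = owner
        return self.root / _KIND_DIR[kind] / oid

    def data_dir(self, kind: ObjectKind, id: str) -> Path:
        return self.root / _KIND_DIR[kind] / id / "data"

    # -- contract --------------------------------------------------------

    def init_store(self) -> None:
        marker = self.root / PROJECT_MARKER
        if marker.exists():
            raise ProjectExistsError(f"project exists: {self.root}")
        try:
            self.root.mkdir(parents=True, exist_ok=True)
            for sub in ("actions", "entities", "templates", "modules"):
                (self.root / sub).mkdir(exist_ok=True)
            self._atomic_write(
                marker, serialize_mapping({"type": "project", "version": FORMAT_VERSION})
            )
            self._atomic_write(self.root / "attributes.yaml", serialize_mapping({}))
        except OSError as exc:
            raise StorageError(f"storage error: cannot initialize {self.root}: {exc}") from exc

    def is_initialized(self) -> bool:
        marker = self.root / PROJECT_MARKER
        if not marker.is_file():
            return False
        try:
            deserialize_mapping(marker.read_text(encoding="utf-8"))
        except (ParseError, OSError):
            return False
        return True

    def read_record(self, kind: ObjectKind, owner: Owner, id: str) -> dict[str, Any]:
        path = self._record_path(kind, owner, id)
        if not path.is_file():
            raise ObjectNotFoundError(f"not found: {kind.value} {id!r}")
        try:
            text = path.read_text(encoding="utf-8")
        except OSError as exc:
            raise StorageError(f"storage error: cannot read {path}: {exc}") from exc
        return deserialize_mapping(text)

    def write_record(
        self, kind: ObjectKind, owner: Owner, id: str, payload: Mapping[str, Any]
    ) -> None:
        path = self._record_path(kind, owner, id)
        if owner is not None and not self._owner_dir(owner).is_dir():
            raise ObjectNotFoundError(f"owner not found: {owner[0].value} {owner[1]!r}")
        text = serialize_mapping(payload)
        try:
            path.parent.mkdir(parents=True, exist_ok=True)
            if kind in _CONTAINER_KINDS:
                # actions/entities get their data folder up front
                (path.parent / "data").mkdir(exist_ok=True)
            self._atomic_write(path, text)
        except OSError as exc:
            raise StorageError(f"storage error: cannot write {path}: {exc}") from exc

    def delete_record(self, kind: ObjectKind, owner: Owner, id: str) -> None:
        path = self._record_path(kind, owner, id)
        if not path.is_file():
            raise ObjectNotFoundError(f"not found: {kind.value} {id!r}")
        if kind in _CONTAINER_KINDS:
            _rmtree(path.parent)
        else:
            path.unlink()

    def list_ids(self, kind: ObjectKind, owner: Owner = None) -> set[str]:
        _check_address(kind, owner)
        if kind in _CONTAINER_KINDS:
            base = self.root / _KIND_DIR[kind]
            return self._scan(base, want_dirs=True)
        if kind is ObjectKind.TEMPLATE:
            return self._scan(self.root / "templates", want_dirs=False)
        if kind in (ObjectKind.MODULE, ObjectKind.MESSAGE):
            sub = "modules" if kind is ObjectKind.MODULE else "messages"
            if owner is None:
                base = self.root / sub
            else:
                owner_dir = self._owner_dir(owner)
                if not owner_dir.is_dir():
                    raise ObjectNotFoundError(
                        f"owner not found: {owner[0].value} {owner[1]!r}"
                    )
                base = owner_dir / sub
            return self._scan(base, want_dirs=False)
        raise StorageError(f"invalid record address: cannot list {kind.value}")

    def record_exists(self, kind: ObjectKind, owner: Owner, id: str) -> bool:
        return self._record_path(kind, owner, id).is_file()

    # -- helpers ---------------------------------------------------------

    def _scan(self, base: Path, want_dirs: bool) -> set[str]:
        if not base.is_dir():
            return set()
        found = set()
        for entry in base.iterdir():
            if want_dirs:
                if not entry.is_dir():
                    continue
                name = entry.name
            else:
                if not entry.is_file() or not entry.name.endswith(".yaml"):
                    continue
                name = entry.name[: -len(".yaml")]
            try:
                validate_identifier(name)
            except Exception:
                logger.warning("ignoring %s: name violates identifier grammar", entry)
                continue
            found.add(name)
        return found

    @staticmethod
    def _atomic_write(path: Path, text: str) -> None:
        fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
        try:
            with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text)
            os.replace(tmp, path)
        except BaseException:
            try:
                os.unlink(tmp)
            except OSError:
                pass
            raise


class MemoryBackend(StorageBackend):
    """In-memory reference backend used for conformance testing.

    Keeps records in a flat dict keyed by ``(kind, owner, id)`` with deep
    copies on read and write, mirroring the copy semantics of a file store.
    """

    def __init__(self):
        self._records: dict[tuple, dict[str, Any]] = {}
        self._initialized = False

    def init_store(self) -> None:
        if self._initialized:
            raise ProjectExistsError("project exists")
        self._initialized = True
        self._records[(ObjectKind.PROJECT, None, "attributes")] = {}

    def is_initialized(self) -> bool:
        return self._initialized

    def _key(self, kind: ObjectKind, owner: Owner, id: str) -> tuple:
        _check_address(kind, owner)
        if kind is ObjectKind.PROJECT:
            return (kind, None, "attributes")
        return (kind, owner, id)

    def _owner_exists(self, owner: Tuple[ObjectKind, str]) -> bool:
        return (owner[0], None, owner[1]) in self._records

    def read_record(self, kind: ObjectKind, owner: Owner, id: str) -> dict[str, Any]:
        key = self._key(kind, owner, id)
        if key not in self._records:
            raise ObjectNotFoundError(f"not found: {kind.value} {id!r}")
        return copy.deepcopy(self._records[key])

    def write_record(
        self, kind: ObjectKind, owner: Owner, id: str, payload: Mapping[str, Any]
    ) -> None:
        key = self._key(kind, owner, id)
        if owner is not None and not self._owner_exists(owner):
            raise ObjectNotFoundError(f"owner not found: {owner[0].value} {owner[1]!r}")
        serialize_mapping(payload)  # reject unserializable payloads like the fs does
        self._records[key] = copy.deepcopy(dict(payload))

    def delete_record(self, kind: ObjectKind, owner: Owner, id: str) -> None:
        key = self._key(kind, owner, id)
        if key not in self._records:
            raise ObjectNotFoundError(f"not found: {kind.value} {id!r}")
        del self._records[key]
        if kind in _CONTAINER_KINDS:
            owned = [
                k for k in self._records if k[1] is not None and k[1] == (kind, id)
            ]
            for k in owned:
                del self._records[k]

    def list_ids(self, kind: ObjectKind, owner: Owner = None) -> set[str]:
        _check_address(kind, owner)
        if kind is ObjectKind.MESSAGE or (kind is ObjectKind.MODULE and owner is not None):
            if owner is not None and not self._owner_exists(owner):
                raise ObjectNotFoundError(
                    f"owner not found: {owner[0].value} {owner[1]!r}"
                )
        return {
            k[2]
            for k in self._records
            if k[0] is kind and k[1] == owner and k[0] is not ObjectKind.PROJECT
        }

    def record_exists(self, kind: ObjectKind, owner: Owner, id: str) -> bool:
        return self._key(kind, owner, id) in self._records


def _rmtree(path: Path) -> None:
    import shutil

    shutil.rmtree(path)


def audit_project_tree(root: str | os.PathLike) -> list[str]:
    """Validity audit of a project tree; returns a list of problems.

    Checks: the project marker parses; every action/entity/template/module/
    message name satisfies the identifier grammar; every metadata YAML file
    parses to a mapping.  An empty list means the tree is valid.
    """
    root = Path(root)
    problems: list[str] = []
    backend = FilesystemBackend(root)
    if not backend.is_initialized():
        return [f"{root}: missing or unparseable {PROJECT_MARKER}"]

    def check_yaml(path: Path) -> None:
        try:
            deserialize_mapping(path.read_text(encoding="utf-8"))
        except (ParseError, OSError) as exc:
            problems.append(f"{path}: {exc}")

    check_yaml(root / "attributes.yaml")
    for tpl in sorted((root / "templates").glob("*.yaml")):
        _check_name(tpl.stem, tpl, problems)
        check_yaml(tpl)
    for mod in sorted((root / "modules").glob("*.yaml")):
        _check_name(mod.stem, mod, problems)
        check_yaml(mod)
    for kind_dir in ("actions", "entities"):
        base = root / kind_dir
        if not base.is_dir():
            problems.append(f"{base}: missing directory")
            continue
        for obj_dir in sorted(p for p in base.iterdir() if p.is_dir()):
            _check_name(obj_dir.name, obj_dir, problems)
            attrs = obj_dir / "attributes.yaml"
            if attrs.is_file():
                check_yaml(attrs)
            else:
                problems.append(f"{attrs}: missing attributes.yaml")
            for sub in ("modules", "messages"):
                for f in sorted((obj_dir / sub).glob("*.yaml")):
                    _check_name(f.stem, f, problems)
                    check_yaml(f)
    return problems


def _check_name(name: str, where: Path, problems: list[str]) -> None:
    try:
        validate_identifier(name)
    except Exception as exc:
        problems.append(f"{where}: {exc}")
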