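"""YAML (de)serialization of module contents.

Module contents are arbitrary-depth string-keyed mappings whose leaves are
scalars, lists, or quantity records.  A mapping with exactly the two keys
``value`` and ``unit`` is the quantity convention (e.g. ``{value: 1, unit:
m}``); any other mapping is plain nesting.

Serialization is deterministic: equal contents always produce byte-identical
YAML (block style, insertion order, 2-space indent, UTF-8, trailing
newline), so re-saving unchanged metadata never dirties a version-controlled
file.  Only the safe YAML subset is read back — no object-construction tags.
"""

from __future__ import annotations

from datetime import date, datetime
from typing import Any, Mapping

import yaml

from .exceptions import ParseError, SerializationError

__all__ = ["Quantity", "is_quantity", "serialize_mapping", "deserialize_mapping"]

_SCALAR_TYPES = (str, int, float, bool, type(None), datetime, date)


class Quantity(dict):
    """A value with a free-form unit label, e.g. ``Quantity(1, "m")``.

    Stored as (and equal to) the plain mapping ``{"value": v, "unit": u}``,
    so round-tripping through YAML preserves equality either way.
    """

    def __init__(self, value: Any, unit: str):
        super().__init__(value=value, unit=unit)

    @property
    def value(self) -> Any:
        return self["value"]

    @property
    def unit(self) -> str:
        return self["unit"]

    def __repr__(self) -> str:
        return f"Quantity({self['value']!r}, {self['unit']!r})"


def is_quantity(obj: Any) -> bool:
    """True for any mapping with exactly the keys ``value`` and ``unit``."""
    return isinstance(obj, Mapping) and set(obj.keys()) == {"value", "unit"}


def _validate(node: Any, path: str) -> Any:
    """Check serializability and return a plain-type deep copy of *node*."""
    if isinstance(node, Mapping):
        out = {}
        for key, value in node.items():
            if not isinstance(key, str):
                raise SerializationError(
                    f"unserializable contents: non-string key {key!r} at {path or '<root>'}"
                )
            out[key] = _validate(value, f"{path}.{key}" if path else key)
        return out
    if isinstance(node, (list, tuple)):
        return [_validate(item, f"{path}[{i}]") for i, item in enumerate(node)]
    if isinstance(node, _SCALAR_TYPES):
        return node
    raise SerializationError(
        f"unserializable contents: {type(node).__name__} at {path or '<root>'}"
    )


def serialize_mapping(contents: Mapping[str, Any]) -> str:
    """Serialize module contents to deterministic YAML text.

    Raises :class:`SerializationError` for non-string keys or leaves outside
    the supported scalar set.
    """
    if not isinstance(contents, Mapping):
        raise SerializationError(
            f"unserializable contents: top level must be a mapping, got {type(contents).__name__}"
        )
    plain = _validate(contents, "")
    return yaml.safe_dump(
        plain,
        default_flow_style=False,
        sort_keys=False,
        allow_unicode=True,
        indent=2,
        width=2**31 - 1,
    )


def _revive_quantities(node: Any) -> Any:
    if isinstance(node, dict):
        revived = {k: _revive_quantities(v) for k, v in node.items()}
        if set(revived.keys()) == {"value", "unit"}:
            return Quantity(revived["value"], revived["unit"])
        return revived
    if isinstance(node, list):
        return [_revive_quantities(item) for item in node]
    return node


def deserialize_mapping(text: str) -> dict[str, Any]:
    """Parse YAML text into module contents.

    Only the safe subset is interpreted.  Two-key ``{value, unit}`` mappings
    come back as :class:`Quantity`.

    Raises
    ------
    ParseError
        For malformed YAML (with the line number) or a non-mapping top level.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ParseError(f"parse error{where}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParseError(
            f"module file must contain a mapping, found {type(data).__name__}"
        )
    return _revive_quantities(data)
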