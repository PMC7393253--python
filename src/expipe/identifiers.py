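"""Identifier grammar and datetime normalization.

Identifiers double as directory and file names, so the accepted grammar is
the portable-filename subset ``[A-Za-z0-9._-]{1,128}``, excluding the
reserved names ``.`` and ``..``.  Datetimes are stored timezone-naive in
ISO-8601 (``YYYY-MM-DDTHH:MM:SS[.ffffff]``) at microsecond resolution.
"""

from __future__ import annotations

import re
from datetime import datetime, timezone

from .exceptions import InvalidDatetimeError, InvalidIdentifierError

__all__ = ["validate_identifier", "normalize_datetime", "format_datetime"]

_IDENTIFIER_RE = re.compile(r"^[A-Za-z0-9._-]{1,128}$")
_RESERVED = {".", ".."}


def validate_identifier(candidate: str) -> str:
    """Return *candidate* unchanged if it is a valid identifier.

    Valid identifiers consist of letters, digits, dash, underscore and dot,
    are 1-128 characters long, contain no path separators, and are not the
    reserved names ``.`` or ``..``.

    Raises
    ------
    InvalidIdentifierError
        With a message naming the offending character or rule.
    """
    if not isinstance(candidate, str):
        raise InvalidIdentifierError(
            f"invalid identifier: expected a string, got {type(candidate).__name__}"
        )
    if candidate == "":
        raise InvalidIdentifierError("invalid identifier: empty string")
    if candidate in _RESERVED:
        raise InvalidIdentifierError(f"invalid identifier: {candidate!r} is reserved")
    if len(candidate) > 128:
        raise InvalidIdentifierError(
            f"invalid identifier: {len(candidate)} characters exceeds the 128 limit"
        )
    if not _IDENTIFIER_RE.match(candidate):
        bad = next(c for c in candidate if not re.match(r"[A-Za-z0-9._-]", c))
        raise InvalidIdentifierError(
            f"invalid identifier {candidate!r}: character {bad!r} not allowed"
        )
    return candidate


def normalize_datetime(raw: str | datetime) -> datetime:
    """Parse *raw* into a timezone-naive :class:`datetime`.

    Accepts ISO-8601 strings or :class:`datetime` instances.  Timezone-aware
    inputs are converted to UTC and the offset is dropped; resolution is
    microseconds (the native :class:`datetime` limit).
    """
    if isinstance(raw, datetime):
        dt = raw
    elif isinstance(raw, str):
        try:
            dt = datetime.fromisoformat(raw)
        except ValueError as exc:
            raise InvalidDatetimeError(f"invalid datetime: {raw!r}") from exc
    else:
        raise InvalidDatetimeError(
            f"invalid datetime: expected string or datetime, got {type(raw).__name__}"
        )
    if dt.tzinfo is not None:
        dt = dt.astimezone(timezone.utc).replace(tzinfo=None)
    return dt


def format_datetime(dt: datetime) -> str:
    """ISO-8601 storage form; the fractional part is omitted when zero."""
    return dt.isoformat()
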