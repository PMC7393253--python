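"""Exception hierarchy.

Every error raised by the public API derives from :class:`ExpipeError` so
callers (and the CLI) can distinguish domain errors from programming errors.
"""


class ExpipeError(Exception):
    """Base class for all expipe errors."""


class InvalidIdentifierError(ExpipeError, ValueError):
    """A name violates the safe-name grammar."""


class InvalidDatetimeError(ExpipeError, ValueError):
    """A datetime string could not be parsed."""


class SerializationError(ExpipeError, ValueError):
    """Module contents contain something that cannot be stored as YAML."""


class ParseError(ExpipeError, ValueError):
    """A metadata file is not valid YAML, or has the wrong top-level type."""


class ProjectExistsError(ExpipeError):
    """Attempt to create a project where one already exists."""


class NotAProjectError(ExpipeError):
    """The given path is not an expipe project."""


class ObjectExistsError(ExpipeError):
    """An action/entity/template/module with this identifier already exists."""


class ObjectNotFoundError(ExpipeError, KeyError):
    """Lookup of a non-existent record."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class StorageError(ExpipeError, OSError):
    """The backing store could not be read or written."""


class PathConflictError(ExpipeError, ValueError):
    """A nested-key update would have to overwrite a non-mapping value."""
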