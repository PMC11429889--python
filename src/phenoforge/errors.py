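"""Exception hierarchy.

Every error raised by the library derives from :class:`PhenoForgeError`, so
callers (and the CLI) can distinguish data problems from programming bugs.
"""


class PhenoForgeError(Exception):
    """Base class for all library errors."""


class StructuralError(PhenoForgeError):
    """The ontology graph violates a structural constraint (e.g. a cycle)."""


class ReferentialError(PhenoForgeError):
    """An edge, binding or range points at an undeclared term."""


class TermNotFoundError(PhenoForgeError, KeyError):
    """A term id was looked up but is not declared."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return Exception.__str__(self)


class TemplateError(PhenoForgeError):
    """A pattern template is malformed (missing field, undeclared var...)."""


class RangeError(PhenoForgeError):
    """A filler term falls outside its variable's declared range."""


class SerializationError(PhenoForgeError):
    """A document cannot be written (e.g. a prefix missing from the curie map)."""


class UsageError(PhenoForgeError):
    """The caller passed arguments that make the operation meaningless."""
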