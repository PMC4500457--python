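"""Exception hierarchy shared by all linneangap modules."""


class LinneangapError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LinneangapError):
    """A record file is missing mandatory columns or is otherwise malformed."""


class IntegrityError(LinneangapError):
    """A dataset violates a cross-row invariant (e.g. duplicated species)."""


class RangeError(LinneangapError):
    """A value lies outside its admissible range (e.g. year outside window)."""


class UsageError(LinneangapError):
    """An operation was called with arguments outside its contract."""


class DegenerateInputError(UsageError):
    """The input is formally valid but makes the requested statistic undefined."""


class ConsistencyError(LinneangapError):
    """Mutually inconsistent inputs (e.g. family counts exceeding totals)."""
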