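"""Exception hierarchy.

``UsageError`` covers bad parameters; ``DataError`` covers malformed or
inconsistent inputs. The CLI maps them to exit codes 2 and 3 respectively.
"""


class OrthoKMeansError(Exception):
    """Base class for all package errors."""


class UsageError(OrthoKMeansError):
    """A parameter is out of range or arguments are inconsistent."""


class ParameterError(UsageError):
    pass


class DataError(OrthoKMeansError):
    """Input data violates a format or consistency requirement."""


class MalformedHeaderError(DataError):
    pass


class DuplicateRecordError(DataError):
    pass


class EmptyInputError(DataError):
    pass


class ParseError(DataError):
    pass


class DimensionMismatchError(DataError):
    pass


class UnknownIdError(DataError):
    pass


class CoverageError(DataError):
    """Two partitions or id sets do not cover the same proteins."""
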