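"""Exception hierarchy shared across the toolkit."""


class DmdkitError(Exception):
    """Base class for all toolkit-specific errors."""


class SchemeDefinitionError(DmdkitError, ValueError):
    """A scheme definition (or an edit to one) violates a well-formedness rule."""


class WorkbookFormatError(DmdkitError, ValueError):
    """A workbook (or metadata directory) is not in the expected layout."""


class XmlFormatError(DmdkitError, ValueError):
    """An XML document is not one of ours, or is malformed."""


class ExportRefusedError(DmdkitError, RuntimeError):
    """Export was requested while error-level validation issues exist."""


class UsageError(DmdkitError, ValueError):
    """An operation was called with an unsupported option."""


class RepositoryError(DmdkitError, RuntimeError):
    """A scheme repository is unreachable, corrupt, or lacks the entry."""


class IntegrityError(RepositoryError):
    """Checksum verification of a scheme package failed."""


class PackagingError(RepositoryError):
    """Packing a scheme was refused (e.g. an example fails validation)."""


class FixtureError(DmdkitError, ValueError):
    """The fixture generator cannot realise the requested fault specification."""
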