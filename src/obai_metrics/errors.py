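"""Exception hierarchy shared by all measurement modules."""


class OBAIError(Exception):
    """Base class for all errors raised by this package."""


class EmptyInput(OBAIError):
    """Raised when a metric is asked to operate on empty or whitespace-only text."""


class NotAWord(OBAIError):
    """Raised when syllabification receives a string without any letter."""


class UnsupportedLanguage(OBAIError):
    """Raised when no configured backend supports the requested language."""


class BackendError(OBAIError):
    """Raised when an annotation or G2P backend is unavailable or fails.

    The message names the missing resource (e.g. a model package) so the
    caller can install it or fall back to the bundled rule backend.
    """


class MissingResource(OBAIError):
    """Raised when a required wordlist or dictionary file cannot be loaded."""


class MissingAnnotation(OBAIError):
    """Raised when a measure needs annotations the document does not carry."""


class UnsupportedMeasure(OBAIError):
    """Raised by grade_label for measures without a published level table."""


class MissingValue(OBAIError):
    """Raised for an empty target/response cell in pair scoring."""


class FileFormatError(OBAIError):
    """Raised for unreadable or malformed input files; names the offending location."""


class SchemaError(OBAIError):
    """Raised when a pairs table lacks a required column; names the column."""


class EmptyBatch(OBAIError):
    """Raised when a batch operation receives no readable input."""


class InvalidSpec(OBAIError):
    """Raised for an invalid synthetic-fixture specification."""
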