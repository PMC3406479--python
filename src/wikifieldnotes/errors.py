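"""Exception hierarchy for the notebook-mining pipeline."""


class WikiFieldNotesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WikiFieldNotesError):
    """A run configuration is unusable (missing index, missing authority snapshot, ...)."""


class IngestError(WikiFieldNotesError):
    """A transport or corpus-file problem; retryable when transient."""


class CorpusFormatError(IngestError):
    """A corpus XML file violates the corpus schema; message names the offending element."""


class DateParseError(WikiFieldNotesError):
    """A date string could not be normalized to a calendar date."""

    def __init__(self, text: str, message: str | None = None):
        self.text = text
        super().__init__(message or f"unparseable date: {text!r}")


class IntegrityError(WikiFieldNotesError):
    """An internal consistency guarantee was violated (duplicate IDs, dangling identifiers)."""
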