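"""Exception hierarchy for gemmannot."""


class GemmannotError(Exception):
    """Base class for all gemmannot errors."""


class EmptyCompositionError(GemmannotError):
    """Raised when an allele-composition string is empty after trimming."""


class NomenclatureSyntaxError(GemmannotError):
    """Raised on a malformed allele token (unbalanced brackets, bad pair split).

    Carries the offending token in ``token``.
    """

    def __init__(self, message: str, token: str = ""):
        super().__init__(message)
        self.token = token


class FileMissingError(GemmannotError):
    """Raised when a required input file does not exist."""


class KnowledgeConflictError(GemmannotError):
    """Raised when a knowledge table contains a duplicate key."""


class UnknownDriverError(GemmannotError):
    """Raised when a driver promoter is absent from the driver table."""


class TemplateSlotError(GemmannotError):
    """Raised when a rendering template is missing a required slot."""


class DuplicateIdError(GemmannotError):
    """Raised when a search corpus contains a duplicate record id."""


class ColumnMissingError(GemmannotError):
    """Raised when a TSV input lacks the expected column."""


class GeneratorConfigError(GemmannotError):
    """Raised when the composition generator is asked for a category the
    knowledge table cannot support."""


class WriteError(GemmannotError):
    """Raised when an output path cannot be written."""
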