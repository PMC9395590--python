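"""Exception hierarchy shared across the pipeline."""


class LncpipeError(Exception):
    """Base class for all pipeline errors."""


class GtfParseError(LncpipeError):
    """A GTF/GFF3 line could not be parsed; the message names the line number."""


class ValidationError(LncpipeError):
    """A domain object violates one of its invariants."""


class ConfigError(LncpipeError):
    """A configuration value is inconsistent or geometrically impossible."""


class LookupError_(LncpipeError):
    """A transcript or sample is missing from a table it is required in."""


class UndefinedCorrelationError(LncpipeError):
    """Pearson correlation requested for a constant vector."""
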