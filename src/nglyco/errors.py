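"""Exception hierarchy for the glycomics pipeline."""


class GlycoError(Exception):
    """Base class for all errors raised by this package."""


class CompositionError(GlycoError):
    """Invalid or empty glycan composition."""


class AdductError(GlycoError):
    """Invalid adduct specification (e.g. net charge zero)."""


class GlycoParseError(GlycoError, ValueError):
    """Malformed composition or adduct string; names the offending token."""


class ConfigurationError(GlycoError):
    """Inconsistent search/simulation configuration."""


class MissingInternalStandard(GlycoError):
    """No peak found inside the internal-standard match window."""


class InsufficientData(GlycoError):
    """Too few observations for the requested statistic."""


class UndefinedStatistic(GlycoError):
    """Statistic undefined for the given input (e.g. constant vector)."""


class SchemaError(GlycoError):
    """Delimited-text input missing required columns or malformed rows."""


class FixtureIntegrityError(GlycoError):
    """Packaged reference table failed its checksum."""
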