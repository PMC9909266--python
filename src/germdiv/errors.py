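"""Exception hierarchy.

All package-specific failures derive from :class:`GermdivError` so callers
can catch one base class; subclasses distinguish configuration problems
(bad parameters, malformed requests) from data problems (malformed or
degenerate inputs), which the CLI maps to exit codes 2 and 3 respectively.
"""


class GermdivError(Exception):
    """Base class for all germdiv errors."""


class ConfigError(GermdivError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(GermdivError):
    """Invalid or degenerate input data (CLI exit code 3)."""


class FormatError(DataError):
    """Malformed tabular or tree file (duplicate ids, missing header...)."""


class EncodingError(FormatError):
    """A cell value outside the declared encoding (e.g. non-binary band call)."""


class AlphabetError(DataError):
    """A nucleotide sequence contains characters outside {A,C,G,T}."""


class AlignmentError(DataError):
    """Tables that must share genotype/organ structure do not."""


class LabelMismatchError(DataError):
    """Two trees or matrices do not share the same label set."""


class DegenerateBandError(DataError):
    """A band has no non-missing calls, so its frequency is undefined."""


class InsufficientDataError(DataError):
    """Fewer than two usable genotypes remain after missing-data exclusion."""


class IncomparablePairError(DataError):
    """A genotype pair shares no non-missing feature, so no distance exists."""


class UndefinedCorrelationError(DataError):
    """Pearson correlation undefined (constant profile or constant vector)."""


class UndefinedHueError(DataError):
    """Hue angle undefined at the achromatic point a*=b*=0."""
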