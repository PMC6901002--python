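"""Exception hierarchy.

All errors the library raises on bad input or bad configuration derive from
:class:`PopphyloError`, so callers (and the CLI) can catch one type.
"""


class PopphyloError(Exception):
    """Base class for all popphylo errors."""


class VcfFormatError(PopphyloError):
    """The input is not a well-formed VCF, or a record line is malformed."""


class ValidationError(PopphyloError):
    """Invalid argument values: unknown sample names, asymmetric matrices, ..."""


class SizeError(ValidationError):
    """Too few genomes for the requested operation (trees need at least four)."""


class ConfigurationError(PopphyloError):
    """Inconsistent run configuration (e.g. p/JC scale without a genome length)."""


class DomainError(PopphyloError, ValueError):
    """A numeric argument is outside the mathematical domain of a transform."""
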