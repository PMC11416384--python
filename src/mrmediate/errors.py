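"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`MrMediateError`, so batch drivers
(the screening loop, the CLI) can trap pipeline failures without masking
programming errors.
"""


class MrMediateError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MrMediateError):
    """A summary-statistics file is missing a mandatory column."""


class EmptyInputError(MrMediateError):
    """An input file or record set is empty."""


class DuplicateVariantError(MrMediateError):
    """Duplicate rsids within one trait's summary statistics."""


class InvalidParameterError(MrMediateError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyInstrumentError(MrMediateError):
    """No SNP survives instrument selection for a trait."""


class HarmonizationEmptyError(MrMediateError):
    """No SNP survives allele harmonization for a pair."""


class InsufficientInstrumentsError(MrMediateError):
    """Fewer SNPs than the estimator's minimum."""


class UndefinedRatioError(MrMediateError, ZeroDivisionError):
    """Wald ratio requested for a SNP with zero exposure effect."""
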