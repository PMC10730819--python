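"""Exception hierarchy.

Three broad classes matter to callers (and to the CLI's exit codes):
configuration problems, data/parsing problems, and numerical/identification
problems with the MR model itself.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """Invalid run configuration: bad thresholds, missing columns, bad options."""


class ParseError(MRKitError):
    """A data file could not be parsed (non-numeric effect sizes etc.)."""


class HarmonizationError(MRKitError):
    """Exposure and outcome summary statistics cannot be aligned."""


class DegenerateInstrumentError(MRKitError):
    """An instrument (or all instruments) carries no exposure signal."""


class InsufficientInstrumentsError(MRKitError):
    """Too few SNPs for the requested estimator."""


class CollinearityError(MRKitError):
    """Exposure effect matrix is rank deficient (multivariable MR)."""


class ScaleError(MRKitError):
    """An estimate on the odds-ratio scale was passed where a log-odds beta is required."""
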