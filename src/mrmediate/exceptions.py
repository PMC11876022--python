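"""Exception hierarchy for mrmediate."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigError(MRMediateError, ValueError):
    """Invalid configuration: bad column mapping, missing LD entries, infeasible simulation settings."""


class InputError(MRMediateError, ValueError):
    """Invalid input data: empty tables, out-of-domain values."""


class InsufficientDataError(MRMediateError, ValueError):
    """Too few instruments for the requested estimator."""


class CollinearityError(MRMediateError, ValueError):
    """Rank-deficient exposure design in multivariable MR."""

    def __init__(self, message, exposures=()):
        super().__init__(message)
        self.exposures = tuple(exposures)
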