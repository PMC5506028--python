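"""Exception hierarchy for tissuefail."""


class TissueFailError(Exception):
    """Base class for all tissuefail errors."""


class InvalidGeometryError(TissueFailError, ValueError):
    """Construct geometry with non-positive dimensions."""


class ConfigurationError(TissueFailError, ValueError):
    """Infeasible or inconsistent protocol/scenario configuration."""


class InconsistentStateError(TissueFailError, ValueError):
    """Two tissue states that should share cell identities do not."""


class IncompleteRecordError(TissueFailError, ValueError):
    """A day's imaging records are missing counts."""


class InsufficientDataError(TissueFailError, ValueError):
    """Too few data points for the requested estimator."""


class UndefinedTrendError(TissueFailError, ValueError):
    """m-vs-n trend is undefined (degenerate abscissa)."""


class CensoredInputError(TissueFailError, ValueError):
    """Operation requires an uncensored lifetime."""


class EmptyDistributionError(TissueFailError, ValueError):
    """No slice holds at least two cells; distance distribution empty."""


class MissingArmError(TissueFailError, ValueError):
    """Conditioned-media experiment matrix is missing an arm."""
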