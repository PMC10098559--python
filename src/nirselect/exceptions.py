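"""Exception hierarchy for nirselect."""


class NirselectError(Exception):
    """Base class for all nirselect errors."""


class ParameterError(NirselectError, ValueError):
    """An argument or configuration value is out of its valid range."""


class DataError(NirselectError, ValueError):
    """Input data violates a contract (non-finite values, bad shapes...)."""


class DegenerateSignalError(DataError):
    """A windowed signal is constant, so standardized moments are undefined."""


class EpochingError(DataError):
    """A trigger's epoch window does not fit inside the recording."""


class SplitError(DataError):
    """A stratified holdout split cannot be formed (class too small)."""
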