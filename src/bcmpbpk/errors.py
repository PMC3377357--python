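"""Package exception hierarchy."""


class BcmPbpkError(Exception):
    """Base class for package errors."""


class ConfigError(BcmPbpkError):
    """Invalid configuration value or missing key."""


class SolverError(BcmPbpkError):
    """The ODE integration failed; message carries solver diagnostics."""


class DatasetError(BcmPbpkError):
    """Malformed or invalid chamber dataset."""


class FitError(BcmPbpkError):
    """Parameter estimation could not be carried out."""
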