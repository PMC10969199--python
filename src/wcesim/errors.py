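"""Exception hierarchy for the wcesim pipeline."""


class WcesimError(Exception):
    """Base class for all package errors."""


class ValidationError(WcesimError):
    """Invalid input data (bad shapes, labels, masks, ...)."""


class DecodeError(WcesimError):
    """An image file could not be decoded."""


class ManifestParseError(WcesimError):
    """A manifest file is malformed."""


class ConfigError(WcesimError):
    """Bad configuration value (unknown method, bad ratio, ...)."""


class CapacityError(WcesimError):
    """A balancing target exceeds what the variant budget can produce."""
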