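"""Exception hierarchy. CLI maps ConfigurationError to exit code 2 and
NumericalError/IntegrationError to exit code 3."""


class AdaptivePullError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdaptivePullError):
    """Invalid or incomplete configuration; message names the offending field."""


class GeometryError(AdaptivePullError):
    """Degenerate geometry (e.g. coincident tagged atoms) or failed construction."""


class LabelingError(AdaptivePullError):
    """Inconsistent atom role labelling (e.g. hydrogen without a donor link)."""


class NumericalError(AdaptivePullError):
    """Quadrature or estimator failure, with diagnostics in the message."""


class IntegrationError(AdaptivePullError):
    """Non-finite state encountered during time integration."""
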