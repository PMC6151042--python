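"""Exception types shared across the package."""


class BayesCCEError(Exception):
    """Base class for package errors."""


class ValidationError(BayesCCEError, ValueError):
    """Invalid input data or parameters."""


class ConvergenceError(BayesCCEError, RuntimeError):
    """An iterative fit failed to converge.

    Carries the last iterate and the gradient norm at that iterate so
    callers can diagnose degenerate inputs.
    """

    def __init__(self, message, last_iterate=None, grad_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.grad_norm = grad_norm
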