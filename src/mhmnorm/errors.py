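"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class InstabilityError(RuntimeError):
    """Raised when an ODE trajectory leaves the numerically safe range.

    Attributes
    ----------
    time : float or None
        The earliest sampling time at which the overflow guard tripped,
        when it could be located.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time
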