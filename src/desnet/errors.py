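"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class PropagationError(RuntimeError):
    """Raised when a numerical propagation diverges or produces NaNs."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)
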