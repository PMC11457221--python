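"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class DomainError(ValueError):
    """A model was evaluated outside its mathematical domain (e.g. r = 0)."""


class UndefinedAngleError(ValidationError):
    """The requested probe angle is undefined (zero-length projection)."""


class SurfaceFormatError(ValidationError):
    """A surface file does not conform to the CSV dialect."""


class NonConvergenceError(RuntimeError):
    """All optimizer starts failed to converge (reports are still written)."""
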