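"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the physically or statistically valid domain."""


class DegenerateEnsembleError(DomainError):
    """All ensemble members are identical: no spread, no usable density."""


class CropFailureError(DomainError):
    """Zero (or negative) yield: a per-unit-yield indicator is undefined.

    Raised instead of returning infinity so that crop failure is reported
    explicitly rather than silently propagated through a footprint table.
    """
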