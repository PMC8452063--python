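"""Coded exceptions shared across the package.

Every error raised deliberately by twistpg carries a short machine-readable
``code`` so that pipeline callers (and the CLI) can report which contract was
violated without parsing messages.
"""

from __future__ import annotations


class TwistError(Exception):
    """Base class for all coded twistpg errors."""

    code = "twist_error"

    def __init__(self, message: str, *, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ValidationError(TwistError):
    """Input data violate the dataset contract (non-binary G/T, empty data, ...)."""

    code = "validation_error"


class SingularDesignError(TwistError):
    """A required stratum is empty or too small to identify the requested contrast."""

    code = "singular_design"


class WeakInstrumentError(TwistError):
    """The MR denominator E[T*|G=1] - E[T*|G=0] is numerically zero."""

    code = "weak_instrument"


class SeparationError(TwistError):
    """Logistic fit separated (probabilities pinned at 0/1); use the linear-probability fallback."""

    code = "separation"


class ScaleMismatchError(TwistError):
    """Estimates on different difference scales (or %-vs-raw) cannot be pooled."""

    code = "scale_mismatch"


class CombinationError(TwistError):
    """Invalid combination request (wrong number of components, unknown pair)."""

    code = "combination_error"


class StageError(TwistError):
    """Pipeline failure, tagged with the stage that raised it."""

    code = "stage_error"

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage
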