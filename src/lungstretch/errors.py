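"""Exception hierarchy shared by all analysis stages."""

from __future__ import annotations


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InvalidMeasurementError(InvalidArgumentError):
    """A physical measurement is internally inconsistent (e.g. soaked mass < dry mass)."""


class SingularStateError(InvalidArgumentError):
    """The requested inversion is unidentifiable at this state (e.g. modulus at zero deflection)."""


class DegenerateCurveError(RuntimeError):
    """A fitted standard curve has a non-positive slope and cannot be inverted."""


class InsufficientCyclesError(RuntimeError):
    """Fewer than two stretch cycles were detected in a pressure trace.

    Carries the per-sample derived quantities so partial output is still available.
    """

    def __init__(self, message: str, samples=None):
        super().__init__(message)
        self.samples = samples


class AliasingError(InvalidArgumentError):
    """Requested sampling rate is too low to resolve the stretch waveform."""
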