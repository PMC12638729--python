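"""Exception hierarchy shared across the package."""


class VffrModelError(Exception):
    """Base class for all errors raised by vffr1d."""


class FormatError(VffrModelError):
    """A file does not follow the expected dialect (missing columns, bad header)."""


class MalformedGeometry(VffrModelError):
    """A centreline profile violates its invariants (non-monotone s, r <= 0, ...)."""


class DomainError(VffrModelError):
    """A scalar argument lies outside its physical or mathematical domain."""


class InfeasibleSpec(VffrModelError):
    """A synthetic-vessel specification cannot produce a valid geometry."""


class LeakageError(VffrModelError):
    """A leakage model cannot distribute the side-branch budget (e.g. fully stenosed vessel)."""


class SimulationFailure(VffrModelError):
    """A pressure iterate became non-physical during a coupled leakage solve."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class VffrUnavailable(VffrModelError):
    """vFFR requested from a simulation that did not converge."""


class DegenerateInput(VffrModelError):
    """A statistical estimator received data it cannot identify (e.g. all pairs identical)."""


class FiltrationWarning(UserWarning):
    """Healthy-lumen envelope iteration stopped before reaching tolerance."""
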