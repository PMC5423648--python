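"""Exception hierarchy shared across the package."""


class ShiftbindError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ShiftbindError, ValueError):
    """An argument is outside the mathematical domain of an operation
    (negative concentration, non-finite shift, zero reference intensity...)."""


class ValidationError(ShiftbindError, ValueError):
    """Structured input violates an invariant (non-monotone ligand schedule,
    duplicate residue in a peak list, mismatched temperatures...)."""


class DegenerateDataError(ShiftbindError, ValueError):
    """Data carry no information about the parameters (e.g. all-zero CSP
    trajectories cannot constrain a dissociation constant)."""


class CapabilityError(ShiftbindError, RuntimeError):
    """The requested analysis needs data the input does not provide,
    with a hint about the supported alternative."""
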