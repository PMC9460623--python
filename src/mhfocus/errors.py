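"""Exception types distinguishing contract violations from I/O problems."""


class MHFocusError(Exception):
    """Base class for all package errors."""


class GeometryError(MHFocusError, ValueError):
    """Antenna/target placement incompatible with the phantom geometry."""


class FormatError(MHFocusError, ValueError):
    """A container file violates the documented layout contract."""


class ContractError(MHFocusError, ValueError):
    """Objects passed together do not share scheme/grid/channel count."""


class DegenerateExcitationError(MHFocusError, ValueError):
    """An excitation carries no power (all-zero voltages or zero field)."""


class MetricError(MHFocusError, ValueError):
    """A metric is undefined for the given input (e.g., zero total energy)."""
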