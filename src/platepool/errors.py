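"""Exception hierarchy for platepool."""


class PlatePoolError(Exception):
    """Base class for all platepool errors."""


class ValidationError(PlatePoolError):
    """An external file or in-memory table violated a structural invariant."""


class DecodeError(PlatePoolError):
    """The pool decoder could not proceed (e.g., too few definite barcodes)."""


class PlanError(PlatePoolError):
    """Re-array planning failed (destination collision or capacity exceeded)."""


class SimulationError(PlatePoolError):
    """Synthetic-data generation was asked for an infeasible configuration."""
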