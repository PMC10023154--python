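"""Exception hierarchy for vesselmech."""


class VesselMechError(Exception):
    """Base class for all package errors."""


class ValidationError(VesselMechError):
    """A record or trace violates a structural invariant."""


class IncompleteDatasetError(ValidationError):
    """A specimen directory is missing one or more required protocols."""


class WallVolumeError(VesselMechError):
    """Measured deformed geometry is inconsistent with the unloaded wall volume."""


class ConfigurationNotFoundError(VesselMechError):
    """No equilibrium configuration exists in the search bracket."""


class EnergyOverflowError(VesselMechError):
    """The exponential fiber terms overflow at the requested deformation."""
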