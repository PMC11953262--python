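"""Exception hierarchy for spectracal."""


class SpectracalError(Exception):
    """Base class for all spectracal errors."""


class GridError(SpectracalError):
    """Wavelength grid is malformed or non-uniform."""


class SpectraParseError(SpectracalError):
    """A spectra/concentration CSV could not be parsed."""


class RangeError(SpectracalError):
    """Requested wavelength range does not intersect the grid."""


class DesignError(SpectracalError):
    """Experimental design is unsupported or physically infeasible."""


class DomainError(SpectracalError):
    """An input value is outside the operation's domain (e.g. negative
    concentration, zero reference mean)."""


class ShapeError(SpectracalError):
    """Matrix dimensions are inconsistent with the model or grid."""


class ConfigError(SpectracalError):
    """A run configuration file is invalid or incomplete."""


class StageError(SpectracalError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str, completed=()):
        self.stage = stage
        self.completed = list(completed)
        super().__init__(f"stage '{stage}' failed: {message}")
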