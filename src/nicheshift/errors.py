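"""Exception hierarchy."""


class NicheShiftError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NicheShiftError):
    """Invalid configuration or parameter values."""


class DegenerateSimulationError(NicheShiftError):
    """Synthetic suitability kernel falls (almost) entirely outside background support."""


class GridMismatchError(NicheShiftError):
    """Two niche grids do not share bounds / resolution."""
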