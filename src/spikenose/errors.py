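"""Exception hierarchy shared across the package."""


class SpikenoseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SpikenoseError, ValueError):
    """A numeric argument is outside its mathematical domain (e.g. R <= 0)."""


class StructuralError(SpikenoseError, ValueError):
    """Malformed composite input: wrong length, missing/duplicate sensor, ..."""


class RangeError(SpikenoseError, ValueError):
    """A computed component leaves the representable byte range [0, 255]."""


class CapacityError(SpikenoseError, RuntimeError):
    """The network needs to commit a neuron but all neurons are in use."""


class StateError(SpikenoseError, RuntimeError):
    """Operation invoked in an invalid state (e.g. classify on an empty net)."""


class FrameError(SpikenoseError, ValueError):
    """Invalid spike frame: duplicate sensor or more spikes than sensors."""
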