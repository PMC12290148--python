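"""Exception hierarchy shared across the package."""


class ScintisegError(Exception):
    """Base class for package-specific failures."""


class FormatError(ScintisegError, ValueError):
    """A raster file violates the expected format (channels, dtype, ...)."""


class PairingError(ScintisegError, ValueError):
    """An image and its mask disagree (shape mismatch, missing pair)."""


class ConfigurationError(ScintisegError, ValueError):
    """A configuration value is out of its admissible range."""


class GenerationError(ScintisegError, RuntimeError):
    """The phantom generator could not satisfy its placement constraints."""


class TrainingError(ScintisegError, RuntimeError):
    """Training produced a non-finite loss or an otherwise invalid state."""
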