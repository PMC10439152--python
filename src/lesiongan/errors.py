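"""Exception types used across the package."""


class ContractError(ValueError):
    """An operation precondition was violated (shape, range, or size)."""


class ConfigurationError(ValueError):
    """A model or training configuration is internally inconsistent."""


class FormatError(ValueError):
    """A file's content does not match the expected image/mask format."""


class GenerationError(RuntimeError):
    """The synthetic-scene sampler could not satisfy its constraints."""


class TrainingDivergedError(RuntimeError):
    """A loss became non-finite during training."""
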