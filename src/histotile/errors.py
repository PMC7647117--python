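"""Exception hierarchy shared by all pipeline stages."""


class HistotileError(Exception):
    """Base class for all histotile errors."""


class InputError(HistotileError):
    """Missing or unusable input file."""


class FormatError(HistotileError):
    """File exists but cannot be decoded as a slide image."""


class BoundsError(HistotileError):
    """A requested region falls outside the slide."""


class ParameterError(HistotileError):
    """An operation received an invalid parameter value."""


class ConfigError(HistotileError):
    """Pipeline configuration is internally inconsistent."""


class StructuralError(HistotileError):
    """Mismatched intermediate data structures (e.g. mask vs. grid)."""


class PipelineError(HistotileError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
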