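"""Exception hierarchy shared across the pipeline."""


class ShgQuantError(Exception):
    """Base class for all package errors."""


class FormatError(ShgQuantError):
    """Input file is readable but not in a supported layout (e.g. RGB TIFF)."""


class BoundsError(ShgQuantError, ValueError):
    """A region of interest does not fit inside the image."""


class ParameterError(ShgQuantError, ValueError):
    """A parameter is outside its documented range."""


class DegenerateImageError(ShgQuantError, ValueError):
    """An operation that needs >= 2 distinct gray values got a constant image."""


class DesignError(ShgQuantError, ValueError):
    """A cohort/statistical design is invalid (empty cell, singleton group...)."""


class BatchMismatchError(ShgQuantError, ValueError):
    """Intensities from different acquisition batches must not be contrasted."""


class PipelineStageError(ShgQuantError):
    """Wraps an error raised inside quantify_sample with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
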