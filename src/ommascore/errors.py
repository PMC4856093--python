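"""Exceptions shared across the pipeline."""


class NoEyeDetected(RuntimeError):
    """No candidate eye region satisfied the detection constraints."""


class TooFewOmmatidia(RuntimeError):
    """Fewer than the seven ommatidia needed to build six-neighbor fans."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause
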