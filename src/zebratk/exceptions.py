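"""Exception types shared across the package."""


class FitError(RuntimeError):
    """A model fit could not be performed or did not converge.

    Carries the optimizer message / diagnostic in ``args[0]``.
    """


class DataError(ValueError):
    """A data file or table failed schema validation (row numbers in message)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
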