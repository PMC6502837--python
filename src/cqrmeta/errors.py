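"""Exception hierarchy."""


class CqrMetaError(Exception):
    """Base class for all package errors."""


class ValidationError(CqrMetaError, ValueError):
    """Invalid user input (parameters, table contents, config)."""


class DegenerateDesignError(CqrMetaError):
    """Design matrix is rank deficient or a regressor is constant."""


class DegenerateInputError(CqrMetaError):
    """Input data cannot support the requested analysis (e.g. constant trait)."""


class StageError(CqrMetaError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
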