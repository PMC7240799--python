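"""Exception hierarchy shared across the pipeline stages."""


class StrokeMDPError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StrokeMDPError, ValueError):
    """Invalid configuration (marginals, rates, predicates, presets...)."""


class IntegrityError(StrokeMDPError, ValueError):
    """Structurally broken input table (duplicates, unfillable blanks...)."""


class AlignmentError(StrokeMDPError, ValueError):
    """Visit days that do not sit on the decision-epoch grid."""


class EstimationError(StrokeMDPError, ValueError):
    """Transition-model estimation on unusable input (e.g. no steps)."""


class SupportError(StrokeMDPError, ValueError):
    """Reference to a (state, action) pair without observed support."""


class SolverError(StrokeMDPError, ValueError):
    """Monte Carlo control invoked on an unusable model."""


class SummaryError(StrokeMDPError, ValueError):
    """Cohort summary requested on unusable input (e.g. no patients)."""


class PipelineError(StrokeMDPError, RuntimeError):
    """A pipeline stage failed; message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
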