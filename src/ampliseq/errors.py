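"""Exception types shared across the pipeline stages."""


class AmpliseqError(Exception):
    """Base class for all package errors."""


class PanelError(AmpliseqError):
    """Malformed or inconsistent panel / catalog / reference input."""


class ConfigError(AmpliseqError):
    """Invalid caller configuration or simulation scenario."""


class SimulationError(AmpliseqError):
    """A requested genotype cannot be simulated on the given panel."""


class PhaseInconsistencyError(AmpliseqError):
    """The pairwise phase evidence admits no diploid assignment.

    Carries the offending variant names in ``conflict``.
    """

    def __init__(self, message: str, conflict=None):
        super().__init__(message)
        self.conflict = list(conflict or [])


class PipelineError(AmpliseqError):
    """A pipeline stage failed; names the stage and sample."""

    def __init__(self, stage: str, sample: str, message: str):
        super().__init__(f"stage {stage!r}, sample {sample!r}: {message}")
        self.stage = stage
        self.sample = sample
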