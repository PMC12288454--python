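"""Exception hierarchy shared across the package."""


class AllosterikError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(AllosterikError):
    """A generator or run specification is internally inconsistent."""


class TrajectoryFormatError(AllosterikError):
    """A trajectory file could not be parsed or is internally inconsistent."""


class InsufficientFramesError(AllosterikError):
    """An operation needs more frames than the trajectory provides."""


class DegenerateModelError(AllosterikError):
    """The elastic network is disconnected or otherwise singular."""


class DegenerateNetworkError(AllosterikError):
    """A dynamical network came out empty under the chosen cutoffs."""


class NoPathError(AllosterikError):
    """No source-sink pair is connected in the network."""


class DegenerateDataError(AllosterikError):
    """Assay data carry no signal (e.g. constant response)."""


class UnitMismatchError(AllosterikError):
    """Two quantities with incompatible units were combined."""


class PipelineError(AllosterikError):
    """A workflow stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
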