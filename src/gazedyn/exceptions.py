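"""Exception taxonomy for the gazedyn pipeline."""


class GazedynError(Exception):
    """Base class for all gazedyn errors."""


class InvalidGeometryError(GazedynError):
    """Stimulus field geometry is degenerate (non-positive extent)."""


class ProtocolError(GazedynError):
    """A trial/session request violates the recording protocol."""


class ConfigurationError(GazedynError):
    """A pipeline or dataset configuration is invalid."""


class ParseError(GazedynError):
    """An on-disk artifact could not be parsed."""


class SchemaError(GazedynError):
    """A table does not conform to the expected schema."""


class TruncationError(GazedynError):
    """Not enough samples remain after a stimulus onset."""


class DegenerateInputError(GazedynError):
    """A series is too short or constant where variation is required."""


class EmbeddingError(GazedynError):
    """Delay embedding is infeasible for the requested (N, m, tau)."""


class StratificationError(GazedynError):
    """A subject has too few vectors to stratify."""


class EvaluationError(GazedynError):
    """Model evaluation was requested on invalid inputs."""


class LabelError(GazedynError):
    """A label outside the known class set was encountered."""


class VotingError(GazedynError):
    """Majority voting was requested on an empty prediction list."""


class FitError(GazedynError):
    """A classifier could not be fitted (e.g. single-class training set)."""
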