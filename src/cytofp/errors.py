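"""Exception hierarchy shared across the package."""


class CytoError(Exception):
    """Base class for all package-specific errors."""


class MissingChannelError(CytoError):
    """A requested channel is absent; message lists available channels."""

    def __init__(self, requested, available):
        self.requested = list(requested)
        self.available = list(available)
        super().__init__(
            f"channel(s) {self.requested} not found; available: {self.available}"
        )


class ChannelMismatchError(CytoError):
    """Two event matrices (or a template and a matrix) disagree on channels."""


class EmptyInputError(CytoError):
    """A file or table contained no events/rows."""


class EmptySampleError(CytoError):
    """A sample ended up with zero events after gating/subsampling."""


class InsufficientEventsError(CytoError):
    """Fewer events available than requested under the strict policy."""


class TransformStateError(CytoError):
    """Operation requires the opposite transformed/raw state."""


class DegenerateChannelError(CytoError):
    """A channel is constant, so no binning grid can span it."""


class InfeasibleModelError(CytoError):
    """Model size is infeasible for the data (e.g. more components than events)."""


class AlignmentError(CytoError):
    """Two tables/matrices do not share labels, ids or column order."""


class UndefinedStatisticError(CytoError):
    """The statistic is undefined for this input (constant vector, zero mass, ...)."""


class ConfigurationError(CytoError):
    """Invalid run configuration or parameter grid."""
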