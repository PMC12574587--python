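"""Exception hierarchy for mixtrack.

Every error raised by the library derives from :class:`MixtrackError`, so
callers (and the CLI) can catch one type and report a one-line diagnostic.
"""


class MixtrackError(Exception):
    """Base class for all mixtrack errors."""


class FormatError(MixtrackError):
    """A counts or mapping file violates the expected TSV dialect."""


class RoleError(MixtrackError):
    """The source/sink role assignment is inconsistent with the counts."""


class DegenerateSampleError(MixtrackError):
    """A sample has zero total count and cannot enter the model."""


class CollinearityError(MixtrackError):
    """Two source profiles are (numerically) identical; the mixing
    proportions are not identifiable."""


class SingularityError(MixtrackError):
    """A matrix required to be invertible is numerically singular."""


class EstimationError(MixtrackError):
    """The GLS estimate could not be post-processed into proportions."""


class DirectionalityError(MixtrackError):
    """No candidate sink assignment produced a finite joint likelihood."""
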