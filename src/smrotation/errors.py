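"""Exception hierarchy.

Distinct classes let the CLI map failures to exit codes: I/O and format
problems, statistically degenerate inputs, and geometric degeneracies are
different user-facing conditions.
"""


class SMRotationError(Exception):
    """Base class for all package errors."""


class HMDFormatError(SMRotationError, ValueError):
    """An input file does not conform to the expected HMD/CSV layout."""


class DegenerateDataError(SMRotationError, ValueError):
    """Too few or too-collinear data points for the requested fit."""


class ParallelLinesError(SMRotationError, ValueError):
    """Two Gompertz lines with equal slopes have no intersection age."""


class MisalignedTableError(SMRotationError, ValueError):
    """Parameter fits and diagnostic records do not line up by period."""
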