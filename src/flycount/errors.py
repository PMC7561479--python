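"""Exception hierarchy.

Every error carries a distinct process exit code so the command-line
front end can map failures deterministically.
"""


class FlyCountError(Exception):
    """Base class for all flycount errors."""

    exit_code = 1


class InputError(FlyCountError):
    """Unreadable or missing input file / malformed argument."""

    exit_code = 2


class NoSheetFound(FlyCountError):
    """No bright convex quadrilateral covering >= 5% of the image."""

    exit_code = 3


class AmbiguousSheet(FlyCountError):
    """Two bright candidate regions differ in area by less than 10%."""

    exit_code = 4


class DegenerateQuad(FlyCountError):
    """Sheet quadrilateral too skewed for a stable homography."""

    exit_code = 5


class NoObjects(FlyCountError):
    """No object survives the length filter; nothing to average."""

    exit_code = 6


class PlacementFailure(FlyCountError):
    """Synthetic scene could not satisfy the separation constraints."""

    exit_code = 7


class EmptyInput(FlyCountError):
    """Statistic requested on an empty pair set."""

    exit_code = 8


class ZeroReference(FlyCountError):
    """MAPE undefined: a reference count is zero."""

    exit_code = 9


class DegenerateVariance(FlyCountError):
    """Correlation undefined: one of the vectors is constant."""

    exit_code = 10


class DegenerateGroups(FlyCountError):
    """Kruskal-Wallis undefined: all pooled values identical."""

    exit_code = 11


class JoinFailure(FlyCountError):
    """Truth and estimate tables share no ids."""

    exit_code = 12
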