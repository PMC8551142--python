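"""Exception hierarchy.

Every error class carries a distinct process exit code so that the CLI can
map failure categories (parse / collision / orientation / config / geometry)
to documented shell exit statuses.
"""


class BrickPhantomError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class LdrawParseError(BrickPhantomError):
    """Malformed or unsupported LDraw input."""

    exit_code = 2


class CollisionError(BrickPhantomError):
    """Two placements claim the same lattice cell."""

    exit_code = 3

    def __init__(self, message, conflicts=()):
        super().__init__(message)
        #: list of (pid_a, pid_b, shared cell tuples)
        self.conflicts = list(conflicts)


class OrientationError(BrickPhantomError):
    """A rotation matrix is not one of the 24 proper cube rotations."""

    exit_code = 4


class ConfigError(BrickPhantomError):
    """Invalid or inconsistent configuration values."""

    exit_code = 5


class GeometryError(BrickPhantomError):
    """Analytical geometry violates an invariant (e.g. a rod source leaves
    its brick's lattice cells)."""

    exit_code = 6


class FixtureError(BrickPhantomError):
    """Unknown canonical layout fixture name."""

    exit_code = 7


class DeckError(BrickPhantomError):
    """An emitted MCNP deck failed an internal structural check."""

    exit_code = 8
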