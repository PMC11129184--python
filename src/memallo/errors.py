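"""Exception hierarchy shared across the package."""


class MemalloError(Exception):
    """Base class for all package errors."""


class ParseError(MemalloError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(MemalloError):
    """Atom counts or atom identities do not match between inputs."""


class SelectionError(MemalloError):
    """A selection expression is invalid or resolves to nothing usable."""


class SpecError(MemalloError):
    """A synthetic-data specification is internally inconsistent."""


class IllPosedError(MemalloError):
    """A geometric or numerical problem is degenerate (e.g. collinear points)."""


class ParameterError(MemalloError):
    """An analysis parameter violates its constraints (e.g. r_off < r_on)."""


class InsufficientDataError(MemalloError):
    """Not enough frames/events to perform the requested computation."""
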