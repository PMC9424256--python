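"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2 (bad configuration), every other
:class:`ProbatlasError` subclass to exit code 3 (bad or inconsistent data).
"""


class ProbatlasError(Exception):
    """Base class for all package errors."""


class GridMismatchError(ProbatlasError):
    """Two spatial domains that must match do not."""


class MaskError(ProbatlasError):
    """Empty, invalid, or incompatible analysis mask."""


class SingleRunError(ProbatlasError):
    """An operation requiring >=2 runs was given fewer."""


class SelectionError(ProbatlasError):
    """Invalid voxel-selection request (e.g. k = 0, missing dof)."""


class ConfigError(ProbatlasError):
    """Invalid pipeline or simulation configuration."""
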