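"""Exception hierarchy shared across the package."""


class SsblupError(Exception):
    """Base class for all package-specific errors."""


class PedigreeError(SsblupError, ValueError):
    """Structural problems in a pedigree: cycles, sex conflicts, unknown ids."""


class DataError(SsblupError, ValueError):
    """Malformed or inconsistent input data."""


class ConvergenceError(SsblupError, RuntimeError):
    """An iterative solver failed to reach its convergence criterion."""
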