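"""Exception hierarchy shared across the package."""

from __future__ import annotations

import numpy as np


class HetpropError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HetpropError):
    """A text input could not be parsed; carries the file path and line number."""

    def __init__(self, path: str, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(HetpropError, ValueError):
    """An input or parameter violated its contract."""


class AssemblyError(HetpropError):
    """The heterogeneous network could not be assembled from its parts."""


class ConvergenceError(HetpropError):
    """Power iteration hit the iteration cap before reaching the tolerance.

    The last iterate and the iteration count are attached so callers can
    inspect how far the walk got.
    """

    def __init__(self, last: "np.ndarray", iterations: int, residual: float):
        self.last = last
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"random walk did not converge within {iterations} iterations "
            f"(last L1 residual {residual:.3e})"
        )
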