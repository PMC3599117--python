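"""Exception hierarchy shared across the pipeline.

Three classes map onto the CLI's exit-code contract: I/O problems exit 2,
validation problems 3, numerical problems 4.
"""


class CrossArrayError(Exception):
    """Base class for all package errors."""


class ValidationError(CrossArrayError, ValueError):
    """Invalid inputs, violated invariants, malformed tables."""


class NumericalError(CrossArrayError, ArithmeticError):
    """Numerical failure: undefined transforms, non-convergence, degenerate matrices."""
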