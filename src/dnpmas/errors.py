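"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ``DataError`` -> 3, ``NumericalError`` -> 4.
Plain ``ValueError`` raised by validation code is treated as a data error too.
"""


class DataError(ValueError):
    """Malformed, ambiguous, or out-of-contract input data."""


class InvalidSpecError(DataError):
    """A synthetic-data specification violates its invariants."""


class NumericalError(RuntimeError):
    """A numerical procedure (fit, optimisation) failed irrecoverably."""
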