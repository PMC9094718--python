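"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataError (incl. MissingStratumError) -> 3, CalibrationError -> 4.
"""


class CaresimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CaresimError, ValueError):
    """Invalid configuration (shares not summing to one, bad ranges, ...)."""


class DataError(CaresimError, ValueError):
    """Invalid or incomplete input data."""


class MissingStratumError(DataError):
    """A parameter table has no entry for a required stratum cell."""

    def __init__(self, table: str, **cell):
        self.table = table
        self.cell = cell
        desc = ", ".join(f"{k}={v}" for k, v in cell.items())
        super().__init__(f"missing cell in {table!r} parameter table: {desc}")


class FitFailureError(CaresimError, RuntimeError):
    """A regression fit failed (separation, degenerate outcome, rank deficiency)."""


class CalibrationError(CaresimError, RuntimeError):
    """A prevalence target cannot be attained by any threshold."""
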