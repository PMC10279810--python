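"""Exception hierarchy shared across the package."""


class PlastidRatesError(Exception):
    """Base class for all package errors."""


class ConfigError(PlastidRatesError):
    """Invalid configuration (bad parameter value, impossible geometry)."""


class FormatError(PlastidRatesError):
    """Malformed input file (FASTA/Newick/TSV). Readers reject, never repair."""


class DataError(PlastidRatesError):
    """Structurally valid input that violates a pipeline contract
    (species-set mismatch, translation mismatch, empty alignment, ...)."""


class NumericalError(PlastidRatesError):
    """Non-finite likelihood, singular design or failed optimisation."""


class ConvergenceError(NumericalError):
    """Optimiser hit its iteration cap; carries the best fit found so far."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
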