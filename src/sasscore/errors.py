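"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2,
DataValidationError -> 3, AnalysisError -> 4.
"""


class SasScoreError(Exception):
    """Base class for all package errors."""


class ConfigError(SasScoreError):
    """Malformed or invariant-violating configuration (rubric, domains, simulation)."""


class DataValidationError(SasScoreError):
    """Input data that fails the documented contracts (bad level, bad column, duplicate id)."""


class IneligibilityError(DataValidationError):
    """Record excluded by an eligibility rule (e.g. age under three years)."""


class ParseError(DataValidationError):
    """Unparseable molecular description (HGVS subset)."""


class ClassificationConflictError(DataValidationError):
    """A molecular finding carrying mutually contradictory evidence."""


class AnalysisError(SasScoreError):
    """Statistical model cannot be fit as requested (rank deficiency, too few levels)."""
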