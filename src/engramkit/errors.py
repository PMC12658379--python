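"""Exception hierarchy shared across the package."""


class EngramkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EngramkitError, ValueError):
    """A generator or run configuration violates its invariants."""


class ParseError(EngramkitError, ValueError):
    """An input table is malformed; the message names the offending row."""


class UndefinedStatistic(EngramkitError, ValueError):
    """A statistic is undefined for the given input (e.g. DI with zero
    total exploration, enrichment with zero chance).  Callers that
    aggregate over animals catch this and exclude the record instead of
    imputing a value."""


class ValidationError(EngramkitError, ValueError):
    """Pipeline-level input validation failed; carries an itemized report."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )
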