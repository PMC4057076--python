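"""Exception types shared across the package."""


class RuleTraitError(Exception):
    """Base class for package errors."""


class ConfigError(RuleTraitError):
    """Invalid generator or pipeline configuration."""


class SchemaError(RuleTraitError):
    """Input table does not match the expected column roles or types."""


class InfeasibleRuleError(RuleTraitError):
    """Canonicalization produced an empty interval for some marker."""


class DegenerateOutcomeError(RuleTraitError):
    """Outcome vector is constant; no discrimination problem exists."""


class DegenerateItemError(RuleTraitError):
    """One or more endorsement columns are constant (all 0 or all 1)."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"degenerate endorsement columns (all 0 or all 1): {self.indices}")


class EmptyGroupError(RuleTraitError):
    """A survival group selected for estimation contains no subjects."""


class UndefinedTestError(RuleTraitError):
    """The requested test statistic is undefined (e.g. no events at all)."""
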