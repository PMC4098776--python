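"""Exception hierarchy for exoqc."""


class ExoqcError(Exception):
    """Base class for all exoqc errors."""


class VcfParseError(ExoqcError):
    """A VCF header or record could not be parsed."""


class TableParseError(ExoqcError):
    """A tabular input (array genotypes, site set, batch table) is malformed."""


class ValidationError(ExoqcError, ValueError):
    """A data-model invariant was violated."""


class UndefinedMetricError(ExoqcError, ArithmeticError):
    """A requested metric has a zero denominator and is undefined."""


class SelectionError(ExoqcError, ValueError):
    """No sweep point satisfies the requested retention target."""
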