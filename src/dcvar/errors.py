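"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`DcVarError` so the CLI can
catch a single type, print one diagnostic line and exit nonzero.
"""


class DcVarError(Exception):
    """Base class for all dcvar errors."""


class FormatError(DcVarError):
    """Malformed input file (column counts, non-numeric cells, ...)."""


class ValidationError(DcVarError):
    """Structurally valid input that violates a contract (duplicate IDs,
    disjoint sample sets, out-of-range parameters)."""


class MultiAllelicError(FormatError):
    """More than two distinct non-missing alleles observed at one SNP."""


class UndefinedMAFError(ValidationError):
    """Minor-allele frequency requested for an all-missing call vector."""


class DegenerateCorrelationError(ValidationError):
    """Pearson correlation requested for a constant vector."""


class InsufficientSamplesError(ValidationError):
    """A genotype group is too small for the z-test denominator (m <= 3)
    or below the configured minimum group size."""
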