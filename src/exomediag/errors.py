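"""Exception hierarchy for the exomediag package."""


class ExomediagError(Exception):
    """Base class for all package errors."""


class ParseError(ExomediagError):
    """A file could not be parsed (malformed VCF/PED/TSV)."""


class SchemaError(ExomediagError):
    """A tabular input violates its documented schema (missing column, duplicate key)."""


class ReconciliationError(ExomediagError):
    """Samples or families in one input cannot be matched against another."""


class PedigreeError(ExomediagError):
    """Structurally invalid pedigree (cyclic parentage, unknown sex code)."""


class ConfigError(ExomediagError):
    """Invalid simulator or pipeline configuration."""


class ValidationError(ExomediagError):
    """Invalid in-memory data (negative allele frequency, unsorted SNP track)."""
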