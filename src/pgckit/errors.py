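"""Exception hierarchy for pgckit."""


class PgckitError(Exception):
    """Base class for all pgckit errors."""


class InputError(PgckitError):
    """Invalid argument to an operation (empty label, bad parameter)."""


class CatalogError(PgckitError):
    """Lookup of an unregistered canonical gene symbol."""


class GeneStringParseError(PgckitError):
    """A compact gene-string token could not be expanded or resolved."""


class FormatError(PgckitError):
    """Malformed input file (missing column, truncated record, bad row)."""


class RangeError(PgckitError):
    """Coordinates outside the replicon, or an empty interval."""


class UndefinedGCError(PgckitError):
    """GC fraction requested for an empty or all-ambiguous sequence."""


class SpecValidationError(PgckitError):
    """A simulation spec is internally inconsistent."""


class TruthSchemaError(PgckitError):
    """A truth record document does not conform to the schema."""
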