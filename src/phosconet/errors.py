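"""Exception hierarchy. Every pipeline failure derives from PhosconetError so
the CLI can turn any stage error into a clean nonzero exit."""


class PhosconetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PhosconetError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidPositionError(PhosconetError):
    """A residue position or motif offset falls outside the sequence."""


class ParseError(PhosconetError):
    """Malformed external input; the message names the row and field."""


class AlignmentError(PhosconetError):
    """Ragged or otherwise inconsistent alignment input."""


class SeedError(PhosconetError):
    """Zero or multiple seed records in an ortholog family."""


class SpeciesMissingError(PhosconetError):
    """Requested species/variant absent from the family (maps to NA)."""


class InputError(PhosconetError):
    """Inconsistently keyed inputs handed to an operation."""


class ConfigError(PhosconetError):
    """Unknown motif name, export format, or other bad option value."""


class SerializationError(PhosconetError):
    """A value outside its legal range was handed to a writer."""
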