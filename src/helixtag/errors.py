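"""Exception hierarchy shared across the pipeline.

Validation problems (bad thresholds, bad junction orders, malformed config)
raise :class:`ValidationError`; unreadable or unwritable files raise
:class:`InputOutputError`. The CLI maps these to exit codes 1 and 2.
"""


class HelixTagError(Exception):
    """Base class for all package errors."""


class ValidationError(HelixTagError):
    """Invalid parameters, config values or domain constraints."""


class InputOutputError(HelixTagError):
    """File cannot be read, parsed or written."""


class StructureParseError(InputOutputError):
    """A structure file failed to parse; message names the file and context."""


class EmptyStructureError(InputOutputError):
    """A structure file contains no polymer chains."""


class FormatOverflowError(ValidationError):
    """Structure does not fit the fixed-width PDB dialect (e.g. >9999 residues)."""


class ChainLookupError(ValidationError):
    """Requested chain id is not present in the structure."""


class DegenerateSegmentError(ValidationError):
    """A helix segment has too few Calpha atoms for an axis fit."""


class MeasurementError(ValidationError):
    """A geometric measurement is impossible (e.g. missing anchor Calpha)."""


class JunctionOrderError(ValidationError):
    """Fusion entry point does not precede the exit point."""


class NumberingError(ValidationError):
    """Residue number outside the declared numbering range."""


class MutationError(ValidationError):
    """A tag mutation addresses a nonexistent position or mismatched residue."""


class EmptyDesignError(ValidationError):
    """No valid (entry, exit) pair remains in a fusion design."""


class ModelMismatchError(ValidationError):
    """Predicted model sequence disagrees with the construct it claims to realize."""


class DomainDefinitionError(ValidationError):
    """Clash-detection domains overlap or fall outside the model."""


class ConfigError(ValidationError):
    """Malformed configuration or annotation table."""


class FixtureError(ValidationError):
    """A synthetic fixture request is geometrically impossible."""
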