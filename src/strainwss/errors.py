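"""Exception hierarchy for strainwss."""


class StrainWSSError(Exception):
    """Base class for all strainwss errors."""


class CatalogError(StrainWSSError):
    """Reference catalog is malformed (missing/duplicate IDs, empty FASTA)."""


class InputError(StrainWSSError):
    """An input file violates its format contract."""


class CoordinateError(InputError):
    """A coordinate falls outside the reference."""


class FormatError(InputError):
    """A field value is not parseable / out of domain."""


class MergeError(StrainWSSError):
    """Profiles cannot be merged (mixed references or individuals)."""


class ComparisonError(StrainWSSError):
    """Profiles cannot be compared (mismatched references)."""


class ParameterError(StrainWSSError):
    """A parameter is outside its allowed domain."""


class TreeError(StrainWSSError):
    """Distance matrix or tree construction failure."""
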