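"""Exception hierarchy used across the package."""


class StrainSiftError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StrainSiftError, ValueError):
    """A parameter is outside its documented range."""


class FormatError(StrainSiftError, ValueError):
    """An input file could not be parsed."""


class InputError(StrainSiftError, ValueError):
    """Inputs are structurally invalid (duplicates, mismatched ids, ...)."""


class IndexError_(StrainSiftError):
    """A serialized index is missing, corrupt, or version-incompatible."""
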