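"""Exception hierarchy for the biogeo pipeline."""


class BiogeoError(Exception):
    """Base class for all biogeo errors."""


class FormatError(BiogeoError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(BiogeoError, ValueError):
    """A value violates a controlled vocabulary or range constraint."""


class IntegrityError(BiogeoError, ValueError):
    """Cross-references between tables are inconsistent."""


class ParameterError(BiogeoError, ValueError):
    """A numeric parameter is outside its admissible range."""
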