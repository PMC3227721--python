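"""Exception hierarchy for ciscompare.

Every error raised deliberately by the package derives from
:class:`CiscompareError`, so pipeline drivers can distinguish expected
input/configuration failures from bugs.
"""


class CiscompareError(Exception):
    """Base class for all ciscompare errors."""


class DegenerateMatrixError(CiscompareError):
    """A matrix position has zero total count and zero pseudocount."""


class AmbiguousBaseError(CiscompareError):
    """A window passed to the scorer contains a non-ACGT symbol."""


class CalibrationError(CiscompareError):
    """Cutoff calibration received unusable inputs (e.g. no true sites)."""


class ContrastError(CiscompareError):
    """Invalid positive/negative sequence grouping."""


class VocabularyError(CiscompareError):
    """An expression-territory label is outside the controlled vocabulary."""


class ConsistencyError(CiscompareError):
    """Cross-referenced identifiers do not resolve (hit vs sequence set)."""


class TransfacFormatError(CiscompareError):
    """Malformed TRANSFAC flat-file input; message names record and line."""


class FastaError(CiscompareError):
    """Malformed FASTA input (empty file, duplicate identifiers)."""


class PlacementError(CiscompareError):
    """Motif planting could not satisfy the non-overlap constraint."""


class ParameterError(CiscompareError):
    """A generator or scoring parameter is out of range."""


class ConfigError(CiscompareError):
    """Invalid pipeline configuration (unknown mode, unresolvable IDs)."""
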