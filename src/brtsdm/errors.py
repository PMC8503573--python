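"""Exception hierarchy shared across the pipeline stages."""


class BrtsdmError(Exception):
    """Base class for all package errors."""


class AscFormatError(BrtsdmError):
    """Malformed ESRI ASCII grid header or body."""


class DimensionError(AscFormatError):
    """Row/column count of the data block disagrees with the header."""


class AlignmentError(BrtsdmError):
    """Layers of a stack do not share an identical georeference header."""


class ConfigurationError(BrtsdmError):
    """A referenced layer, parameter or config entry is missing or invalid."""


class EmptyInputError(BrtsdmError):
    """An operation received an empty record list or table."""


class SamplingError(BrtsdmError):
    """Random sampling is impossible (no mass, or not enough eligible cells)."""


class DegenerateFitError(BrtsdmError):
    """Model fitting received degenerate data (single class, constant response)."""


class UndefinedStatisticError(BrtsdmError):
    """A statistic (AUC, relative influence) is undefined for the given input."""


class ConsistencyError(BrtsdmError):
    """Internal consistency violated (e.g. presence/background cell overlap)."""


class ClassificationError(BrtsdmError):
    """Natural-breaks classification impossible (too few distinct values)."""


class NormalizationError(BrtsdmError):
    """Min-max normalization impossible because a layer is constant."""


class EnsembleError(BrtsdmError):
    """Too many ensemble iterations failed."""
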