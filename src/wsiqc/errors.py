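"""Exception hierarchy for wsiqc.

Everything derives from :class:`WsiQcError` so callers can catch the whole
family; the leaf classes mirror the failure modes of the public API
(domain checks, geometry, class schemes, model configuration, I/O of
paired records).
"""


class WsiQcError(Exception):
    """Base class for all wsiqc errors."""


class DomainError(WsiQcError, ValueError):
    """A scalar argument is outside its valid domain (e.g. power <= 0)."""


class BoundsError(WsiQcError, ValueError):
    """A requested box or point lies outside the raster extent."""


class ResolutionError(WsiQcError, ValueError):
    """A resolution finer than the slide's base level was requested."""


class MappingError(WsiQcError, KeyError):
    """An unknown class label or artifact kind was supplied."""


class SchemeError(WsiQcError, ValueError):
    """A mask or model carries the wrong class scheme for the operation."""


class ShapeError(WsiQcError, ValueError):
    """Array dimensions do not match the operation's contract."""


class ConfigError(WsiQcError, ValueError):
    """An invalid model or pipeline configuration."""


class DataError(WsiQcError, ValueError):
    """A dataset is empty or otherwise unusable."""


class GenerationError(WsiQcError, RuntimeError):
    """A synthetic-data constraint could not be satisfied."""


class PairingError(WsiQcError, ValueError):
    """Paired-record analysis received incomplete pairs."""
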