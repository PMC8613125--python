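"""Exception hierarchy shared across the package."""


class CueshiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CueshiftError, ValueError):
    """Input violates a documented precondition."""


class ParseError(CueshiftError, ValueError):
    """Structured file could not be parsed; message names the offending line."""


class DegenerateScanError(CueshiftError, ValueError):
    """Torsion scan carries no information (all energies equal)."""


class MissingConformerError(CueshiftError, ValueError):
    """An ensemble lacks a conformer required by the requested analysis."""


class NoDonorHydrogenError(CueshiftError, ValueError):
    """Hydrogen-bond donor atom has no covalently bound hydrogen."""


class AtomMismatchError(CueshiftError, ValueError):
    """Two structures cannot be put in atom-wise correspondence."""


class InsufficientDataError(CueshiftError, ValueError):
    """Too few records to fit or test anything."""


class DegenerateFitError(CueshiftError, ValueError):
    """Regression input has no variance on the predictor side."""


class UnbalancedDesignError(CueshiftError, ValueError):
    """Paired assay design has missing (subject, treatment) cells."""


class ConfigError(CueshiftError, ValueError):
    """Synthetic-data generator configuration is inconsistent."""
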