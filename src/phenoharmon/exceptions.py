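"""Exception hierarchy for phenoharmon.

All package errors derive from :class:`PhenoharmonError` so callers can
catch one base class at pipeline boundaries.
"""


class PhenoharmonError(Exception):
    """Base class for all phenoharmon errors."""


class ConfigurationError(PhenoharmonError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(PhenoharmonError):
    """Simulation could not satisfy its contract (e.g. ascertainment quota)."""


class CalibrationError(PhenoharmonError):
    """A calibration target (e.g. a kappa value) is unattainable."""


class LookupError_(PhenoharmonError):
    """Unknown subtype, system or definition name."""


class EstimationError(PhenoharmonError):
    """Degenerate input to a statistical estimator."""


class FormatError(PhenoharmonError):
    """Malformed input file; carries column / line context in the message."""


class HarmonizationError(PhenoharmonError):
    """Allele harmonization failed (strand or allele mismatch)."""
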