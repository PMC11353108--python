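"""Exception hierarchy for the livercond pipeline.

The CLI maps these onto exit codes: configuration problems → 2, data
problems → 3, degenerate statistical situations → 4.
"""


class LiverCondError(Exception):
    """Base class for all livercond errors."""


class ConfigurationError(LiverCondError):
    """Invalid configuration or parameter values (CLI exit code 2)."""


class SpectrumParseError(LiverCondError):
    """Malformed spectrum or cohort CSV (CLI exit code 3)."""


class SingularImpedanceError(LiverCondError):
    """R = X = 0 at some frequency: admittance undefined (exit code 3)."""


class GridMismatchError(LiverCondError):
    """Tissue and calibration frequency grids differ (exit code 3)."""


class DegenerateBufferError(LiverCondError):
    """Reference buffer with non-positive conductance (exit code 3)."""


class ProbeFitError(LiverCondError):
    """Tumor smaller than the electrode array span (exit code 3)."""


class MissingGroupError(LiverCondError):
    """A group required for a ratio or test is absent (exit code 4)."""


class DegenerateDataError(LiverCondError):
    """Statistical test cannot run (e.g. all values tied) (exit code 4)."""
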