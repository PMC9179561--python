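"""Exception hierarchy.

Everything raised on bad user input derives from :class:`ValidationError`;
errors that signal a failed internal procedure (calibration, placement)
have their own classes so pipelines can annotate and re-raise them.
"""


class MicroglioqError(Exception):
    """Base class for all package errors."""


class ValidationError(MicroglioqError, ValueError):
    """Invalid argument or domain-object invariant violation."""


class DegenerateHistogramError(MicroglioqError):
    """Otsu thresholding requested on a constant-intensity region."""


class CalibrationError(MicroglioqError):
    """Retraction calibration target outside the achievable RI range."""


class PlacementError(MicroglioqError):
    """Poisson-disk cell placement failed within the retry budget."""
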