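"""Exception hierarchy."""


class BarcodeGapError(Exception):
    """Base class for all errors raised by barcodegap."""


class MalformedNameError(BarcodeGapError):
    """A taxon name string could not be parsed."""


class ValidationError(BarcodeGapError):
    """An input table failed validation; the message names the offending row/column."""


class DegenerateFitError(BarcodeGapError):
    """A model fit is undefined for the supplied data (e.g. zero-spread sample)."""


class FitConvergenceError(BarcodeGapError):
    """A numerical optimisation failed to converge."""
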