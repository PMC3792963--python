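"""Exception hierarchy for the perivasc pipeline.

Every error a caller is expected to handle (skip a field, fall back to a
different threshold rule, refuse a statistic) has its own class so that
handling code never has to parse message strings.
"""


class PerivascError(Exception):
    """Base class for all perivasc errors."""


class MissingChannel(PerivascError, KeyError):
    """A named channel does not exist on the field image."""


class DegenerateHistogram(PerivascError):
    """Otsu thresholding was requested on a constant-valued channel."""


class NoVesselInField(PerivascError):
    """A vessel mask contains no vessel pixel; distances are undefined."""


class FieldTooSmall(PerivascError):
    """The scan grid is smaller than the requested counting window."""


class NoValidField(PerivascError):
    """No candidate window survives the excluded-area eligibility cut."""


class InsufficientFields(PerivascError):
    """Fewer than the required number of usable fields for an animal."""


class InsufficientData(PerivascError):
    """Too few values to compute the requested statistic."""


class UnequalSubgroups(PerivascError):
    """Subgroup summaries with unequal n cannot be pooled by this design."""


class DegenerateAnova(PerivascError):
    """Zero within-group variance: the F statistic is undefined."""


class InconsistentSpec(PerivascError):
    """A synthetic-field specification is internally contradictory."""


class IOFailure(PerivascError):
    """A manifest record points at a file that cannot be read or written."""
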