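"""Exception hierarchy for grace_melt.

Everything raised deliberately by this package derives from
:class:`GraceMeltError`, so callers (and the CLI) can catch one type.
"""


class GraceMeltError(Exception):
    """Base class for all grace_melt errors."""


class PanelConfigError(GraceMeltError):
    """A panel configuration file is malformed or violates panel invariants."""


class MeltCsvError(GraceMeltError):
    """A melt-curve CSV file cannot be parsed into a valid run."""


class ParameterError(GraceMeltError):
    """A signal-processing parameter is out of its valid range."""


class PlacementError(GraceMeltError):
    """No sufficiently flat plateau exists to place a normalization window."""


class NormalizationError(GraceMeltError):
    """The two-window normalization is degenerate (pre and post levels coincide)."""


class ReferencePeakError(GraceMeltError):
    """The reference-gene melt peak is absent; the sample cannot be quantified."""


class RunQCError(GraceMeltError):
    """Run-level quality control failed (e.g. the wild-type control miscalls)."""


class ValidationInputError(GraceMeltError):
    """Calls and truth table cannot be reconciled."""
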