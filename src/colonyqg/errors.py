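"""Exception hierarchy used across the package.

Every error raised on purpose derives from :class:`ColonyQGError`, so callers
can catch package failures with a single except clause while still
distinguishing argument problems (``ValueError`` subclasses) from data
problems.
"""


class ColonyQGError(Exception):
    """Base class for all errors raised by colonyqg."""


class InvalidArgumentError(ColonyQGError, ValueError):
    """An argument violates a documented precondition."""


class InvalidCoordinateError(InvalidArgumentError):
    """A nest coordinate lies outside the island rectangle."""


class SchemaError(ColonyQGError, KeyError):
    """A required column is missing from a table; the message names it."""


class GroupingError(ColonyQGError, ValueError):
    """Records from different seasons were mixed where one season is required."""


class CyclicPedigreeError(ColonyQGError, ValueError):
    """The pedigree contains an ancestry cycle.

    ``cycle`` holds one offending id sequence, closed (first == last).
    """

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "pedigree contains a cycle: " + " -> ".join(map(str, self.cycle))
        )


class DuplicateRecordError(ColonyQGError, ValueError):
    """The same individual id appears more than once in a pedigree."""


class InconsistentPedigreeError(ColonyQGError, ValueError):
    """An operation referenced an individual absent from the pedigree."""


class DegenerateColumnError(ColonyQGError, ValueError):
    """A column required to have positive variance is constant."""


class ConfigError(ColonyQGError, ValueError):
    """A run configuration is incomplete or self-contradictory."""


class SamplerError(ColonyQGError, RuntimeError):
    """The MCMC sampler failed (non-finite deviance, decomposition failure)."""


class InsufficientSamplesError(ColonyQGError, ValueError):
    """A posterior summary was requested from too few samples."""


class WrongModelError(ColonyQGError, ValueError):
    """A summary was requested from chains of an incompatible model type."""


class AlignmentError(ColonyQGError, ValueError):
    """Two chains that must be compared elementwise have different lengths."""


class UndefinedStatisticError(ColonyQGError, ValueError):
    """A statistic (autocorrelation, correlation) is undefined, e.g. zero variance."""
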