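"""Exception types shared across the pipeline stages."""


class NoduleWalkError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(NoduleWalkError, ValueError):
    """A phantom specification violates its invariants."""


class InvalidParamsError(NoduleWalkError, ValueError):
    """Stage parameters are outside their admissible range."""


class FormatError(NoduleWalkError, ValueError):
    """Input array has the wrong shape, dtype or channel layout."""


class SeedError(NoduleWalkError, ValueError):
    """A seed map is missing a required label class."""


class EmptyRegionError(NoduleWalkError, ValueError):
    """A region-based operation received an empty mask."""


class DegenerateRegionError(NoduleWalkError, ValueError):
    """A region is too small for the requested statistic."""


class ContractError(NoduleWalkError, ValueError):
    """A numeric contract (normalisation, count balance) was violated."""


class TrainingError(NoduleWalkError, ValueError):
    """Classifier training preconditions are not met."""
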