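"""Exception hierarchy for mutprop.

Every validation failure raises a subclass of :class:`MutpropError` so callers
(and the CLI) can catch one base class and report a machine-readable error
class name.
"""


class MutpropError(Exception):
    """Base class for all mutprop errors."""


class PropertyTableError(MutpropError):
    """Malformed property table (missing residue column, duplicate id, non-numeric cell)."""


class DegeneratePropertyError(PropertyTableError):
    """All 20 residue values of a property are identical; min-max normalization is undefined."""


class ResidueLookupError(MutpropError):
    """Residue code is not one of the 20 standard one-letter amino-acid codes."""


class PropertyLookupError(MutpropError):
    """Unknown property identifier."""


class FeatureContextError(MutpropError):
    """A requested feature encoding lacks its required context (sequence or structure)."""


class StructureError(MutpropError):
    """Invalid structural context (unknown position, malformed coordinates)."""


class DatasetValidationError(MutpropError):
    """Mutant dataset violates its invariants (wild == mutant, sequence mismatch, ...)."""


class InsufficientDataError(MutpropError):
    """Regression refused: fewer observations than parameters + 2 (saturated fit)."""


class CollinearityError(MutpropError):
    """Design matrix is rank deficient; names the dependent columns."""

    def __init__(self, message: str, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class UndefinedStatisticError(MutpropError):
    """A statistic (correlation, sensitivity, specificity) has a zero denominator."""


class SearchSpaceError(MutpropError):
    """Exhaustive search refused: enumerated model count exceeds the configured ceiling."""

    def __init__(self, message: str, n_models: int):
        super().__init__(message)
        self.n_models = n_models


class LabelingError(MutpropError):
    """A response value cannot be converted to an increase/decrease label."""


class SingleClassError(MutpropError):
    """Classification requested on data containing only one class."""


class UnknownMethodError(MutpropError):
    """Classifier method id not in the bundled set."""


class ConfigError(MutpropError):
    """Invalid run configuration (missing path, bad setting)."""
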