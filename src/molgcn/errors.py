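"""Exception hierarchy shared across the package."""


class MolGCNError(Exception):
    """Base class for all package errors."""


class InputError(MolGCNError):
    """A required input file is missing or unreadable."""


class EmptyDatasetError(MolGCNError):
    """No usable compounds remained after parsing/filtering."""


class SchemaError(MolGCNError):
    """A tabular input violates its declared schema."""


class ValueCoercionError(MolGCNError):
    """A label cell is neither binary nor empty."""


class FeaturizationError(MolGCNError):
    """A molecule cannot be converted to the graph representation."""


class BalanceError(MolGCNError):
    """The negative pool cannot equalize class counts."""


class SplitError(MolGCNError):
    """A requested split or fold assignment is impossible."""


class SpecError(MolGCNError):
    """A model specification violates layer-ordering or shape rules."""


class TrainingError(MolGCNError):
    """Training cannot proceed (e.g. no observed labels)."""


class CompatibilityError(MolGCNError):
    """Dataset and model feature configurations disagree."""


class AttributionError(MolGCNError):
    """Attribution was requested for an invalid task or input."""


class RenderError(MolGCNError):
    """Importance vector and molecule do not align for rendering."""


class OptimizationError(MolGCNError):
    """Hyper-parameter optimization produced no successful trial."""


class GenerationError(MolGCNError):
    """Synthetic fixture generation failed after bounded retries."""
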