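"""Exception taxonomy shared across the package."""


class HncnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HncnetError):
    """Invalid configuration values (bad specs, bad bounds, missing seeds)."""


class AlignmentError(HncnetError):
    """Image and mask do not share shape/spacing."""


class DegenerateInputError(HncnetError):
    """Structurally empty input (e.g. an empty GTV mask)."""


class DataError(HncnetError):
    """Clinical table violates the schema (missing follow-up, all-missing column)."""


class StratificationError(HncnetError):
    """Too few members of a class to build stratified folds."""


class ArchitectureError(HncnetError):
    """Layer configuration does not produce the contracted tensor shapes."""


class TrainingError(HncnetError):
    """Training cannot proceed (single-class split, divergent loss)."""
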