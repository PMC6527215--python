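"""Exception hierarchy shared across the pipeline stages."""


class VfdetectError(Exception):
    """Base class for all package errors."""


class ReadError(VfdetectError):
    """Missing, corrupt or mutually inconsistent record files."""


class LabelingError(VfdetectError):
    """Annotation or rhythm code outside the closed vocabulary."""


class SplitError(VfdetectError):
    """Patient-wise partitioning is infeasible (e.g. < 2 patients)."""


class FilteringError(VfdetectError):
    """Signal too short (or otherwise unusable) for a filtering stage."""


class ArchitectureError(VfdetectError):
    """Network hyperparameters incompatible with the input length."""


class TrainingError(VfdetectError):
    """Optimization failure (divergence, degenerate labels)."""


class ThresholdError(VfdetectError):
    """Decision-threshold selection needs both classes present."""


class FeatureError(VfdetectError):
    """Feature extraction requested from an incompatible model."""


class RegistryError(VfdetectError):
    """Unknown feature name requested from the feature registry."""


class ConfigError(VfdetectError):
    """Infeasible or inconsistent experiment/cohort configuration."""
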