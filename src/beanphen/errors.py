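"""Exception hierarchy for beanphen."""


class BeanPhenError(Exception):
    """Base class for all beanphen errors."""


class FormatError(BeanPhenError):
    """An input file violates its documented format."""


class ContinuityError(FormatError):
    """A weather series has a gap or duplicate date."""


class SchemaError(BeanPhenError):
    """A config references an unknown covariate, marker, or field."""


class ModelError(BeanPhenError):
    """A trait model term cannot be evaluated for the given inputs."""


class DeterminacyError(ModelError):
    """Growth-habit (determinacy) of a genotype cannot be resolved."""


class RangeError(BeanPhenError):
    """A requested window falls outside the available data."""


class UnsupportedLatitudeError(BeanPhenError):
    """Day-length computation was requested for a polar latitude."""


class MetricError(BeanPhenError):
    """Evaluation statistics cannot be computed for the given vectors."""


class ObjectiveError(BeanPhenError):
    """A calibration objective has no matching observations."""
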