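"""Exception and warning taxonomy shared across the package."""


class AismatureError(Exception):
    """Base class for all package errors."""


class SchemaError(AismatureError):
    """A table or record set does not have the expected columns/keys."""


class FormatError(AismatureError):
    """A file's contents violate the declared format (e.g. non-monotonic time)."""


class UnitError(AismatureError):
    """Required unit declaration is missing or inconsistent."""


class ParameterError(AismatureError, ValueError):
    """A physical parameter is out of its admissible range."""


class ProtocolError(AismatureError):
    """A step-protocol set violates its contract (ordering, emptiness...)."""


class QualityError(AismatureError):
    """A fit or measurement failed its quality gate."""


class GeometryError(AismatureError):
    """A path or profile does not cover the required spatial extent."""


class DetectionError(AismatureError):
    """A threshold/half-max criterion was never met on the data."""


class NoAPError(DetectionError):
    """No action potential satisfying the criterion is present."""


class RheobaseNotFoundError(DetectionError):
    """No step in the protocol elicited a spike."""


class ShapeError(AismatureError):
    """Waveform lacks the landmarks required by the measurement."""


class StabilityError(AismatureError):
    """Numerical integration diverged (reduce the time step)."""


class InsufficientDataError(AismatureError):
    """Fewer samples/groups than the statistic requires."""


class AismatureWarning(UserWarning):
    """Base class for non-fatal analysis warnings."""


class BaselineDriftWarning(AismatureWarning):
    """Baseline drifted beyond the stability criterion."""


class LowerBoundWarning(AismatureWarning):
    """Smallest protocol step already spiking: rheobase is only an upper bound."""


class ReliabilityWarning(AismatureWarning):
    """Estimate close to the noise floor."""
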