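"""Exception hierarchy for the roqsar package."""


class RoqsarError(Exception):
    """Base class for all roqsar errors."""


class ParseError(RoqsarError):
    """Molecular structure input could not be parsed."""


class EmptyGraphError(RoqsarError):
    """Operation requires a graph with at least one edge."""


class DescriptorError(RoqsarError):
    """Descriptor computation failed for a molecule."""


class GeometryError(DescriptorError):
    """3D coordinates required but unavailable."""


class TableLookupError(DescriptorError):
    """A bond type or element is missing from a parameter table."""


class FixtureError(RoqsarError):
    """Packaged dataset fixture is corrupted or inconsistent."""


class AssemblyError(RoqsarError):
    """Dataset components could not be aligned."""


class SelectionError(RoqsarError):
    """Feature-selection cascade failed."""


class ScalingError(RoqsarError):
    """Degenerate variable encountered during min-max scaling."""


class TrainingError(RoqsarError):
    """Network training misconfigured or diverged."""


class SingularityError(RoqsarError):
    """Design matrix is rank deficient."""


class MetricsError(RoqsarError):
    """Fit statistic undefined for the given vectors."""
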