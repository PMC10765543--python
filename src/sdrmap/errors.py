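"""Exception hierarchy shared across the package."""


class SdrmapError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SdrmapError):
    """Invalid needle-lattice geometry (duplicate coordinates, bad level...)."""


class GridLookupError(SdrmapError, KeyError):
    """A needle or electrode address does not exist in the grid."""


class ParameterError(SdrmapError, ValueError):
    """A generator or analysis parameter violates its contract."""


class SpecificationError(SdrmapError, ValueError):
    """An inconsistent synthetic-protocol specification (e.g. a >10 s
    tachyarrhythmia episode declared with zero defibrillations)."""


class DetectionError(SdrmapError):
    """Fiducial detection failed on a degenerate signal (e.g. flat line)."""


class MeasurementError(SdrmapError):
    """Interval measurement could not be completed (too few beats...)."""


class AnalysisError(SdrmapError):
    """A dispersion/restitution computation has no valid input (e.g. one
    ventricle fully rejected)."""


class ContractError(SdrmapError, ValueError):
    """An operation was called on an object that does not satisfy its
    preconditions (e.g. scoring a non-TdP episode)."""


class ValidationError(SdrmapError, ValueError):
    """A run configuration failed validation.

    Carries the full list of violations so a caller can report all of
    them at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(
            f"  - {v}" for v in self.violations))


class ComparisonError(SdrmapError, ValueError):
    """Two runs cannot be compared (geometry or schema mismatch)."""
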