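"""Exception and warning types shared across the simulator."""


class EggSimError(Exception):
    """Base class for all eggsim errors."""


class InvalidParameterError(EggSimError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateSegmentError(EggSimError, ValueError):
    """Two consecutive centerline points coincide (zero-length segment)."""


class InvalidGeometryError(EggSimError, ValueError):
    """A geometric configuration the model cannot represent."""


class SingularityError(EggSimError, ValueError):
    """An electrode coincides (or nearly coincides) with a dipole location."""


class NumericError(EggSimError, ArithmeticError):
    """A quadrature or sub-expression left its valid numeric domain."""


class ComparisonError(EggSimError, ValueError):
    """Two signals cannot be compared (length / alignment mismatch)."""


class UnsupportedComparisonError(EggSimError, ValueError):
    """No conventional reference model exists for the requested scenario."""


class DegenerateQuadWarning(UserWarning):
    """A surface quad has zero area (pinched tube); it carries no dipole."""
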