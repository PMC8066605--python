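"""Exception hierarchy for the tubewidth pipeline."""


class TubeWidthError(Exception):
    """Base class for all tubewidth errors."""


class ParameterError(TubeWidthError, ValueError):
    """A parameter violates its contract (e.g. sigma <= 0, z1 >= z2)."""


class DimensionError(TubeWidthError, ValueError):
    """Input image has the wrong shape or channel count."""


class InsufficientEdgesError(TubeWidthError):
    """Fewer than two edge components were detected.

    Usually means the hysteresis thresholds are too aggressive for the
    image; lower ``z1_frac``/``z2_frac`` or use the manual override.
    """


class EmptySilhouetteError(TubeWidthError):
    """The edge image contained nothing to fill."""


class CentrelineInvariantError(TubeWidthError):
    """The skeleton violated the <=2-neighbour centreline invariant."""
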