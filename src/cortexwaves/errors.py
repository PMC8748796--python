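"""Exception types shared across the package."""


class CortexWavesError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CortexWavesError, ValueError):
    """A configuration object violates its invariants."""


class ConnectomeLoadError(CortexWavesError, ValueError):
    """Connectome matrices/tables on disk are malformed."""


class IntegrationDivergedError(CortexWavesError, RuntimeError):
    """A phase became non-finite during integration.

    Attributes
    ----------
    time : float
        Simulation time (s) at which the non-finite value was detected.
    """

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"non-finite phase encountered at t={time:.6f} s")


class UndefinedMeanError(CortexWavesError, ValueError):
    """The circular mean is undefined (zero resultant vector)."""


class ZeroVarianceError(CortexWavesError, ValueError):
    """A regression covariate has no variance; the slope is undefined."""
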