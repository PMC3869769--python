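"""Exception hierarchy for the melres pipeline."""


class MelresError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(MelresError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class DegenerateResponseError(MelresError, ValueError):
    """The regression response (e.g. GI50) has zero variance."""


class DegenerateCovariateError(MelresError, ValueError):
    """A Cox covariate column is constant across subjects."""


class ConvergenceError(MelresError, RuntimeError):
    """Newton-Raphson failed to converge (e.g. monotone partial likelihood)."""


class EmptySignatureError(MelresError, ValueError):
    """A gene signature with no probes was produced or supplied."""


class MissingProbeError(MelresError, KeyError):
    """Signature probes are absent from an expression matrix."""

    def __init__(self, probe_ids):
        self.probe_ids = list(probe_ids)
        super().__init__(
            "probes missing from expression matrix: " + ", ".join(self.probe_ids)
        )


class UnweightedSignatureError(MelresError, ValueError):
    """A resistance index was requested from a signature lacking new weights."""


class DegenerateStratificationError(MelresError, ValueError):
    """All resistance indices are identical; percentile strata are undefined."""


class UndefinedROCError(MelresError, ValueError):
    """Time-dependent ROC is undefined (no events by, or no survivors past, the horizon)."""
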