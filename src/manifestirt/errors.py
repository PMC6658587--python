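"""Structured exceptions for improper distributions and numerical failures."""


class ManifestIRTError(Exception):
    """Base class for all package-specific errors."""


class ImproperLatentDistributionError(ManifestIRTError):
    """The latent distribution g(zeta) has a divergent normalizing constant.

    g is proper only when 0 < Z = integral of prod_i Z_i(zeta) k(zeta) < inf;
    the ``condition`` attribute names the violated finiteness condition.
    """

    def __init__(self, message: str, condition: str = ""):
        super().__init__(message)
        self.condition = condition


class DivergentExpectationError(ManifestIRTError):
    """E[exp(r1*theta - r2*theta^2/2)] diverges (r2*v^2 + 1 <= 0)."""


class QuadratureConvergenceError(ManifestIRTError):
    """Adaptive quadrature did not reach the requested relative tolerance."""


class SeriesConvergenceError(ManifestIRTError):
    """Truncated series did not converge within the allowed number of terms."""


class NonFiniteNormalizerError(ManifestIRTError):
    """An item normalizer Z_i(zeta) evaluated to a non-finite value."""

    def __init__(self, message: str, item_index: int | None = None):
        super().__init__(message)
        self.item_index = item_index


class UnsupportedModelError(ManifestIRTError):
    """Operation not defined for this model family (e.g. curved items)."""


class ParameterError(ManifestIRTError):
    """Invalid model parameters or malformed parameter file."""
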