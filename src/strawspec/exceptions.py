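"""Exception hierarchy for strawspec.

All domain errors derive from :class:`StrawspecError` so callers can catch
pipeline failures with one clause while still distinguishing misuse
(``ValueError`` subclasses) from numerical failure (``RuntimeError``).
"""


class StrawspecError(Exception):
    """Base class for all strawspec errors."""


class SpectralDomainError(StrawspecError, ValueError):
    """An intensity or absorbance value falls outside the formula's domain
    (e.g. non-positive net intensity under the log)."""


class GridMismatchError(StrawspecError, ValueError):
    """Two objects that must share a wavelength grid do not."""


class FormatError(StrawspecError, ValueError):
    """A tabular spectral file violates the expected layout."""


class DegenerateDataError(StrawspecError, ValueError):
    """Input data carry no usable variance (e.g. constant response)."""


class ConvergenceError(StrawspecError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class ConfigError(StrawspecError, ValueError):
    """A configuration object violates its invariants."""
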