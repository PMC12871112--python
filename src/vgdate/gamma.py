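"""Gamma distributions in canonical and natural parameterizations.

The Gamma family is the currency of the whole package: every message,
cavity and posterior in the expectation-propagation engine is a Gamma
(possibly non-normalizable when viewed as a single factor).  Two views
are used throughout:

* canonical ``(shape, rate)`` — density proportional to
  ``t**(shape-1) * exp(-rate*t)``; normalizable iff shape > 0, rate > 0.
* natural ``(shape-1, -rate)`` — the log-linear coefficients of the
  sufficient statistics ``(log t, t)``.  Factors are added/subtracted in
  this view.

Internally the engine stores factors as ``(a, b)`` pairs with density
``t**a * exp(-b*t)``, i.e. ``a = shape-1`` and ``b = rate`` (the sign of
the second natural coordinate is flipped for readability; conversion to
the signed natural view is exact either way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GammaParams:
    """A Gamma distribution with shape ``alpha`` and rate ``beta``."""

    shape: float
    rate: float

    @property
    def natural(self) -> tuple[float, float]:
        """Natural parameters ``(shape - 1, -rate)``."""
        return (self.shape - 1.0, -self.rate)

    @classmethod
    def from_natural(cls, n1: float, n2: float) -> "GammaParams":
        return cls(shape=n1 + 1.0, rate=-n2)

    @property
    def is_proper(self) -> bool:
        return self.shape > 0.0 and self.rate > 0.0

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2

    def quantile(self, q):
        return stats.gamma.ppf(q, self.shape, scale=1.0 / self.rate)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (float(self.quantile(lo)), float(self.quantile(1.0 - lo)))


def moments_to_canonical(m1: float, m2: float) -> tuple[float, float]:
    """Shape and rate of the Gamma matching first two raw moments.

    Raises ``ValueError`` on a degenerate pair (``m2 <= m1**2``), which
    callers treat as a signal to project or skip.
    """
    var = m2 - m1 * m1
    if not (var > 0.0 and m1 > 0.0) or not np.isfinite(var):
        raise ValueError(f"degenerate moments m1={m1}, m2={m2}")
    return (m1 * m1 / var, m1 / var)


def moments_to_natural(m1: float, m2: float) -> tuple[float, float]:
    """Natural parameters ``(m1^2/(m2-m1^2) - 1, -m1/(m2-m1^2))``."""
    shape, rate = moments_to_canonical(m1, m2)
    return (shape - 1.0, -rate)
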