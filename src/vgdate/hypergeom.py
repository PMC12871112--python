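"""Log-space evaluation of Gauss hypergeometric ratios for EP moments.

The surrogate distribution attached to one ARG edge has density
proportional to::

    t_i**(ai-1) * t_j**(aj-1) * (t_i - t_j)**y
        * exp(-bi*t_i - bj*t_j - mus*(t_i - t_j)),   0 < t_j < t_i,

where ``(ai, bi)`` and ``(aj, bj)`` are the parent/child cavity Gamma
parameters, ``y`` the mutation count and ``mus`` the expected mutations
per generation on the edge.  Its moments reduce to ratios ``F_n/F_0`` of
Gauss hypergeometric values

    F_n = 2F1(aj + n, T + n; aj + y + n + 1; z),
    T = ai + aj + y,    z = (mus - bj) / (mus + bi),

which this module evaluates stably for the full feasible range z < 1:

* a log-scaled power series — after a Pfaff transformation for z < 0
  chosen so that every term is positive (the transformed parameters
  ``(y + 1, T + n)`` are positive), so no cancellation can occur;
* a tanh-sinh (double-exponential) quadrature of the defining Euler
  integral as fallback when the series would need too many terms.

Accuracy contract: relative error <= 1e-8 against an adaptive 2-D
quadrature oracle on the test grid exercised in the test-suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["log_hyp2f1_pos", "hyp_f_ratios"]

_MAX_TERMS = 4000
_SERIES_RTOL = 1e-14


class SeriesNotConverged(RuntimeError):
    pass


def _log_series_pos_impl(a: float, b: float, c: float, z: float,
                         max_terms: int) -> float:
    # all terms positive: accumulate in linear space with periodic
    # rescaling (no cancellation possible); NaN signals non-convergence
    if z == 0.0:
        return 0.0
    term = 1.0
    total = 1.0
    offset = 0.0  # log of the factor divided out of `total`
    for k in range(max_terms):
        term *= (a + k) * (b + k) / ((c + k) * (k + 1.0)) * z
        total += term
        if (term < _SERIES_RTOL * total
                and (a + k) * (b + k) * z < (c + k) * (k + 1.0)):
            return offset + math.log(total)
        if total > 1e250:
            offset += math.log(total)
            term /= total
            total = 1.0
    return math.nan


try:  # hot loop: compile when numba is available, else run as-is
    from numba import njit

    _log_series_pos_fast = njit("float64(float64, float64, float64, "
                                "float64, int64)", cache=True,
                                nogil=True)(_log_series_pos_impl)
except ImportError:  # pragma: no cover
    _log_series_pos_fast = _log_series_pos_impl


def _log_series_pos(a: float, b: float, c: float, z: float,
                    max_terms: int = _MAX_TERMS) -> float:
    """log 2F1(a,b;c;z) by direct summation; requires a,b,c > 0, 0 <= z < 1.

    Raises ``SeriesNotConverged`` when the term budget is exhausted.
    """
    val = _log_series_pos_fast(a, b, c, z, max_terms)
    if math.isnan(val):
        raise SeriesNotConverged(f"2F1 series: {max_terms} terms at z={z}")
    return val


def log_hyp2f1_pos(a: float, b: float, c: float, z: float) -> float:
    """log 2F1(a,b;c;z) for a,b,c > 0 and z < 1, via series with a Pfaff
    transform for negative arguments.

    For z < 0 the Pfaff transform on the second parameter,
    ``2F1(a,b;c;z) = (1-z)**-b * 2F1(c-a, b; c; z/(z-1))``, maps the
    argument into (0, 1); for the EP use-case ``c - a = y + 1 > 0`` so the
    transformed series again has positive terms only.

    Raises ``SeriesNotConverged`` when the argument is too close to 1 for
    the series to converge within the term budget.
    """
    if not z < 1.0:
        raise ValueError(f"hypergeometric argument must satisfy z < 1, got {z}")
    if z < 0.0:
        w = z / (z - 1.0)
        if not c - a > 0.0:
            raise ValueError("Pfaff-transformed series requires c - a > 0")
        return -b * np.log1p(-z) + _log_series_pos(c - a, b, c, w)
    return _log_series_pos(a, b, c, z)


# ---------------------------------------------------------------------------
# tanh-sinh quadrature fallback on the Euler integral
#
#   I_n = int_0^1 x**(aj+n-1) (1-x)**y (1-z*x)**(-(T+n)) dx
#   F_n = Gamma(aj+y+n+1) / (Gamma(aj+n) Gamma(y+1)) * I_n
#
# With the substitution x = sigma(u), u = pi*sinh(t), both x and 1-x are
# logistic values that can be kept in log space, so endpoint singularities
# (aj < 1) and extreme exponents are handled without under/overflow.
# ---------------------------------------------------------------------------

def _de_level(h: float, t_max: float = 10.5):
    t = np.arange(-int(t_max / h), int(t_max / h) + 1) * h
    u = np.pi * np.sinh(t)
    log_sig = -np.logaddexp(0.0, -u)       # log sigma(u)  = log x
    log_sig_neg = -np.logaddexp(0.0, u)    # log sigma(-u) = log(1-x)
    # dx/dt = pi*cosh(t)*sigma(u)*sigma(-u); fold into log weights
    log_w = np.log(h * np.pi * np.cosh(t)) + log_sig + log_sig_neg
    x = np.exp(log_sig)
    return x, log_sig, log_sig_neg, log_w


_DE_LEVELS = [_de_level(1.0 / 24.0), _de_level(1.0 / 48.0), _de_level(1.0 / 96.0)]


def _log_euler_integral(aj: float, y: float, T: float, z: float, n: int,
                        level) -> float:
    x, log_x, log_1mx, log_w = level
    # 1 - z*x computed as (1-x) + x*(1-z): exact split, stable for z -> 1
    one_m_zx = np.exp(log_1mx) + x * (1.0 - z)
    log_f = ((aj + n - 1.0) * log_x + y * log_1mx
             - (T + n) * np.log(one_m_zx) + log_w)
    m = np.max(log_f)
    return m + np.log(np.sum(np.exp(log_f - m)))


def _log_f_de(aj: float, y: float, T: float, z: float, n: int) -> float:
    """log F_n via the Euler integral, refined over a tanh-sinh ladder."""
    from scipy.special import gammaln

    prev = _log_euler_integral(aj, y, T, z, n, _DE_LEVELS[0])
    val = prev
    for level in _DE_LEVELS[1:]:
        val = _log_euler_integral(aj, y, T, z, n, level)
        if np.isfinite(val) and abs(val - prev) <= 1e-10 * max(1.0, abs(val)):
            break
        prev = val
    return val + gammaln(aj + y + n + 1.0) - gammaln(aj + n) - gammaln(y + 1.0)


def hyp_f_ratios(aj: float, y: float, T: float, z: float) -> tuple[float, float]:
    """Return ``(F1/F0, F2/F0)`` for the EP surrogate-moment formulas.

    Parameters are the child cavity shape ``aj``, the edge mutation count
    ``y`` (may be fractional for phase-weighted singletons), the total
    shape ``T = ai + aj + y`` and the argument ``z``.
    """
    try:
        lf0 = log_hyp2f1_pos(aj, T, aj + y + 1.0, z)
        lf1 = log_hyp2f1_pos(aj + 1.0, T + 1.0, aj + y + 2.0, z)
        lf2 = log_hyp2f1_pos(aj + 2.0, T + 2.0, aj + y + 3.0, z)
    except SeriesNotConverged:
        lf0 = _log_f_de(aj, y, T, z, 0)
        lf1 = _log_f_de(aj, y, T, z, 1)
        lf2 = _log_f_de(aj, y, T, z, 2)
    return float(np.exp(lf1 - lf0)), float(np.exp(lf2 - lf0))
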