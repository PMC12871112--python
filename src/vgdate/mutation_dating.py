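"""Mutation-age posteriors and frequency-controlled age z-scores.

A mutation on an edge is taken to be equally likely anywhere along the
edge's time extent; integrating that uniform placement over independent
Gamma posteriors for the parent age ``ti`` and child age ``tj`` gives

    E[m]   = (E[ti] + E[tj]) / 2
    E[m^2] = (E[ti^2] + E[ti] E[tj] + E[tj^2]) / 3

and the mutation posterior is the Gamma matched to those moments.
Independence of parent and child ages is inherited from the factorized
variational posterior; it is an approximation, not a property of the
exact posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamma import GammaParams, moments_to_canonical

__all__ = ["MutationPosterior", "mutation_posterior", "uniform_edge_moments",
           "age_zscore"]


@dataclass(frozen=True)
class MutationPosterior:
    mutation_id: int
    posterior: GammaParams
    mean: float
    variance: float
    lower: float
    upper: float
    dac: int = -1
    daf: float = np.nan


def uniform_edge_moments(m1_parent, m2_parent, m1_child, m2_child):
    """Raw moments of ``Uniform(tj, ti)`` integrated over independent
    parent/child age distributions (vectorized)."""
    m1 = 0.5 * (m1_parent + m1_child)
    m2 = (m2_parent + m1_parent * m1_child + m2_child) / 3.0
    return m1, m2


def mutation_posterior(parent_post: GammaParams,
                       child_post: GammaParams | None,
                       mutation_id: int = -1,
                       level: float = 0.95) -> MutationPosterior:
    """Gamma posterior for a mutation's age from its parent and child
    node posteriors (``child_post=None`` for a contemporary sample
    child at age 0)."""
    if child_post is None:
        cm1, cm2 = 0.0, 0.0
    else:
        cm1 = child_post.mean
        cm2 = child_post.variance + cm1**2
    pm1 = parent_post.mean
    pm2 = parent_post.variance + pm1**2
    if not pm1 > cm1:
        # degenerate edge: fall back to a point mass at the common mean
        g = GammaParams(shape=np.inf, rate=np.inf)
        return MutationPosterior(mutation_id, g, cm1, 0.0, cm1, cm1)
    m1, m2 = uniform_edge_moments(pm1, pm2, cm1, cm2)
    shape, rate = moments_to_canonical(m1, m2)
    g = GammaParams(shape=shape, rate=rate)
    lo, hi = g.interval(level)
    return MutationPosterior(mutation_id, g, m1, m2 - m1 * m1, lo, hi)


def age_zscore(ages, dac, min_bin: int = 2) -> np.ndarray:
    """Z-score log10 ages within discrete derived-allele-count bins.

    ``z_i = (log10 t_i - mean_g) / sd_g`` with the population (divisor
    ``n``) standard deviation of ``log10 t`` inside bin ``g``.  Bins
    with fewer than ``min_bin`` usable members, nonpositive ages, and
    zero-spread bins yield NaN.
    """
    ages = np.asarray(ages, dtype=float)
    dac = np.asarray(dac)
    z = np.full(len(ages), np.nan)
    ok = ages > 0
    if (~ok).any():
        import warnings

        warnings.warn(f"{int((~ok).sum())} nonpositive ages excluded from "
                      "z-scoring")
    logt = np.where(ok, np.log10(np.maximum(ages, 1e-300)), np.nan)
    df = pd.DataFrame({"logt": logt, "g": dac, "ok": ok})
    for g, sub in df[df["ok"]].groupby("g"):
        if len(sub) < min_bin:
            continue
        mu = sub["logt"].mean()
        sd = sub["logt"].std(ddof=0)
        if sd > 0:
            z[sub.index] = (sub["logt"] - mu) / sd
    return z
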