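"""Closed-form power for two-condition comparisons of overdispersed counts.

The model is the standard normal-approximation sample-size calculation for
count data (Hart et al.'s RNA-seq formulation, equally applicable to Hi-C
loop pixels): counts are negative-binomial with per-replicate mean ``mu``
and biological dispersion ``phi`` (squared coefficient of variation across
replicates, variance = mu + phi * mu**2).  On the log scale the squared
coefficient of variation of a single replicate is ``1/mu + phi`` (shot
noise plus biological), so a two-sided level-``alpha`` test of a fold
change ``delta`` with ``n`` replicates per condition has power

    power = Phi( sqrt( n * ln(delta)**2 / (2 * (1/mu + phi)) ) - z_{1-alpha/2} )

where Phi is the standard normal CDF.  The test is symmetric in
``delta <-> 1/delta``; at ``delta = 1`` power equals ``alpha/2``, one tail
of the false-positive rate.

All functions broadcast over numpy arrays.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from hicpower.fc_compression import observed_fc
from hicpower.loop_io import LoopRecord

__all__ = [
    "bonferroni_alpha",
    "power_two_group",
    "loop_power",
    "solve_min_counts",
]


def bonferroni_alpha(nominal: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance level after Bonferroni correction.

    For loop screens the number of tests is the number of loops evaluated
    at the given sequencing depth.
    """
    if not 0 < nominal < 1:
        raise ValueError("nominal alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return nominal / n_tests


def _validate_power_args(mu, dispersion, effect, alpha, n):
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    eff = np.asarray(effect, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mean counts must be positive")
    if np.any(phi < 0):
        raise ValueError("dispersion must be non-negative")
    if np.any(eff <= 0):
        raise ValueError("effect (fold change) must be positive")
    if np.any(n < 1):
        raise ValueError("replicates must be >= 1")
    if not np.all((0 < np.asarray(alpha)) & (np.asarray(alpha) < 1)):
        raise ValueError("alpha must be in (0, 1)")
    return mu, phi, eff, n


def power_two_group(mu, dispersion, effect, alpha, n):
    """Power of a two-sided two-group test for a fold change in counts.

    Parameters
    ----------
    mu:
        Per-replicate expected counts at the feature (the loop pixel).
    dispersion:
        Squared coefficient of variation phi across replicates;
        0 degenerates to the Poisson (shot-noise only) case.
    effect:
        Fold change on the observed-counts scale; direction is ignored
        (|ln effect| is used).
    alpha:
        Two-sided per-test significance level.
    n:
        Replicates per condition.
    """
    mu, phi, eff, n = _validate_power_args(mu, dispersion, effect, alpha, n)
    z_alpha = stats.norm.isf(np.asarray(alpha, dtype=float) / 2.0)
    arg = np.sqrt(n * np.log(eff) ** 2 / (2.0 * (1.0 / mu + phi))) - z_alpha
    out = np.clip(stats.norm.cdf(arg), 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


def loop_power(
    loop: LoopRecord,
    fc_looping: float,
    dispersion: float,
    alpha: float,
    n: int,
    depth_scale: float = 1.0,
):
    """Per-loop power to detect a fold change in looping counts.

    The looping fold change is first compressed to the observed-counts
    scale via :func:`hicpower.fc_compression.observed_fc`; the per-replicate
    mean is the loop's own observed counts rescaled by ``depth_scale``
    (target depth over the counts' reference depth).
    """
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    effect = observed_fc(loop.observed, loop.expected, fc_looping)
    return power_two_group(loop.observed * depth_scale, dispersion, effect, alpha, n)


def loops_power(
    observed,
    expected,
    fc_looping: float,
    dispersion: float,
    alpha: float,
    n: int,
    depth_scale: float = 1.0,
) -> np.ndarray:
    """Vectorized :func:`loop_power` over arrays of observed/expected counts."""
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    effect = observed_fc(np.asarray(observed, float), np.asarray(expected, float),
                         fc_looping)
    return np.asarray(
        power_two_group(np.asarray(observed, float) * depth_scale,
                        dispersion, effect, alpha, n)
    )


def solve_min_counts(
    dispersion: float,
    effect: float,
    alpha: float,
    n: int,
    target_power: float,
    rel_tol: float = 1e-6,
) -> float:
    """Smallest per-replicate mean count reaching a target power.

    Returns ``math.inf`` when even unbounded counts cannot reach the
    target, i.e. when the dispersion floor ``n * ln(effect)**2 / (2*phi)``
    is too small.  Solved by bisection to ``rel_tol`` relative precision.
    """
    if effect == 1:
        raise ValueError("effect = 1: no fold change, no finite solution")
    z_alpha = stats.norm.isf(alpha / 2.0)
    if not stats.norm.cdf(-z_alpha) < target_power < 1:
        raise ValueError("target_power must be in (alpha/2, 1)")
    # limit mu -> inf: power -> Phi(sqrt(n ln^2 / (2 phi)) - z_alpha)
    if dispersion > 0:
        limit = stats.norm.cdf(
            math.sqrt(n * math.log(effect) ** 2 / (2.0 * dispersion)) - z_alpha
        )
        if limit < target_power:
            return math.inf
    lo, hi = 1e-12, 1.0
    while power_two_group(hi, dispersion, effect, alpha, n) < target_power:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - guarded by the limit check above
            return math.inf
    f = lambda mu: power_two_group(mu, dispersion, effect, alpha, n) - target_power
    return optimize.brentq(f, lo, hi, rtol=rel_tol)
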