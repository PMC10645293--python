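"""Depth x replicates x dispersion sweeps over a loop set.

For each grid cell, every loop's counts are rescaled from the reference
depth of the loop list to the cell's sequencing depth per replicate
(linear in expectation, the mean of Bernoulli thinning), per-loop power to
detect the stated looping fold change is evaluated under a Bonferroni-
corrected alpha, and the percentage of loops exceeding the power
threshold ("well-powered", > 0.8 by default) is reported.  Total depth per
condition is replicates times depth per replicate — the planning axis for
"how much do I sequence".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from hicpower.fc_compression import observed_fc
from hicpower.loop_io import DEFAULT_BIN_SIZE, LoopRecord, bin_span, loop_span
from hicpower.power_model import bonferroni_alpha, power_two_group

__all__ = [
    "GridSpec",
    "scale_counts",
    "percent_well_powered",
    "sweep",
    "power_by_distance",
    "DEFAULT_DEPTHS",
]

#: depth-per-replicate ladder used for the standard sweeps (contacts)
DEFAULT_DEPTHS: tuple[int, ...] = (
    50_000_000,
    100_000_000,
    250_000_000,
    500_000_000,
    750_000_000,
    1_000_000_000,
    2_000_000_000,
    3_000_000_000,
    4_000_000_000,
    5_000_000_000,
)


def scale_counts(count_at_ref, reference_depth: float, target_depth: float):
    """Rescale counts from a reference to a target sequencing depth.

    ``count * target / reference`` — the expectation of Bernoulli thinning
    of the underlying contacts; not rounded.
    """
    if reference_depth <= 0 or target_depth <= 0:
        raise ValueError("depths must be positive")
    out = np.asarray(count_at_ref, dtype=float) * (target_depth / reference_depth)
    return out.item() if out.ndim == 0 else out


@dataclass
class GridSpec:
    """Grid of experiment designs to sweep.

    Defaults mirror the standard planning axes: depths per replicate from
    50 million to 5 billion contacts, 2-10 replicates, dispersions
    {0.001, 0.01, 0.04}, a 2-fold change in looping, and a 0.8 power
    threshold with a 0.05 Bonferroni-corrected family alpha.
    """

    depths_per_replicate: Sequence[int] = DEFAULT_DEPTHS
    replicates: Sequence[int] = tuple(range(2, 11))
    dispersions: Sequence[float] = (0.001, 0.01, 0.04)
    fc_looping: float = 2.0
    power_threshold: float = 0.8
    nominal_alpha: float = 0.05
    reference_depth: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.depths_per_replicate):
            raise ValueError("depths must be positive")
        if any(r < 2 for r in self.replicates):
            raise ValueError("replicates must be >= 2")
        if any(phi < 0 for phi in self.dispersions):
            raise ValueError("dispersions must be non-negative")
        if not 0 < self.power_threshold < 1:
            raise ValueError("power_threshold must be in (0, 1)")
        if self.fc_looping <= 0:
            raise ValueError("fc_looping must be positive")


def _loop_arrays(loops: Sequence[LoopRecord]) -> tuple[np.ndarray, np.ndarray, float]:
    if not loops:
        raise ValueError("empty loop set")
    obs = np.array([lp.observed for lp in loops], dtype=float)
    exp = np.array([lp.expected for lp in loops], dtype=float)
    ref = loops[0].reference_depth
    return obs, exp, float(ref)


def _per_loop_power(
    obs: np.ndarray,
    exp: np.ndarray,
    fc_looping: float,
    dispersion: float,
    alpha: float,
    n_replicates: int,
    depth_per_replicate: float,
    reference_depth: float,
) -> np.ndarray:
    effect = observed_fc(obs, exp, fc_looping)
    mu = scale_counts(obs, reference_depth, depth_per_replicate)
    return np.asarray(power_two_group(mu, dispersion, effect, alpha, n_replicates))


def percent_well_powered(
    loops: Sequence[LoopRecord],
    fc_looping: float,
    dispersion: float,
    alpha_nominal: float,
    n_replicates: int,
    depth_per_replicate: float,
    reference_depth: float | None = None,
    threshold: float = 0.8,
) -> float:
    """Percent of loops with power strictly above ``threshold``.

    The per-test alpha is ``alpha_nominal`` Bonferroni-corrected by the
    number of loops evaluated.
    """
    obs, exp, ref = _loop_arrays(loops)
    if reference_depth is not None:
        ref = float(reference_depth)
    if ref <= 0:
        raise ValueError("reference depth unknown: set it on the loops or pass it")
    alpha = bonferroni_alpha(alpha_nominal, len(loops))
    power = _per_loop_power(
        obs, exp, fc_looping, dispersion, alpha, n_replicates,
        depth_per_replicate, ref,
    )
    return 100.0 * float(np.count_nonzero(power > threshold)) / len(loops)


def sweep(grid: GridSpec, loops: Sequence[LoopRecord]) -> pd.DataFrame:
    """Evaluate :func:`percent_well_powered` over every grid cell.

    Returns one row per (depth_per_replicate, replicates, dispersion)
    combination with ``total_depth_per_condition`` and
    ``percent_well_powered``; deterministic, no silent skips.
    """
    obs, exp, ref = _loop_arrays(loops)
    if grid.reference_depth is not None:
        ref = float(grid.reference_depth)
    if ref <= 0:
        raise ValueError("reference depth unknown: set it on the loops or in the grid")
    alpha = bonferroni_alpha(grid.nominal_alpha, len(loops))
    rows = []
    for depth in grid.depths_per_replicate:
        for n_rep in grid.replicates:
            for phi in grid.dispersions:
                power = _per_loop_power(
                    obs, exp, grid.fc_looping, phi, alpha, n_rep, depth, ref
                )
                pct = 100.0 * float(
                    np.count_nonzero(power > grid.power_threshold)
                ) / len(loops)
                rows.append(
                    (depth, n_rep, phi, depth * n_rep, pct, len(loops))
                )
    return pd.DataFrame(
        rows,
        columns=[
            "depth_per_replicate",
            "replicates",
            "dispersion",
            "total_depth_per_condition",
            "percent_well_powered",
            "n_loops",
        ],
    )


def power_by_distance(
    loops: Sequence[LoopRecord],
    fc_looping: float,
    dispersion: float,
    alpha_nominal: float,
    n_replicates: int,
    depth_per_replicate: float,
    reference_depth: float | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Well-powered percent and counts per distance bin.

    Bins with no loops are omitted; rows are ordered by distance.  The
    Bonferroni correction uses the total loop count, as in the grid sweep.
    """
    obs, exp, ref = _loop_arrays(loops)
    if reference_depth is not None:
        ref = float(reference_depth)
    if ref <= 0:
        raise ValueError("reference depth unknown: set it on the loops or pass it")
    alpha = bonferroni_alpha(alpha_nominal, len(loops))
    power = _per_loop_power(
        obs, exp, fc_looping, dispersion, alpha, n_replicates,
        depth_per_replicate, ref,
    )
    bins = np.array([bin_span(loop_span(lp), bin_size) for lp in loops])
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        n_total = int(np.count_nonzero(mask))
        n_well = int(np.count_nonzero(power[mask] > threshold))
        rows.append((int(b), 100.0 * n_well / n_total, n_well, n_total))
    return pd.DataFrame(
        rows, columns=["bin_start", "percent_well_powered", "n_well", "n_total"]
    )
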