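"""Distance-decay summaries and power-law fits of Hi-C counts.

Contact frequency falls with genomic separation in a power-law-like way
(the polymer "distance decay").  This module summarizes per-loop counts as
quantile profiles over 10 kb distance bins and fits the decay
``count = a * distance**b`` used to de-noise count/expected profiles.

The fit is ordinary least squares in log-log space — deterministic and
closed-form, adequate for its smoothing role — with an optional nonlinear
least-squares refinement on the natural scale initialized from the
log-OLS solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from hicpower.loop_io import DEFAULT_BIN_SIZE, LoopRecord, bin_span, loop_span

__all__ = [
    "DistanceProfile",
    "DecayModel",
    "PowerLawDecay",
    "profile_by_distance",
    "fit_power_law",
    "predict_counts",
]

_QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


@dataclass(frozen=True)
class DecayModel:
    """Power-law decay ``count = coefficient * distance**exponent``."""

    coefficient: float
    exponent: float
    r2_log: float = float("nan")

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")

    def predict(self, distance):
        return predict_counts(self, distance)


@dataclass(frozen=True)
class DistanceProfile:
    """Per-bin count quantiles (q10/q25/median/q75/q90) vs binned distance."""

    table: pd.DataFrame  # columns: bin, q10, q25, median, q75, q90, n

    def __len__(self) -> int:
        return len(self.table)


def profile_by_distance(
    loops: Sequence[LoopRecord],
    bin_size: int = DEFAULT_BIN_SIZE,
    field: str = "observed",
) -> DistanceProfile:
    """Quantile profile of a count field over 10 kb (default) distance bins.

    Quantiles use linear interpolation between order statistics (numpy's
    default rule).  Bins with no loops are omitted; bins are sorted
    ascending.
    """
    if field not in ("observed", "expected"):
        raise ValueError("field must be 'observed' or 'expected'")
    if not loops:
        return DistanceProfile(
            pd.DataFrame(columns=["bin", "q10", "q25", "median", "q75", "q90", "n"])
        )
    bins = np.array([bin_span(loop_span(lp), bin_size) for lp in loops])
    vals = np.array([getattr(lp, field) for lp in loops], dtype=float)
    rows = []
    for b in np.unique(bins):
        v = vals[bins == b]
        q = np.quantile(v, _QUANTILES)
        rows.append((int(b), *q, len(v)))
    table = pd.DataFrame(
        rows, columns=["bin", "q10", "q25", "median", "q75", "q90", "n"]
    )
    return DistanceProfile(table)


class PowerLawDecay:
    """Power-law decay regressor, ``count = a * distance**b``.

    scikit-learn-style estimator: ``fit(distances, counts)`` stores the
    fitted ``coefficient_``, ``exponent_`` and log-space ``r2_log_``;
    ``predict(distances)`` evaluates the curve.  The primary fit is OLS on
    ``log(count) ~ log(distance)``; ``refine="nls"`` follows with
    natural-scale nonlinear least squares initialized at the OLS solution.
    """

    def __init__(self, refine: str = "none"):
        self.refine = refine

    def get_params(self, deep: bool = True) -> dict:
        return {"refine": self.refine}

    def set_params(self, **params) -> "PowerLawDecay":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "PowerLawDecay":
        d = np.asarray(X, dtype=float).ravel()
        c = np.asarray(y, dtype=float).ravel()
        if d.shape != c.shape:
            raise ValueError("distances and counts must have equal length")
        if d.size < 3:
            raise ValueError("need at least 3 points to fit a power law")
        if np.any(d <= 0) or np.any(c <= 0):
            raise ValueError("distances and counts must be positive")
        ld, lc = np.log(d), np.log(c)
        if np.allclose(ld, ld[0]):
            raise ValueError("degenerate fit: all distances equal")
        b, log_a = np.polyfit(ld, lc, 1)
        a = float(np.exp(log_a))
        b = float(b)
        if self.refine == "nls":
            (a, b), _ = optimize.curve_fit(
                lambda x, aa, bb: aa * x**bb, d, c, p0=(a, b), maxfev=10_000
            )
        resid = lc - (np.log(a) + b * ld)
        ss_tot = float(np.sum((lc - lc.mean()) ** 2))
        self.r2_log_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        self.coefficient_ = float(a)
        self.exponent_ = float(b)
        return self

    def predict(self, X):
        if not hasattr(self, "coefficient_"):
            raise ValueError("estimator is not fitted")
        return predict_counts(self.model_, X)

    @property
    def model_(self) -> DecayModel:
        return DecayModel(self.coefficient_, self.exponent_, self.r2_log_)


def fit_power_law(
    distances: Sequence[float], counts: Sequence[float], refine: str = "none"
) -> DecayModel:
    """Fit ``count = a * distance**b``; see :class:`PowerLawDecay`."""
    return PowerLawDecay(refine=refine).fit(distances, counts).model_


def predict_counts(model: DecayModel, distance):
    """Evaluate the decay curve at a positive genomic distance."""
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    out = model.coefficient * d**model.exponent
    return out.item() if out.ndim == 0 else out
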