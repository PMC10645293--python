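"""Fold-change compression between looping counts and observed counts.

Observed counts ``o`` at a loop pixel decompose into a polymer-background
component ``e`` (expected counts) and a looping component ``o - e``.  A
biological fold change ``FC_looping`` acts only on the looping component,
so on the observed-counts scale it appears as

    FC_observed = ((o - e) * FC_looping + e) / o

which is compressed toward 1: for FC_looping > 1 and 0 < e < o,
1 < FC_observed < FC_looping.  The compression is strongest where the
background dominates (small looping fraction), i.e. for shorter-range
loops.  All functions accept scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["observed_fc", "looping_counts", "looping_fraction", "invert_observed_fc"]


def _validate_oe(o, e) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(o <= 0):
        raise ValueError("observed counts must be positive")
    if np.any(e < 0):
        raise ValueError("expected counts must be non-negative")
    if np.any(e > o):
        raise ValueError(
            "expected counts exceed observed counts (input not filtered?)"
        )
    return o, e


def observed_fc(o, e, fc_looping):
    """Observed-counts fold change implied by a fold change in looping counts.

    Parameters
    ----------
    o, e:
        Observed and expected counts at the loop pixel, ``0 <= e <= o``.
    fc_looping:
        Fold change of the looping component (o - e).  Values below 1
        (loop loss) are permitted; the result is then bounded below by
        ``e / o``, the observed ratio when looping vanishes entirely.
    """
    o, e = _validate_oe(o, e)
    fc = np.asarray(fc_looping, dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fc_looping must be positive")
    out = ((o - e) * fc + e) / o
    return out.item() if out.ndim == 0 else out


def looping_counts(o, e):
    """Counts attributed to loop-forming forces: observed minus expected."""
    o, e = _validate_oe(o, e)
    out = o - e
    return out.item() if out.ndim == 0 else out


def looping_fraction(o, e):
    """Fraction of observed counts due to looping: (o - e) / o, in [0, 1]."""
    o, e = _validate_oe(o, e)
    out = (o - e) / o
    return out.item() if out.ndim == 0 else out


def invert_observed_fc(o, e, fc_observed):
    """Looping fold change implied by an observed-counts fold change.

    Algebraic inverse of :func:`observed_fc`:
    ``FC_looping = (FC_observed * o - e) / (o - e)``.  Undefined when
    ``o == e`` (no looping signal).
    """
    o, e = _validate_oe(o, e)
    if np.any(o == e):
        raise ValueError("no looping signal (o == e): inverse undefined")
    fc_obs = np.asarray(fc_observed, dtype=float)
    if np.any(fc_obs <= e / o):
        raise ValueError("fc_observed must exceed e/o (observed floor)")
    out = (fc_obs * o - e) / (o - e)
    return out.item() if out.ndim == 0 else out
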