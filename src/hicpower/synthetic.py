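"""Synthetic loop sets, replicate count matrices, and contact streams.

The generator emulates the statistical structure of a deeply sequenced
human Hi-C loop call set so every analysis step is testable without
downloads:

* loop spans are log-normal (median 300 kb, skewed short), truncated to
  [20 kb, 2 Mb] and binned to 10 kb;
* expected counts follow a power-law distance decay, calibrated so a
  350 kb loop pixel carries ~36 expected counts at the full reference
  depth of ~5.5 billion contacts;
* the fraction of observed counts due to looping rises from ~0.5 to ~0.8
  with log-span, so observed = expected / (1 - fraction) with 10% CV
  multiplicative log-normal noise;
* replicate counts are negative-binomial around the (depth-scaled)
  observed means with a chosen dispersion phi (Poisson at phi = 0).

It does not emulate TADs, compartments, anchor-level structure, or
loop-calling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from hicpower.dispersion import CountMatrix
from hicpower.distance_model import DecayModel
from hicpower.fc_compression import observed_fc
from hicpower.loop_io import DEFAULT_BIN_SIZE, GenomicAnchor, LoopRecord

__all__ = [
    "LoopSimSpec",
    "default_looping_fraction",
    "simulate_loop_set",
    "simulate_replicate_counts",
    "simulate_contact_file",
]

#: full-depth reference map size (total unique contacts)
DEFAULT_REFERENCE_DEPTH = 5_536_073_657

SPAN_MIN = 20_000
SPAN_MAX = 2_000_000

#: decay exponent ~ -1 with the coefficient set so expected(350 kb) ~ 36
DEFAULT_DECAY = DecayModel(coefficient=1.26e7, exponent=-1.0)


def default_looping_fraction(span) -> np.ndarray:
    """Fraction of observed counts due to looping, rising 0.5 -> 0.8 with log-span."""
    span = np.asarray(span, dtype=float)
    t = (np.log(span) - math.log(SPAN_MIN)) / (math.log(SPAN_MAX) - math.log(SPAN_MIN))
    return np.clip(0.5 + 0.3 * t, 0.05, 0.95)


@dataclass
class LoopSimSpec:
    """Parameters of one synthetic loop set.

    ``span_median``/``span_sigma`` are the log-normal span parameters
    (median 300 kb, log-sd 0.75 gives the short-skewed shape of real loop
    calls); ``noise_cv`` is the multiplicative log-normal CV of observed
    counts around their construction value — a fixture choice distinct
    from replicate-level dispersion.
    """

    n_loops: int = 10_000
    span_median: float = 300_000.0
    span_sigma: float = 0.75
    decay: DecayModel = field(default_factory=lambda: DEFAULT_DECAY)
    looping_fraction: Callable[[np.ndarray], np.ndarray] = default_looping_fraction
    reference_depth: int = DEFAULT_REFERENCE_DEPTH
    noise_cv: float = 0.10
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0


def _sample_spans(spec: LoopSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Log-normal spans truncated to [SPAN_MIN, SPAN_MAX] by resampling."""
    mu = math.log(spec.span_median)
    spans = np.empty(0)
    while spans.size < spec.n_loops:
        draw = rng.lognormal(mu, spec.span_sigma, size=2 * spec.n_loops)
        draw = draw[(draw >= SPAN_MIN) & (draw < SPAN_MAX)]
        spans = np.concatenate([spans, draw])
    return spans[: spec.n_loops]


def simulate_loop_set(spec: LoopSimSpec | None = None) -> list[LoopRecord]:
    """Generate a loop set with decay-calibrated counts.

    Every returned record passes the standard inclusion filters (span
    < 2 Mb, autosomal, observed > expected); the multiplicative noise is
    floored just above 1x expected to guarantee the last rule.
    Deterministic per ``spec.seed``.
    """
    spec = spec or LoopSimSpec()
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    spans = _sample_spans(spec, rng)
    spans = (spans // spec.bin_size) * spec.bin_size
    spans = spans.clip(min=spec.bin_size)  # binned span 0 would be self-interaction
    expected = spec.decay.predict(spans)
    frac = np.asarray(spec.looping_fraction(spans), dtype=float)
    if np.any((frac <= 0) | (frac >= 1)):
        raise ValueError("looping_fraction must map spans into (0, 1)")
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    noise = rng.lognormal(-0.5 * sigma**2, sigma, size=spans.size)
    observed = expected / (1.0 - frac) * noise
    # keep observed strictly above expected despite noise
    observed = np.maximum(observed, expected * 1.001)

    chroms = rng.integers(1, 23, size=spans.size)
    starts = (
        rng.integers(1, 20_000, size=spans.size) * spec.bin_size
    )  # anchor1 positions on a 10 kb lattice
    loops = []
    for i in range(spans.size):
        chrom = f"chr{chroms[i]}"
        s1 = int(starts[i])
        s2 = s1 + int(spans[i])
        loops.append(
            LoopRecord(
                GenomicAnchor(chrom, s1, s1 + spec.bin_size),
                GenomicAnchor(chrom, s2, s2 + spec.bin_size),
                observed=float(observed[i]),
                expected=float(expected[i]),
                reference_depth=spec.reference_depth,
                name=f"loop{i}",
            )
        )
    return loops


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, phi: float, size: tuple[int, ...]
) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), size=size)


def simulate_replicate_counts(
    loops: Sequence[LoopRecord],
    n_reps: int,
    dispersion: float,
    condition_fc: float = 1.0,
    depth_scale: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, CountMatrix]:
    """Negative-binomial replicate counts for two conditions.

    Condition A replicates have mean ``observed * depth_scale`` per loop;
    condition B applies ``condition_fc`` to the looping component (so its
    observed-scale mean is compressed via
    :func:`hicpower.fc_compression.observed_fc`).  Variance is
    mean + phi * mean**2; phi = 0 degenerates to Poisson.  Deterministic
    per seed.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    rng = np.random.Generator(np.random.PCG64(seed))
    obs = np.array([lp.observed for lp in loops], dtype=float)
    exp = np.array([lp.expected for lp in loops], dtype=float)
    mean_a = obs * depth_scale
    mean_b = mean_a * np.asarray(observed_fc(obs, exp, condition_fc))
    shape = (len(loops), n_reps)
    counts_a = _nb_draw(rng, mean_a[:, None], dispersion, shape)
    counts_b = _nb_draw(rng, mean_b[:, None], dispersion, shape)
    return CountMatrix(counts_a), CountMatrix(counts_b)


def simulate_contact_file(n_records: int, seed: int = 0) -> Iterator[str]:
    """Yield dummy whitespace-delimited contact lines (merged-contacts style).

    Fields mimic a read-pair record (strands, chromosomes, positions,
    fragments); content is immaterial to thinning, which treats lines as
    opaque.  Deterministic per seed.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = np.random.Generator(np.random.PCG64(seed))
    for i in range(n_records):
        s1, s2 = rng.integers(0, 2, size=2)
        c1, c2 = rng.integers(1, 23, size=2)
        p1, p2 = rng.integers(1, 200_000_000, size=2)
        yield f"{s1} {c1} {p1} {i} {s2} {c2} {p2} {i + 1}\n"
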