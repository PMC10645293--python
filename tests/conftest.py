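import numpy as np
import pytest

from hicpower.loop_io import GenomicAnchor, LoopRecord
from hicpower.synthetic import LoopSimSpec, simulate_loop_set

BIN = 10_000


def make_loop(chrom="chr1", start=1_000_000, span=350_000, observed=159.0,
              expected=36.0, reference_depth=5_536_073_657, name="."):
    return LoopRecord(
        GenomicAnchor(chrom, start, start + BIN),
        GenomicAnchor(chrom, start + span, start + span + BIN),
        observed=observed,
        expected=expected,
        reference_depth=reference_depth,
        name=name,
    )


@pytest.fixture
def worked_example_loop():
    """The 350 kb loop pixel with 159 observed / 36 expected counts."""
    return make_loop()


@pytest.fixture
def toy_filter_loops():
    """Five loops exercising each inclusion rule.

    Spans {100 kb, 500 kb, 2.5 Mb, 300 kb, 300 kb}; the 4th sits on chrX,
    the 5th has observed == expected.  Only loops 1 and 2 survive.
    """
    return [
        make_loop(span=100_000, name="l1"),
        make_loop(span=500_000, name="l2"),
        make_loop(span=2_500_000, name="l3"),
        make_loop(chrom="chrX", span=300_000, name="l4"),
        make_loop(span=300_000, observed=50, expected=50, name="l5"),
    ]


@pytest.fixture(scope="session")
def synthetic_loops():
    """Default calibrated loop set, shared across tests (read-only)."""
    return simulate_loop_set(LoopSimSpec(n_loops=10_000, seed=11))


@pytest.fixture(scope="session")
def small_loops():
    return simulate_loop_set(LoopSimSpec(n_loops=500, seed=5))


def nb_draw(rng: np.random.Generator, mean, phi, size):
    """Reference NB sampler (variance = mean + phi*mean^2), Poisson at phi=0."""
    if phi <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.asarray(mean, float)), size)
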