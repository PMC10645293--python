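import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hicpower.power_model import (
    bonferroni_alpha,
    loop_power,
    power_two_group,
    solve_min_counts,
)

from conftest import make_loop, nb_draw


def wald_rejection_rate(mu, phi, n, delta, alpha=0.05, sims=100_000, seed=0):
    """Monte-Carlo oracle: two-sided Wald test on log group-mean counts.

    NB replicate counts (variance mu + phi*mu^2) are drawn for a control
    group at mean ``mu`` and a treated group at ``mu*delta``; the statistic
    is the log ratio of group means over its delta-method standard error.
    Empirical size is ~0.048 at alpha 0.05, so rejection rates under the
    alternative estimate true power.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    y1 = nb_draw(rng, mu, phi, (sims, n)).mean(axis=1)
    y2 = nb_draw(rng, mu * delta, phi, (sims, n)).mean(axis=1)
    y1 = np.maximum(y1, 0.5 / n)
    y2 = np.maximum(y2, 0.5 / n)
    se = np.sqrt((1 / y1 + phi) / n + (1 / y2 + phi) / n)
    z = (np.log(y2) - np.log(y1)) / se
    return float(np.mean(np.abs(z) > stats.norm.isf(alpha / 2)))


class TestBonferroni:
    def test_divides_by_test_count(self):
        assert bonferroni_alpha(0.05, 14_849) == pytest.approx(0.05 / 14_849)
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 2) == 0.025

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 10)


class TestClosedForm:
    @pytest.mark.parametrize("alpha", [0.05, 0.01, 1e-5])
    @pytest.mark.parametrize("mu,phi,n", [(50, 0.001, 2), (7, 0.1, 9)])
    def test_null_effect_gives_half_alpha(self, mu, phi, n, alpha):
        assert power_two_group(mu, phi, 1.0, alpha, n) == pytest.approx(
            alpha / 2, rel=1e-9
        )

    def test_direction_symmetric(self):
        assert power_two_group(50, 0.01, 2.0, 0.05, 3) == pytest.approx(
            power_two_group(50, 0.01, 0.5, 0.05, 3)
        )

    def test_power_tends_to_one_with_replicates(self):
        ns = [2, 4, 8, 16, 64, 256]
        p = [power_two_group(50, 0.001, 2, 0.05, n) for n in ns]
        assert np.all(np.diff(p) > -1e-15)
        assert p[-1] > 0.999999

    def test_known_value_against_formula(self):
        # independent recomputation of the normal approximation
        mu, phi, delta, alpha, n = 50, 0.001, 2, 0.05, 2
        z = math.sqrt(n * math.log(delta) ** 2 / (2 * (1 / mu + phi)))
        expected = stats.norm.cdf(z - stats.norm.isf(alpha / 2))
        assert power_two_group(mu, phi, delta, alpha, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu=0, dispersion=0.01, effect=2, alpha=0.05, n=2),
            dict(mu=50, dispersion=-0.1, effect=2, alpha=0.05, n=2),
            dict(mu=50, dispersion=0.01, effect=0, alpha=0.05, n=2),
            dict(mu=50, dispersion=0.01, effect=2, alpha=1.2, n=2),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            power_two_group(**kwargs)

    def test_bounded_in_unit_interval(self):
        p = power_two_group(
            np.array([0.01, 1, 1e9]), 0.001, 2.0, 1e-8, 2
        )
        assert np.all((p >= 0) & (p <= 1))


class TestMonteCarloOracle:
    def test_fig2d_parameter_setting(self):
        """Dispersion/alpha/replicates/counts at 0.001 / 0.05 / 2 / 50."""
        closed = power_two_group(50, 0.001, 2, 0.05, 2)
        empirical = wald_rejection_rate(50, 0.001, 2, 2, sims=100_000, seed=42)
        assert abs(closed - empirical) < 0.03

    @pytest.mark.parametrize("mu,phi,n", [(50, 0.01, 2), (200, 0.04, 4), (20, 0.01, 8)])
    def test_grid_spot_checks(self, mu, phi, n):
        closed = power_two_group(mu, phi, 2, 0.05, n)
        empirical = wald_rejection_rate(mu, phi, n, 2, sims=50_000, seed=7)
        assert abs(closed - empirical) < 0.05


class TestMonotonicity:
    @settings(derandomize=True, max_examples=100)
    @given(
        mu=st.floats(1.0, 1e4),
        phi=st.floats(0.0, 0.2),
        delta=st.floats(1.05, 10.0),
        alpha=st.floats(1e-7, 0.2),
        n=st.integers(2, 12),
    )
    def test_increasing_in_mu_n_effect_decreasing_in_phi_alpha(
        self, mu, phi, delta, alpha, n
    ):
        base = power_two_group(mu, phi, delta, alpha, n)
        assert power_two_group(mu * 1.5, phi, delta, alpha, n) >= base
        assert power_two_group(mu, phi, delta, alpha, n + 1) >= base
        assert power_two_group(mu, phi, delta * 1.2, alpha, n) >= base
        assert power_two_group(mu, phi + 0.01, delta, alpha, n) <= base
        assert power_two_group(mu, phi, delta, alpha / 2, n) <= base

    @settings(derandomize=True, max_examples=100)
    @given(
        total_depth_counts=st.floats(10.0, 1e5),
        phi=st.floats(0.0, 0.2),
        delta=st.floats(1.05, 10.0),
    )
    def test_replicates_never_hurt_at_fixed_total_depth(
        self, total_depth_counts, phi, delta
    ):
        """Splitting a fixed per-condition depth over more replicates never
        loses power: the shot-noise term 1/mu grows with n but is divided
        back by n, while the biological term phi shrinks as phi/n."""
        ns = np.arange(2, 11)
        p = [
            power_two_group(total_depth_counts / n, phi, delta, 1e-4, n) for n in ns
        ]
        assert np.all(np.diff(p) >= -1e-12)


class TestLoopPower:
    def test_composes_compression_and_scaling(self, worked_example_loop):
        phi, alpha, n = 0.001, 1e-5, 3
        got = loop_power(worked_example_loop, 2.0, phi, alpha, n, depth_scale=0.5)
        want = power_two_group(159 * 0.5, phi, 282 / 159, alpha, n)
        assert got == pytest.approx(want)

    def test_null_looping_fc(self, worked_example_loop):
        assert loop_power(worked_example_loop, 1.0, 0.01, 0.05, 2) == pytest.approx(
            0.025
        )

    def test_no_background_effect_is_uncompressed(self):
        lp = make_loop(observed=100, expected=0)
        got = loop_power(lp, 3.0, 0.01, 0.05, 2)
        assert got == pytest.approx(power_two_group(100, 0.01, 3.0, 0.05, 2))


class TestSolveMinCounts:
    @pytest.mark.parametrize("target", [0.5, 0.8, 0.95])
    def test_round_trip(self, target):
        mu = solve_min_counts(0.01, 1.5, 0.05, 3, target)
        assert power_two_group(mu, 0.01, 1.5, 0.05, 3) == pytest.approx(
            target, abs=1e-4
        )

    def test_poisson_limit_closed_form(self):
        # phi=0: mu = 2 (z_a + z_p)^2 / (n ln^2 delta), by rearrangement
        alpha, n, delta, target = 0.05, 2, 2.0, 0.8
        z = stats.norm.isf(alpha / 2) + stats.norm.isf(1 - target)
        expected = 2 * z**2 / (n * math.log(delta) ** 2)
        assert solve_min_counts(0.0, delta, alpha, n, target) == pytest.approx(
            expected, rel=1e-4
        )

    def test_unreachable_target_signals_infinity(self):
        assert solve_min_counts(1.0, 1.2, 0.05, 2, 0.99) == math.inf

    def test_unit_effect_rejected(self):
        with pytest.raises(ValueError):
            solve_min_counts(0.01, 1.0, 0.05, 2, 0.8)
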