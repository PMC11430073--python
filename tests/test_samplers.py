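"""Sampler correctness on analytic targets, determinism and bookkeeping."""

import math

import numpy as np
import pytest

from cartmc.samplers import (
    ChainSet,
    DEFAULT_GAMMA,
    accept_probability,
    demetropolis_sample,
    demetropolisz_sample,
    mh_sample,
)


def std_normal_1d(x):
    return float(-0.5 * x[0] ** 2)


def make_gaussian_2d(rho=0.8):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    prec = np.linalg.inv(cov)

    def logp(x):
        return float(-0.5 * x @ prec @ x)

    return logp, cov


class TestAcceptProbability:
    @pytest.mark.parametrize(
        "new,old,expected",
        [(0.0, 0.0, 1.0), (-math.inf, -1.0, 0.0), (math.log(0.5) - 1.0, -1.0, 0.5), (5.0, -1.0, 1.0)],
    )
    def test_values(self, new, old, expected):
        assert accept_probability(new, old) == pytest.approx(expected)


class TestMetropolis:
    def test_recovers_standard_normal_moments(self):
        # 3 independent seeds, 3-SE bands on the mean, 5% on the variance
        for seed in (1, 2, 3):
            cs = mh_sample(std_normal_1d, np.array([0.0]), 50_000, proposal_scales=2.4, seed=seed)
            x = cs.pooled()[5000:, 0]
            ess_floor = x.size / 20  # generous autocorrelation allowance
            assert abs(x.mean()) < 3.0 / math.sqrt(ess_floor)
            assert x.var() == pytest.approx(1.0, rel=0.05)

    def test_zero_scale_degenerate_warns_and_stays(self):
        with pytest.warns(UserWarning, match="zero"):
            cs = mh_sample(std_normal_1d, np.array([0.7]), 50, proposal_scales=0.0, seed=0)
        assert np.all(cs.draws == 0.7)

    def test_seed_determinism_bit_identical(self):
        a = mh_sample(std_normal_1d, np.array([0.0]), 500, 1.0, seed=42, n_chains=2)
        b = mh_sample(std_normal_1d, np.array([0.0]), 500, 1.0, seed=42, n_chains=2)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.accept_flags, b.accept_flags)

    def test_init_outside_support_rejected(self):
        def logp(x):
            return -math.inf if x[0] < 0 else 0.0

        with pytest.raises(ValueError, match="non-finite"):
            mh_sample(logp, np.array([-1.0]), 10, 1.0, seed=0)

    def test_discrete_three_state_stationary(self):
        # MH on a 3-point target with masses 0.2/0.3/0.5: empirical visit
        # frequencies over 1e6 steps match within 1% (detailed balance).
        dens = {0: 0.2, 1: 0.3, 2: 0.5}

        def logp(x):
            k = int(round(x[0]))
            if k < 0 or k > 2 or abs(x[0] - k) > 1e-9:
                return -math.inf
            return math.log(dens[k])

        rng = np.random.default_rng(99)
        state, lp = 0, math.log(0.2)
        counts = np.zeros(3)
        for _ in range(1_000_000):
            prop = rng.integers(0, 3)  # symmetric independent proposal
            lp_prop = math.log(dens[int(prop)])
            if rng.random() < accept_probability(lp_prop, lp):
                state, lp = int(prop), lp_prop
            counts[state] += 1
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, [0.2, 0.3, 0.5], atol=0.01)


class TestDEMetropolis:
    def test_needs_four_chains(self):
        with pytest.raises(ValueError, match="n_chains"):
            demetropolis_sample(std_normal_1d, np.array([0.0]), 3, 10, seed=0)

    def test_recovers_correlated_gaussian_covariance(self):
        logp, cov = make_gaussian_2d(0.8)
        rng = np.random.default_rng(0)
        init = rng.normal(0, 1, size=(16, 2))
        cs = demetropolis_sample(logp, init, 16, 5000, seed=3, epsilon_scale=1e-4)
        x = cs.discard(0.2).pooled()
        est = np.cov(x, rowvar=False)
        assert np.linalg.norm(est - cov) / np.linalg.norm(cov) < 0.10
        assert np.all(np.abs(x.mean(axis=0)) < 0.05)

    def test_proposal_geometry_epsilon_zero(self):
        # with eps=0 and all chains on a line, proposals stay on that line
        logp = lambda x: 0.0
        init = np.array([[float(i), 2.0 * i] for i in range(6)])
        cs = demetropolis_sample(logp, init, 6, 200, seed=1, epsilon_scale=0.0)
        x = cs.pooled()
        np.testing.assert_allclose(x[:, 1], 2.0 * x[:, 0], atol=1e-9)

    def test_identical_starts_never_move_without_jitter(self):
        init = np.tile([1.5, -2.0], (8, 1))
        cs = demetropolis_sample(make_gaussian_2d()[0], init, 8, 100, seed=5, epsilon_scale=0.0)
        assert np.all(cs.draws == cs.draws[:, :1, :])

    def test_determinism(self):
        logp, _ = make_gaussian_2d()
        init = np.random.default_rng(1).normal(size=(4, 2))
        a = demetropolis_sample(logp, init, 4, 300, seed=7, epsilon_scale=1e-3)
        b = demetropolis_sample(logp, init, 4, 300, seed=7, epsilon_scale=1e-3)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestDEMetropolisZ:
    def test_single_chain_standard_normal(self):
        cs = demetropolisz_sample(std_normal_1d, np.array([0.0]), 51_000, seed=2, rw_fallback_scales=1.0)
        x = cs.draws[0, 1000:, 0]
        ess_floor = x.size / 20
        assert abs(x.mean()) < 3.0 / math.sqrt(ess_floor)
        assert x.var() == pytest.approx(1.0, rel=0.05)

    def test_recovers_correlated_gaussian(self):
        logp, cov = make_gaussian_2d(0.8)
        for seed in (1, 2, 3):
            cs = demetropolisz_sample(
                logp, np.array([0.0, 0.0]), 20_000, seed=seed, n_chains=2, rw_fallback_scales=1.0,
                epsilon_scale=1e-4,
            )
            x = cs.discard(0.25).pooled()
            est = np.cov(x, rowvar=False)
            assert np.linalg.norm(est - cov) / np.linalg.norm(cov) < 0.10

    def test_parallel_direction_construction(self):
        # frozen two-point history, eps=0, p_gamma_one=0: every proposal lies
        # on the line x + g*(z_a - z_b), i.e. second coordinate never changes
        # when the history difference has no second component
        logp = lambda x: 0.0
        cs = demetropolisz_sample(
            logp, np.array([[0.0, 0.0], [1.0, 0.0]])[0:1], 50, seed=4, epsilon_scale=0.0,
            p_gamma_one=0.0, rw_fallback_scales=np.array([1.0, 0.0]),
        )
        assert np.all(cs.draws[0, :, 1] == 0.0)

    def test_determinism(self):
        a = demetropolisz_sample(std_normal_1d, np.array([0.1]), 400, seed=9, rw_fallback_scales=0.5)
        b = demetropolisz_sample(std_normal_1d, np.array([0.1]), 400, seed=9, rw_fallback_scales=0.5)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_posts, b.log_posts)


class TestChainSet:
    def test_acceptance_bookkeeping_exact(self):
        cs = mh_sample(std_normal_1d, np.array([0.0]), 2000, 1.0, seed=11)
        assert cs.acceptance_rate == np.mean(cs.accept_flags)
        # accepted draws differ from predecessor; rejected ones are identical
        x = cs.draws[0, :, 0]
        moved = np.concatenate([[True], x[1:] != x[:-1]])
        assert np.all(moved[1:] <= cs.accept_flags[0, 1:])

    def test_discard_and_pooled_shapes(self):
        cs = mh_sample(std_normal_1d, np.array([0.0]), 1000, 1.0, seed=1, n_chains=3)
        kept = cs.discard(0.2)
        assert kept.n_draws == 800
        assert kept.pooled().shape == (2400, 1)

    def test_long_format_export(self, tmp_path):
        cs = mh_sample(std_normal_1d, np.array([0.0]), 10, 1.0, seed=1, n_chains=2, param_names=("x",))
        df = cs.to_dataframe()
        assert set(df.columns) == {"chain", "draw", "parameter", "value"}
        assert len(df) == 2 * 10 * 1
        p = cs.save_manifest(tmp_path / "m.json")
        assert p.exists()

    def test_default_gamma_formula(self):
        assert DEFAULT_GAMMA(14) == pytest.approx(2.38 / math.sqrt(28))
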