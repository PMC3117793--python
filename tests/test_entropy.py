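import numpy as np
import pytest
from scipy.stats import multivariate_normal

import pinnasonar as ps
from pinnasonar.entropy import StrengthPrior, _PosteriorEngine


@pytest.fixture(scope="module")
def templates16(head_config, partition16):
    em, hl, hr = ps.synthetic_head_fields(head_config, 60.0, partition16)
    return ps.build_templates(em, hl, hr)


def brute_force_posterior(b, ts, cov, prior):
    """Exhaustive enumeration over the joint (cell x strength) grid in
    linear space with scipy's multivariate normal — the independent oracle
    for the marginalized log-space pipeline."""
    grid = prior.grid
    w = np.ones(grid.size)
    if grid.size > 1:
        w[0] = w[-1] = 0.5
    w = w / w.sum()
    joint = np.zeros(ts.partition.n_cells)
    bv = np.asarray(b.values if hasattr(b, "values") else b, dtype=float)
    for c in range(ts.partition.n_cells):
        for wi, a in zip(w, grid):
            mu = np.maximum(ts.templates[c] + a, 0.0)
            joint[c] += wi * multivariate_normal.pdf(bv, mu, cov.matrix)
    return joint / joint.sum()


class TestStrengthPrior:
    def test_grid_and_weights(self):
        p = StrengthPrior(0.0, 50.0, 1.0)
        assert p.grid.size == 51
        assert np.exp(p.log_weights).sum() == pytest.approx(1.0)
        assert np.exp(p.log_weights[0]) == pytest.approx(0.5 / 50.0)

    def test_point_prior(self):
        p = StrengthPrior(30.0, 30.0, 1.0)
        assert p.grid.tolist() == [30.0]

    def test_invalid(self):
        with pytest.raises(ValueError):
            StrengthPrior(10.0, 0.0)
        with pytest.raises(ValueError):
            StrengthPrior(0.0, 10.0, -1.0)


class TestSimulateMeasurement:
    def test_floor_dominates_for_deeply_subthreshold(self, templates16, cov_default, rng):
        m = ps.simulate_measurement(templates16.templates[0], -1000.0, cov_default, rng)
        assert np.all(m.values == 0.0)

    def test_noiseless_limit(self, templates16, rng):
        cov0 = ps.build_covariance(1e-9, 0.0, 0.0, 7)
        t = templates16.templates[3]
        m = ps.simulate_measurement(t, 30.0, cov0, rng)
        assert np.allclose(m.values, np.maximum(t + 30.0, 0.0), atol=1e-6)

    def test_unbiased_at_high_strength(self, templates16, cov_default, rng):
        t = templates16.templates[3]
        draws = np.array([
            ps.simulate_measurement(t, 60.0, cov_default, rng).values
            for _ in range(2000)
        ])
        assert np.max(np.abs(draws.mean(axis=0) - (t + 60.0))) < 0.5


class TestLikelihood:
    def test_mode_at_floored_mean(self, templates16, cov_default):
        t = templates16.templates[4]
        mu = np.maximum(t + 20.0, 0.0)
        at_mode = ps.likelihood(mu, t, 20.0, cov_default)
        off = ps.likelihood(mu + 1.0, t, 20.0, cov_default)
        assert at_mode > off

    def test_identical_templates_identical_likelihood(self, cov_default, rng):
        t = np.zeros(14)
        b = np.maximum(rng.normal(10, 5, 14), 0)
        assert ps.likelihood(b, t, 10.0, cov_default) == pytest.approx(
            ps.likelihood(b, t.copy(), 10.0, cov_default)
        )

    def test_gaussian_normalizer_diagonal(self):
        # 14 iid elements with sigma=5: density at the mean is (2 pi 25)^-7
        cov = ps.build_covariance(5.0, 0.0, 0.0, 7)
        t = np.zeros(14)
        val = ps.likelihood(np.full(14, 30.0), t, 30.0, cov)
        assert val == pytest.approx((2 * np.pi * 25.0) ** -7, rel=1e-9)


class TestMarginalLikelihood:
    def test_point_prior_equals_fixed_strength(self, templates16, cov_default, rng):
        t = templates16.templates[2]
        b = ps.simulate_measurement(t, 30.0, cov_default, rng)
        point = StrengthPrior(30.0, 30.0)
        assert ps.marginal_likelihood(b, t, cov_default, point) == pytest.approx(
            ps.likelihood(b, t, 30.0, cov_default)
        )

    def test_average_below_max(self, templates16, cov_default, rng):
        t = templates16.templates[2]
        b = ps.simulate_measurement(t, 25.0, cov_default, rng)
        prior = StrengthPrior(0.0, 50.0, 1.0)
        marg = ps.marginal_likelihood(b, t, cov_default, prior)
        best = max(ps.likelihood(b, t, a, cov_default) for a in prior.grid)
        assert marg <= best + 1e-30

    def test_grid_refinement_converges(self, templates16, cov_default, rng):
        t = templates16.templates[2]
        b = ps.simulate_measurement(t, 25.0, cov_default, rng)
        coarse = ps.marginal_likelihood(b, t, cov_default, StrengthPrior(0, 50, 1.0))
        fine = ps.marginal_likelihood(b, t, cov_default, StrengthPrior(0, 50, 0.5))
        assert fine == pytest.approx(coarse, rel=0.01)


class TestPosterior:
    def test_normalization(self, templates16, cov_default, rng):
        b = ps.simulate_measurement(templates16.templates[7], 20.0, cov_default, rng)
        p = ps.posterior(b, templates16, cov_default, StrengthPrior())
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_identical_templates_uniform(self, partition16, cov_default, rng):
        ts = ps.TemplateSet(
            frequency_khz=60.0,
            partition=partition16,
            templates=np.zeros((16, 14)),
            position_gain_db=np.zeros(16),
            max_raw_gain_db=0.0,
            protocol=ps.EarSweepProtocol(),
        )
        b = ps.simulate_measurement(ts.templates[0], 20.0, cov_default, rng)
        p = ps.posterior(b, ts, cov_default, StrengthPrior())
        assert np.allclose(p, 1.0 / 16)

    def test_matches_bruteforce_enumeration(self, templates16, cov_default, rng):
        prior = StrengthPrior(0.0, 40.0, 10.0)  # 5-point strength grid
        for _ in range(10):
            cell = int(rng.integers(16))
            a = float(rng.uniform(5, 45))
            b = ps.simulate_measurement(templates16.templates[cell], a, cov_default, rng)
            p = ps.posterior(b, templates16, cov_default, prior)
            oracle = brute_force_posterior(b, templates16, cov_default, prior)
            # relative agreement wherever the linear-space oracle itself has
            # not underflowed; negligible cells agree absolutely
            meaningful = oracle > 1e-12
            assert np.max(
                np.abs(p - oracle)[meaningful] / oracle[meaningful]
            ) < 1e-10
            if np.any(~meaningful):
                assert np.max(np.abs(p - oracle)[~meaningful]) < 1e-12


class TestEntropy:
    def test_uniform_256_is_8_bits(self):
        assert ps.entropy(np.full(256, 1 / 256)) == pytest.approx(8.0)

    def test_point_mass_and_coin(self):
        p = np.zeros(16)
        p[3] = 1.0
        assert ps.entropy(p) == pytest.approx(0.0)
        assert ps.entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_invalid_probabilities(self):
        with pytest.raises(ValueError):
            ps.entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            ps.entropy([0.2, 0.2])


class TestExpectedEntropyAndMap:
    def test_subfloor_strength_is_chance_level(self, head_config, cov_default):
        # when every candidate strength leaves every template fully below
        # the detection floor, all positions are indistinguishable and the
        # entropy is exactly the chance level log2(N)
        part = ps.partition_hemisphere(256)
        em, hl, hr = ps.synthetic_head_fields(head_config, 60.0, part)
        ts = ps.build_templates(em, hl, hr)
        subfloor = StrengthPrior(-500.0, -450.0, 10.0)
        h = ps.expected_entropy(0, ts, cov_default, -500.0,
                                n_realizations=5, rng=1, prior=subfloor)
        assert h == pytest.approx(np.log2(256), abs=1e-9)

    def test_near_noiseless_strong_echo_localizes(self, templates16):
        cov0 = ps.build_covariance(0.01, 0.0, 0.0, 7)
        h = ps.expected_entropy(3, templates16, cov0, 50.0, n_realizations=5, rng=1)
        assert h < 0.5

    def test_stability_in_realization_count(self, templates16, cov_default):
        h20 = ps.expected_entropy(5, templates16, cov_default, 30.0,
                                  n_realizations=20, rng=3)
        h200 = ps.expected_entropy(5, templates16, cov_default, 30.0,
                                   n_realizations=200, rng=4)
        assert abs(h20 - h200) < 0.3

    def test_map_bounds_and_shape(self, templates16, cov_default):
        emap = ps.entropy_map({60.0: templates16}, cov_default,
                              np.array([0.0, 25.0, 50.0]), n_realizations=4, rng=5)
        assert emap.data.shape == (16, 1, 3)
        assert float(emap.data.min()) >= 0.0
        assert float(emap.data.max()) <= np.log2(16) + 1e-9

    def test_antiphase_permutation_leaves_entropy_unchanged(
        self, head_config, partition16, cov_default
    ):
        em, hl, hr = ps.synthetic_head_fields(head_config, 60.0, partition16)
        anti = ps.build_templates(em, hl, hr, ps.EarSweepProtocol(antiphase=True))
        sync = ps.build_templates(em, hl, hr, ps.EarSweepProtocol(antiphase=False))
        # permute the measurement and the covariance consistently: the
        # posterior, hence the entropy, is invariant
        perm = np.concatenate([np.arange(7), 7 + np.arange(7)[::-1]])
        cov_perm = ps.FlutterCovariance(
            cov_default.sigma_db,
            cov_default.within_ear_lag_corr,
            cov_default.interaural_corr,
            7,
            cov_default.matrix[np.ix_(perm, perm)],
        )
        rng = np.random.default_rng(9)
        b = ps.simulate_measurement(anti.templates[4], 25.0, cov_default, rng)
        p1 = ps.posterior(b, anti, cov_default, StrengthPrior())
        b_perm = b.values[perm]
        p2 = ps.posterior(b_perm, sync, cov_perm, StrengthPrior())
        assert ps.entropy(p1) == pytest.approx(ps.entropy(p2), abs=1e-9)

    def test_sweep_direction_robustness(self, head_config, partition64, cov_default):
        # diagonal, azimuth-only and elevation-only sweeps give similar
        # globally averaged entropies on the synthetic head
        results = []
        for proto in (
            ps.EarSweepProtocol.diagonal(),
            ps.EarSweepProtocol.azimuth_only(),
            ps.EarSweepProtocol.elevation_only(),
        ):
            em, hl, hr = ps.synthetic_head_fields(head_config, 60.0, partition64)
            ts = ps.build_templates(em, hl, hr, proto)
            emap = ps.entropy_map({60.0: ts}, cov_default,
                                  np.array([15.0, 30.0, 45.0]),
                                  n_realizations=10, rng=11)
            results.append(float(emap.global_mean().mean()))
        # the diagonal sweep covers a larger arc (21 deg) than the
        # single-axis sweeps (15 deg), so on the beam-like synthetic head
        # the agreement tolerance is 1 bit (documented in the methods note)
        assert max(results) - min(results) < 1.0

    def test_float32_map_agrees_with_float64_posteriors(
        self, templates16, cov_default, rng
    ):
        prior = StrengthPrior()
        fast = _PosteriorEngine(templates16, cov_default, prior, dtype=np.float32)
        exact = _PosteriorEngine(templates16, cov_default, prior)
        b = np.stack([
            ps.simulate_measurement(templates16.templates[i % 16], 25.0,
                                    cov_default, rng).values
            for i in range(8)
        ])
        assert np.max(np.abs(fast.posteriors(b) - exact.posteriors(b))) < 1e-4


class TestAngularResolution:
    def test_extremes_and_coin_case(self, partition256):
        n = 256
        assert ps.angular_resolution(8.0, partition256) == pytest.approx(2 * np.pi)
        assert ps.angular_resolution(0.0, partition256) == pytest.approx(2 * np.pi / n)
        assert ps.angular_resolution(1.0, partition256) == pytest.approx(4 * np.pi / n)

    def test_out_of_range_rejected(self, partition256):
        with pytest.raises(ValueError):
            ps.angular_resolution(9.0, partition256)
        with pytest.raises(ValueError):
            ps.angular_resolution(-0.1, partition256)
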