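"""Tests for trajectory and posterior analyses."""

import numpy as np
import pytest

import dsbrepair as d
from dsbrepair.analysis import activity_from_trajectories
from dsbrepair.hierarchy import HyperPrior
from dsbrepair.model import CHANNELS, RateParams, Trajectory

from conftest import make_observed


def single_channel_traj(x0=2000, k_per_break=1.0, kp=0.5, grid=None, seed=0):
    C = x0
    params = RateParams.from_channels({"fast": (k_per_break / C, kp, "full")})
    grid = grid if grid is not None else np.linspace(0, 24, 400)
    return d.simulate(params, x0, [C, 0, 0], grid, seed=seed)


class TestTally:
    def test_single_channel_conservation(self):
        traj = single_channel_traj(x0=500, grid=np.linspace(0, 60, 100))
        tally = d.tally_mechanisms(traj)
        assert tally.n_entered[0] + tally.x_final == 500
        assert tally.completed[0] <= tally.n_entered[0]
        assert 0 <= tally.proportions[0] <= 1

    def test_symmetric_channels_split_evenly(self):
        x0, C = 2000, 2000
        params = RateParams(np.array([0.5 / C, 0.5 / C, 0]), np.array([1.0, 1.0, 0]),
                            ("full", "full", "absent"))
        ratios = []
        for s in range(30):
            traj = d.simulate(params, x0, [C, C, 0], np.linspace(0, 40, 50), seed=s)
            n = d.tally_mechanisms(traj).n_entered
            ratios.append(n[0] / n[1])
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert np.mean(ratios) == pytest.approx(1.0, abs=3 * se)

    def test_event_count_matches_quadrature_on_dense_grid(self):
        traj = single_channel_traj(x0=10000, grid=np.linspace(0, 30, 1200))
        tally = d.tally_mechanisms(traj)
        assert tally.quadrature[0] == pytest.approx(tally.n_entered[0], rel=0.05)


class TestOccupancy:
    def test_single_channel_share_is_one_while_bound(self):
        traj = single_channel_traj(x0=500, kp=0.2)
        shares = d.occupancy_series(traj)
        bound = traj.y.sum(axis=1) > 0
        assert np.all(shares[bound, 0] == 1.0)
        assert np.all(shares[~bound] == 0.0)

    def test_shares_sum_to_one_where_bound(self, d1_spec, d1_rates):
        traj = d.simulate_dataset(d1_spec, d1_rates, seed=2,
                                  t_grid=np.linspace(0, 24, 200))
        shares = d.occupancy_series(traj)
        bound = traj.y.sum(axis=1) > 0
        assert shares[bound].sum(axis=1) == pytest.approx(np.ones(bound.sum()))

    def test_fast_share_declines_over_time(self, d1_spec, d1_rates):
        # wild type at reference medians: fast dominates early, slow late
        early, late = [], []
        grid = np.array([0.0, 0.5, 8.0])
        for s in range(20):
            traj = d.simulate_dataset(d1_spec, d1_rates, seed=100 + s, t_grid=grid)
            shares = d.occupancy_series(traj)
            early.append(shares[1, CHANNELS.index("fast")])
            late.append(shares[2, CHANNELS.index("fast")])
        assert np.mean(early) > np.mean(late)


class TestHalfMax:
    def test_exponential_half_life(self):
        # near-instant recruitment, ligation at ln2 per hour: half of the
        # eventually-ligated breaks are done by ~1 h
        traj = single_channel_traj(x0=4000, k_per_break=200.0, kp=np.log(2),
                                   grid=np.linspace(0, 20, 2000))
        assert d.time_to_half_max(traj, "fast") == pytest.approx(1.0, abs=0.15)

    def test_rejects_non_full_channel(self, d5_spec, d5_rates):
        traj = d.simulate_dataset(d5_spec, d5_rates, seed=0)
        with pytest.raises(ValueError, match="full"):
            d.time_to_half_max(traj, "fast")

    def test_halving_rates_doubles_half_time(self):
        grid = np.linspace(0, 96, 800)
        t_fast = np.median([d.time_to_half_max(
            single_channel_traj(4000, 0.4, 0.4, grid, seed=s), "fast")
            for s in range(10)])
        t_slow = np.median([d.time_to_half_max(
            single_channel_traj(4000, 0.2, 0.2, grid, seed=s), "fast")
            for s in range(10)])
        assert t_slow / t_fast == pytest.approx(2.0, rel=0.2)


@pytest.fixture(scope="module")
def small_ensemble():
    """A quick real fit on one wild-type-like dataset."""
    spec = d.default_dataset_specs()["D1"]
    from dsbrepair import reference
    obs = make_observed(spec, reference.median_rate_params("D1"), seed=40, noise_sd=1.0)
    return d.fit([obs], schedule=d.SMCSchedule(n_particles=60, n_generations=4),
                 seed=41), obs


class TestPredictive:
    def test_quantile_envelopes_nested(self, small_ensemble):
        ens, spec = small_ensemble
        bands = d.predictive_bands(ens, spec, n_draws=40, seed=0)
        assert np.all(bands["q025"] <= bands["q25"])
        assert np.all(bands["q25"] <= bands["q50"])
        assert np.all(bands["q50"] <= bands["q75"])
        assert np.all(bands["q75"] <= bands["q975"])

    def test_rejects_too_few_draws(self, small_ensemble):
        ens, spec = small_ensemble
        with pytest.raises(ValueError):
            d.predictive_bands(ens, spec, n_draws=5)

    def test_bands_widen_with_population_variance(self, small_ensemble):
        ens, spec = small_ensemble
        narrow = d.predictive_bands(ens, spec, n_draws=60, seed=1)
        wide_ens = d.PosteriorEnsemble(
            thetas=ens.thetas, weights=ens.weights, distances=ens.distances,
            per_dataset=ens.per_dataset, rate_K=ens.rate_K,
            rate_Kprime=ens.rate_Kprime, datasets=ens.datasets,
            prior=HyperPrior(sigma2=1.0),  # doubled log-sd
        )
        wide = d.predictive_bands(wide_ens, spec, n_draws=60, seed=1)
        width = lambda b: np.mean(b["q975"] - b["q025"])
        assert width(wide) > width(narrow)

    def test_knockout_of_everything_is_flat(self, small_ensemble):
        ens, spec = small_ensemble
        bands = d.channel_knockout_resim(ens, spec, CHANNELS, n_draws=20, seed=2)
        assert np.allclose(bands["q50"], 19.9914)

    def test_knockout_of_nothing_matches_plain_bands(self, small_ensemble):
        ens, spec = small_ensemble
        a = d.predictive_bands(ens, spec, n_draws=20, seed=3)
        b = d.channel_knockout_resim(ens, spec, [], n_draws=20, seed=3)
        assert np.allclose(a["q50"], b["q50"])

    def test_wildtype_knockout_of_fast_and_slow_still_repairs(self, small_ensemble):
        # A-EJ alone can clear the breaks eventually (capacity not saturated)
        ens, spec = small_ensemble
        grid = np.linspace(0, 48, 30)
        bands = d.channel_knockout_resim(ens, spec, ["fast", "slow"],
                                         grid=grid, n_draws=20, seed=4)
        assert bands["q50"].iloc[-1] < 0.5 * spec.dose_gy


class TestActivity:
    def test_single_channel_always_active_until_empty(self):
        traj = single_channel_traj(x0=500, kp=0.2, grid=np.linspace(0, 30, 60))
        active = activity_from_trajectories([traj], threshold=0.3)[0]
        bound = traj.y.sum(axis=1) > 0
        assert np.all(active[0, bound])
        assert not np.any(active[:, ~bound])

    def test_threshold_one_never_active_with_competition(self, d1_spec, d1_rates):
        traj = d.simulate_dataset(d1_spec, d1_rates, seed=5,
                                  t_grid=np.linspace(0, 8, 50))
        shares = d.occupancy_series(traj)
        multi = (shares > 0).sum(axis=1) >= 2
        active = activity_from_trajectories([traj], threshold=1.0)[0]
        assert not np.any(active[:, multi])

    def test_faster_channels_are_active_for_less_time(self, small_ensemble):
        from scipy import stats
        ens, spec = small_ensemble
        tl = d.activity_timeline(ens, spec, grid=np.linspace(0, 24, 60),
                                 n_draws=100, seed=6)
        # pooled across channels: higher recruitment rate, shorter activity
        rates = tl["rates"].ravel()
        durs = tl["durations"].ravel()
        keep = rates > 0
        rho = stats.spearmanr(np.log(rates[keep]), durs[keep]).statistic
        assert rho < -0.2


class TestKS:
    def test_identical_samples_zero(self):
        x = np.linspace(0, 1, 50)
        D, p = d.ks_two_sample(x, x.copy())
        assert D == 0.0

    def test_disjoint_supports_one(self):
        D, _ = d.ks_two_sample(np.arange(10), np.arange(100, 110))
        assert D == 1.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            d.ks_two_sample(np.arange(5), np.arange(20))

    def test_resample_unweighted_respects_weights(self):
        vals = np.array([0.0, 1.0])
        w = np.array([0.25, 0.75])
        out = d.resample_unweighted(vals, w, 4000, seed=0)
        assert np.mean(out) == pytest.approx(0.75, abs=0.03)
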