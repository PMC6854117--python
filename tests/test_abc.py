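import numpy as np
import pandas as pd
import pytest

from invadepop.abc import (ABCPosterior, Prior, ReferenceTable, abc_rejection,
                           build_reference_table, hpd_interval, pls_reduce,
                           regression_adjust, simulate_observed_summary)
from invadepop.coalescent import DemographicModel, Fusion


class TwoPopPreset:
    name = "twopop"

    def __init__(self, n_regions=60):
        self.n_regions = n_regions

    def build(self, overrides=None):
        p = {"T": 1000.0, **(overrides or {})}
        t = float(p["T"])
        return DemographicModel(
            pop_names=["CH", "SH", "A"],
            sizes={"CH": 15000.0, "SH": 20000.0, "A": 20000.0},
            events=[Fusion(t, "CH", "SH"), Fusion(t + 1, "SH", "A")],
            mu=2.5e-8, region_length=214, n_regions=self.n_regions)


SAMPLES = {"CH": 12, "SH": 12}


@pytest.fixture(scope="module")
def small_table():
    preset = TwoPopPreset()
    priors = {"T": Prior(100.0, 20000.0, log=True)}
    return preset, priors, build_reference_table(
        preset, priors, n_sims=120, samples=SAMPLES, seed=51)


class TestReferenceTable:
    def test_fixed_seed_bitwise_identical(self):
        preset = TwoPopPreset(n_regions=20)
        priors = {"T": Prior(200.0, 5000.0)}
        t1 = build_reference_table(preset, priors, n_sims=15, samples=SAMPLES, seed=7)
        t2 = build_reference_table(preset, priors, n_sims=15, samples=SAMPLES, seed=7)
        assert t1.params.equals(t2.params)
        assert np.array_equal(t1.summaries, t2.summaries)

    def test_point_mass_prior(self):
        preset = TwoPopPreset(n_regions=20)
        priors = {"T": Prior(999.9999, 1000.0001, log=False)}
        table = build_reference_table(preset, priors, n_sims=8, samples=SAMPLES, seed=3)
        assert table.params["T"].std() < 1e-3
        assert table.summaries.std(axis=0).sum() > 0  # Monte-Carlo noise remains

    def test_divergence_time_separates_summaries(self):
        # private-allele mass grows with T (3-point monotone check)
        preset = TwoPopPreset(n_regions=120)
        masses = []
        for t, seed in ((300.0, 1), (8000.0, 2), (80000.0, 3)):
            s = simulate_observed_summary(preset.build({"T": t}), SAMPLES, seed=seed)
            arr = s.reshape(13, 13)
            shared = arr[1:, 1:].sum()
            masses.append(arr.sum() - shared)  # mass on an axis: private alleles
        assert masses[0] < masses[1] < masses[2]

    def test_row_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReferenceTable(params=pd.DataFrame({"T": [1.0, 2.0]}),
                           summaries=np.zeros((3, 4)), seed=1, model_id="x")


class TestPlsReduce:
    def test_components_centred(self, small_table):
        _, _, table = small_table
        reduced, _, _ = pls_reduce(table, table.summaries[0], n_components=3)
        assert np.allclose(reduced.mean(axis=0), 0.0, atol=1e-8)

    def test_linear_signal_recovered(self):
        rng = np.random.default_rng(11)
        theta = rng.uniform(0, 10, size=400)
        summaries = np.column_stack([
            3.0 * theta + rng.normal(0, 0.5, 400),
            -1.0 * theta + rng.normal(0, 0.5, 400),
            rng.normal(0, 1, 400),
        ])
        table = ReferenceTable(params=pd.DataFrame({"theta": theta}),
                               summaries=summaries, seed=1, model_id="lin")
        reduced, _, _ = pls_reduce(table, summaries[0], n_components=2)
        corr = np.corrcoef(reduced[:, 0], theta)[0, 1]
        assert abs(corr) > 0.9

    def test_single_component_matches_hand_pls_direction(self):
        # 5-row toy with 2 informative summaries; first PLS weight vector is
        # w = X' y / ||X' y|| on standardised data
        X = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 1.5], [4.0, 3.0], [5.0, 4.0]])
        y = np.array([2.0, 3.9, 6.1, 8.0, 10.2])
        table = ReferenceTable(params=pd.DataFrame({"p": y}), summaries=X,
                               seed=1, model_id="toy")
        obs = X[2]
        reduced, reduced_obs, _ = pls_reduce(table, obs, n_components=1)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        yc = y - y.mean()
        w = Xs.T @ yc
        w = w / np.linalg.norm(w)
        hand = Xs @ w
        assert np.allclose(reduced[:, 0], hand, atol=1e-8)
        assert reduced_obs[0] == pytest.approx(hand[2], abs=1e-8)

    def test_component_bound_validated(self, small_table):
        _, _, table = small_table
        with pytest.raises(ValueError):
            pls_reduce(table, table.summaries[0], n_components=0)


class TestRejection:
    def test_observed_equal_to_row_has_zero_distance(self, small_table):
        _, _, table = small_table
        reduced, _, _ = pls_reduce(table, table.summaries[4], n_components=3)
        post = abc_rejection(reduced, reduced[4], table.params, n_accept=10)
        assert post.distances[0] == pytest.approx(0.0, abs=1e-10)
        assert post.draws.iloc[0]["T"] == table.params.iloc[4]["T"]

    def test_accept_all_returns_prior(self, small_table):
        _, _, table = small_table
        reduced, robs, _ = pls_reduce(table, table.summaries[0], n_components=3)
        post = abc_rejection(reduced, robs, table.params, n_accept=len(table.params))
        assert sorted(post.draws["T"]) == sorted(table.params["T"])

    def test_accept_count_validated(self, small_table):
        _, _, table = small_table
        reduced, robs, _ = pls_reduce(table, table.summaries[0], n_components=3)
        with pytest.raises(ValueError):
            abc_rejection(reduced, robs, table.params, n_accept=10**6)


def _linear_setup(rng, n=600):
    theta = rng.uniform(0, 10, size=n)
    S = np.column_stack([theta + rng.normal(0, 1.0, n),
                         0.5 * theta + rng.normal(0, 1.0, n)])
    return theta, S


class TestRegressionAdjust:
    def test_no_signal_leaves_posterior_mean(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 10, size=500)
        S = rng.normal(0, 1, size=(500, 2))  # independent of theta
        params = pd.DataFrame({"theta": theta})
        post = abc_rejection(S, np.zeros(2), params, n_accept=200)
        adj = regression_adjust(post, S, np.zeros(2))
        assert adj.draws["theta"].mean() == pytest.approx(
            post.draws["theta"].mean(), abs=0.6)

    def test_linear_map_shrinks_variance(self):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            theta, S = _linear_setup(rng)
            obs = S.mean(axis=0)
            params = pd.DataFrame({"theta": theta})
            post = abc_rejection(S, obs, params, n_accept=150)
            adj = regression_adjust(post, S, obs)
            if adj.draws["theta"].var() < post.draws["theta"].var():
                wins += 1
        assert wins >= 18

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        theta, S = _linear_setup(rng, n=200)
        params = pd.DataFrame({"theta": theta})
        post = abc_rejection(S, S[0], params, n_accept=80)
        a = regression_adjust(post, S, S[0], method="loclinear", seed=2)
        b = regression_adjust(post, S, S[0], method="loclinear", seed=2)
        assert a.draws.equals(b.draws)

    def test_neuralnet_runs_and_is_seeded(self):
        rng = np.random.default_rng(8)
        theta, S = _linear_setup(rng, n=150)
        params = pd.DataFrame({"theta": theta})
        post = abc_rejection(S, S.mean(axis=0), params, n_accept=60)
        a = regression_adjust(post, S, S.mean(axis=0), method="neuralnet", seed=4)
        b = regression_adjust(post, S, S.mean(axis=0), method="neuralnet", seed=4)
        assert a.draws.equals(b.draws)


class TestEndToEndRecovery:
    def test_posterior_median_within_factor_three(self):
        # known invasion time; scaled-down table shared across replicates
        preset = TwoPopPreset(n_regions=60)
        priors = {"T": Prior(100.0, 20000.0, log=True)}
        table = build_reference_table(preset, priors, n_sims=400,
                                      samples=SAMPLES, seed=77)
        keep = table.summaries.std(axis=0) > 0
        reduced, _, pls = pls_reduce(table, table.summaries[0], n_components=3)
        truth = 3000.0
        hits = 0
        for k in range(20):
            obs = simulate_observed_summary(preset.build({"T": truth}),
                                            SAMPLES, seed=90_000 + k)
            robs = pls.transform(obs[keep].reshape(1, -1))[0]
            post = abc_rejection(reduced, robs, table.params,
                                 n_accept=40).summarise()
            med = post.point_estimates["T"]["median"]
            hits += truth / 3 <= med <= truth * 3
        assert hits >= 16, f"median within factor 3 in only {hits}/20"


class TestHpd:
    def test_uniform_1_to_100(self):
        draws = np.arange(1.0, 101.0)
        lo, hi = hpd_interval(draws, mass=0.95)
        assert hi - lo == 94.0  # 95 consecutive values

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(19)
        draws = rng.standard_normal(10000)
        lo, hi = hpd_interval(draws, mass=0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_identical_draws_zero_width(self):
        lo, hi = hpd_interval(np.full(50, 3.7), mass=0.95)
        assert lo == hi == 3.7

    def test_width_monotone_in_mass(self):
        rng = np.random.default_rng(23)
        draws = rng.gamma(3.0, 2.0, size=4000)
        widths = []
        for mass in (0.5, 0.8, 0.9, 0.95, 0.99):
            lo, hi = hpd_interval(draws, mass=mass)
            widths.append(hi - lo)
        assert all(w2 >= w1 for w1, w2 in zip(widths, widths[1:]))

    def test_weighted_hpd_respects_weights(self):
        draws = np.array([0.0] * 10 + [100.0])
        weights = np.array([1.0] * 10 + [1e-9])
        lo, hi = hpd_interval(draws, weights=weights, mass=0.95)
        assert hi == 0.0

    def test_posterior_summarise_orders(self):
        rng = np.random.default_rng(29)
        draws = pd.DataFrame({"T": rng.lognormal(7, 0.5, size=500)})
        post = ABCPosterior(draws=draws, weights=np.ones(500),
                            distances=np.zeros(500), method="rejection").summarise()
        lo, hi = post.hpd["T"]
        assert lo <= post.point_estimates["T"]["median"] <= hi
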