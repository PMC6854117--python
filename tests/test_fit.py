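import numpy as np
import pytest

from invadepop.coalescent import DemographicModel, Fusion, simulate_dataset
from invadepop.fit import (ModelFitResult, aic, bayes_factor_2ln,
                           composite_log_likelihood, expected_sfs, fit_model,
                           rank_models)
from invadepop.io_formats import PopulationMap
from invadepop.sfs import JointSFS, compute_joint_sfs

MU, L = 2.5e-8, 214


class SimplePreset:
    """Panmictic single-size preset for parameter-recovery tests."""

    name = "pan"

    def __init__(self, n_regions=300):
        self.n_regions = n_regions

    def build(self, overrides=None):
        p = {"N": 10000.0, **(overrides or {})}
        return DemographicModel(pop_names=["P"], sizes={"P": float(p["N"])},
                                mu=MU, region_length=L, n_regions=self.n_regions)


class SplitPreset:
    """Two populations splitting at time T."""

    name = "split"

    def __init__(self, n_regions=300):
        self.n_regions = n_regions

    def build(self, overrides=None):
        p = {"T": 10000.0, "N": 12000.0, **(overrides or {})}
        n = float(p["N"])
        t = float(p["T"])
        return DemographicModel(
            pop_names=["X", "Y", "A"], sizes={"X": n, "Y": n, "A": n},
            events=[Fusion(t, "X", "A"), Fusion(t + 1, "Y", "A")],
            mu=MU, region_length=L, n_regions=self.n_regions)


class TestArithmetic:
    def test_multinomial_example(self):
        obs = JointSFS(np.array([0.0, 3.0, 7.0, 0.0]), folded=False)
        probs = np.array([0.0, 0.3, 0.7, 0.0])
        lnl = composite_log_likelihood(obs, probs)
        assert lnl == pytest.approx(3 * np.log(0.3) + 7 * np.log(0.7), abs=1e-9)
        assert round(lnl, 4) == -6.1086

    def test_likelihood_maximal_at_proportional_probs(self):
        m = np.array([0.0, 5.0, 9.0, 2.0, 0.0])
        obs = JointSFS(m, folded=False)
        p_star = m / m.sum()
        best = composite_log_likelihood(obs, p_star)
        rng = np.random.default_rng(6)
        for _ in range(25):
            q = p_star.copy()
            q[1:-1] = np.maximum(q[1:-1] + rng.normal(0, 0.05, size=3), 1e-6)
            assert composite_log_likelihood(obs, q) <= best + 1e-12

    def test_zero_probability_cell_floored(self, caplog):
        obs = JointSFS(np.array([0.0, 4.0, 1.0, 0.0]), folded=False)
        probs = JointSFS(np.array([0.0, 1.0, 0.0, 0.0]), folded=False)
        probs.n_sims = 100
        with caplog.at_level("WARNING"):
            lnl = composite_log_likelihood(obs, probs)
        assert np.isfinite(lnl)
        assert lnl == pytest.approx(4 * np.log(1.0) + 1 * np.log(1 / 1000))
        assert any("floored" in r.message for r in caplog.records)

    def test_shape_mismatch_rejected(self):
        obs = JointSFS(np.zeros(4), folded=False)
        with pytest.raises(ValueError):
            composite_log_likelihood(obs, np.zeros(5))

    @pytest.mark.parametrize("lnl,d,expected", [
        (-23162.0, 10, 46344.0),
        (-22245.0, 13, 44516.0),
        (0.0, 0, 0.0),
    ])
    def test_aic_identity(self, lnl, d, expected):
        assert aic(lnl, d) == expected

    def test_aic_exact_to_machine_precision(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            lnl = rng.uniform(-1e7, 0)
            d = int(rng.integers(0, 60))
            assert aic(lnl, d) == 2.0 * d - 2.0 * lnl

    def test_bayes_factor_paper_row(self):
        assert bayes_factor_2ln(-8368.0, -8369.0) == 2.0

    @pytest.mark.parametrize("a,b,expected", [(5.0, 5.0, 0.0), (-100.0, -110.0, 20.0)])
    def test_bayes_factor_arithmetic(self, a, b, expected):
        assert bayes_factor_2ln(a, b) == expected


class TestRankModels:
    def _fit(self, mid, a, d=3):
        return ModelFitResult(model_id=mid, params={}, lnl=(2 * d - a) / 2.0, d=d)

    def test_paper_rank_column(self):
        aics = {"model1": 46344.0, "model2": 46323.0, "model3": 44516.0,
                "model4": 37271.0}
        fits = [self._fit(m, a) for m, a in aics.items()]
        ranked = rank_models(fits)
        by_model = {f.model_id: f.rank for f in ranked}
        assert by_model == {"model1": 4, "model2": 3, "model3": 2, "model4": 1}

    def test_tie_broken_by_smaller_d(self):
        f1 = self._fit("mA", 100.0, d=3)
        f2 = self._fit("mB", 100.0, d=2)
        ranked = rank_models([f1, f2])
        assert ranked[0].model_id == "mB" and ranked[0].rank == 1

    def test_single_model_rank_one(self):
        ranked = rank_models([self._fit("only", 10.0)])
        assert ranked[0].rank == 1


class TestExpectedSfs:
    def test_panmictic_unfolded_frequencies(self):
        model = SimplePreset().build({"N": 10000.0})
        probs = expected_sfs(model, {"P": 4}, n_sims=4000, seed=5, folded=False)
        # singleton:doubleton:tripleton = (1, 1/2, 1/3) / (11/6)
        expected = np.array([1.0, 0.5, 1 / 3]) / (11 / 6)
        got = probs.counts[1:4]
        assert np.allclose(got, expected, atol=0.02)

    def test_split_time_monotone_private_mass(self):
        preset = SplitPreset()
        private = []
        for t in (500.0, 20000.0, 200000.0):
            probs = expected_sfs(preset.build({"T": t}), {"X": 4, "Y": 4},
                                 n_sims=1500, seed=11, folded=False)
            c = probs.counts
            shared = c[1:-1, 1:-1].sum()
            priv = c.sum() - shared
            private.append(priv)
        assert private[0] < private[1] < private[2]

    def test_fixed_seed_reproducible(self):
        model = SplitPreset().build()
        a = expected_sfs(model, {"X": 4, "Y": 4}, n_sims=500, seed=3)
        b = expected_sfs(model, {"X": 4, "Y": 4}, n_sims=500, seed=3)
        assert np.array_equal(a.counts, b.counts)

    def test_n_sims_validated(self):
        with pytest.raises(ValueError):
            expected_sfs(SimplePreset().build(), {"P": 4}, n_sims=0, seed=1)


def _observed(preset, params, samples, seed, n_regions):
    gm = simulate_dataset(preset.build(params), samples, diploid=True,
                          seed=seed, n_regions=n_regions)
    pops = list(samples)
    pm = PopulationMap(assignments={i: i.split("_")[0] for i in gm.individual_ids},
                      labels=pops)
    return compute_joint_sfs(gm, pm, pops, folded=True)


class TestFitModel:
    def test_theta_recovery_within_25_percent(self):
        preset = SimplePreset(n_regions=300)
        truth = 20000.0
        obs = _observed(preset, {"N": truth}, {"P": 40}, seed=11, n_regions=300)
        res = fit_model(obs, preset, {"N": (2000.0, 200000.0)}, samples={"P": 40},
                        cycles=(4, 8), n_runs=3, n_sims=400, seed=2,
                        objective="poisson", obs_regions=300)
        assert res.d == 1
        assert abs(res.params["N"] - truth) / truth < 0.25

    def test_split_time_recovery_within_factor_two(self):
        preset = SplitPreset(n_regions=250)
        truth = 15000.0
        obs = _observed(preset, {"T": truth}, {"X": 10, "Y": 10}, seed=23,
                        n_regions=250)
        res = fit_model(obs, preset, {"T": (1000.0, 150000.0)},
                        samples={"X": 10, "Y": 10}, cycles=(3, 6), n_runs=2,
                        n_sims=300, seed=5)
        assert truth / 2 <= res.params["T"] <= truth * 2

    def test_seed_fixed_double_execution_identical(self):
        preset = SimplePreset(n_regions=60)
        obs = _observed(preset, {"N": 8000.0}, {"P": 8}, seed=3, n_regions=60)
        kwargs = dict(free_params={"N": (2000.0, 50000.0)}, samples={"P": 8},
                      cycles=(2, 3), n_runs=2, n_sims=120, seed=9)
        r1 = fit_model(obs, preset, **kwargs)
        r2 = fit_model(obs, preset, **kwargs)
        assert r1.lnl == r2.lnl and r1.params == r2.params and r1.aic == r2.aic

    def test_nested_model_never_fits_worse(self):
        # freeing an extra parameter cannot lower the best achievable lnL
        # beyond Monte-Carlo noise
        preset = SplitPreset(n_regions=150)
        obs = _observed(preset, {"T": 20000.0}, {"X": 8, "Y": 8}, seed=31,
                        n_regions=150)
        common = dict(samples={"X": 8, "Y": 8}, cycles=(3, 5), n_runs=2,
                      n_sims=300, seed=13)
        r_small = fit_model(obs, preset, {"T": (1000.0, 100000.0)}, **common)
        r_big = fit_model(obs, preset, {"T": (1000.0, 100000.0),
                                        "N": (3000.0, 50000.0)}, **common)
        assert r_big.lnl >= r_small.lnl - 12.0  # Monte-Carlo slack
        assert r_big.d == 2 and r_small.d == 1

    def test_invalid_bounds_rejected(self):
        preset = SimplePreset()
        obs = JointSFS(np.zeros(9), folded=True)
        with pytest.raises(ValueError):
            fit_model(obs, preset, {"N": (0.0, np.inf)}, samples={"P": 8})
        with pytest.raises(ValueError):
            fit_model(obs, preset, {}, samples={"P": 8})
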