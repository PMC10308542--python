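"""DASS scoring, slider aggregation and mediation decomposition."""

import numpy as np
import pandas as pd
import pytest

import ftrclassify as f


class TestDassScoring:
    def test_all_zero(self):
        assert f.score_dass([0] * 21) == {"depression": 0, "anxiety": 0, "stress": 0}

    def test_all_three_hits_theoretical_max(self):
        assert f.score_dass([3] * 21) == {"depression": 42, "anxiety": 42,
                                          "stress": 42}

    def test_hand_computed_single_dimension(self):
        from ftrclassify.mediation import DASS_ITEM_MAP
        dep_items = [i for i, d in DASS_ITEM_MAP.items() if d == "depression"]
        values = dict.fromkeys(range(1, 22), 0)
        for item, v in zip(dep_items, [1, 1, 2, 0, 3, 1, 2]):
            values[item] = v
        scores = f.score_dass(values)
        assert scores == {"depression": 20, "anxiety": 0, "stress": 0}

    def test_missing_and_out_of_range_reported(self):
        with pytest.raises(ValueError, match="missing items"):
            f.score_dass({i: 0 for i in range(1, 21)})
        bad = dict.fromkeys(range(1, 22), 0)
        bad[5] = 4
        with pytest.raises(ValueError, match=r"\[5\]"):
            f.score_dass(bad)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        values = {i: int(v) for i, v in
                  zip(range(1, 22), rng.integers(0, 4, 21))}
        shuffled = dict(sorted(values.items(), key=lambda kv: -kv[0]))
        assert f.score_dass(values) == f.score_dass(shuffled)


class TestSubjectiveDistance:
    @pytest.mark.parametrize("ratings, expected", [
        ([50] * 11, 50.0),
        ([0, 100], 50.0),
        ([min(r * 10, 100) for r in range(1, 12)], 650 / 11),
    ])
    def test_mean(self, ratings, expected):
        assert f.mean_subjective_distance(ratings) == pytest.approx(expected)

    def test_permutation_invariant(self):
        r = [3, 97, 40, 12, 88]
        assert f.mean_subjective_distance(r) == f.mean_subjective_distance(r[::-1])

    def test_bounds_and_empty(self):
        with pytest.raises(ValueError):
            f.mean_subjective_distance([])
        with pytest.raises(ValueError):
            f.mean_subjective_distance([101])


class TestEffectDecomposition:
    def test_single_draw_arithmetic(self):
        eff = f.effect_decomposition(np.array([2.0]), np.array([3.0]),
                                     np.array([1.0]))
        assert eff["indirect"][0] == 6 and eff["direct"][0] == 1
        assert eff["total"][0] == 7

    def test_drawwise_identity_exact(self):
        rng = np.random.default_rng(1)
        a, b, t = rng.normal(size=(3, 500))
        eff = f.effect_decomposition(a, b, t)
        assert np.array_equal(eff["total"], eff["indirect"] + eff["direct"])

    def test_interval_endpoints_match_quantile_oracle(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(1.0, 0.5, 4000)
        from ftrclassify.mediation import _summary
        s = _summary(draws, point=1.0, direction=+1)
        assert s.ci90 == pytest.approx(tuple(np.quantile(draws, [0.05, 0.95])))
        assert s.ci95 == pytest.approx(tuple(np.quantile(draws, [0.025, 0.975])))
        assert s.pp == pytest.approx(np.mean(draws > 0))

    def test_identical_draws_zero_width(self):
        from ftrclassify.mediation import _summary
        s = _summary(np.full(100, 2.5), point=2.5, direction=+1)
        assert s.ci90 == (2.5, 2.5) and s.ci95 == (2.5, 2.5)


class TestFitMediation:
    def test_planted_paths_recovered_large_n(self):
        df = f.simulate_study2(5000, seed=2, alpha1=0.5, beta=0.3, tau1=0.0,
                               sigma1=1.0, sigma2=0.1)
        res = f.fit_mediation(df, n_draws=400, seed=3)
        eff = res.effects["anxiety"]
        assert eff["indirect"].point == pytest.approx(0.15, abs=0.01)
        assert eff["direct"].point == pytest.approx(0.0, abs=0.01)
        assert eff["total"].point == pytest.approx(0.15, abs=0.01)

    def test_noiseless_outcome_equation_recovered_exactly(self):
        df = f.simulate_study2(300, seed=5, alpha1=0.5, alpha2=0.2, beta=0.3,
                               tau1=0.0, tau2=0.0, sigma1=2.0, sigma2=0.0)
        res = f.fit_mediation(df, n_draws=50, seed=1)
        assert res.paths["beta"].point == pytest.approx(0.3)
        assert res.paths["tau1"].point == pytest.approx(0.0, abs=1e-10)
        assert res.paths["alpha1"].point == pytest.approx(0.5, abs=0.05)

    def test_zero_mediator_noise_is_degenerate(self):
        """With no mediator noise M is an exact linear combination of the
        predictors, leaving the outcome equation unidentified."""
        df = f.simulate_study2(300, seed=5, sigma1=0.0, sigma2=0.5)
        with pytest.raises(ValueError, match="collinear"):
            f.fit_mediation(df, n_draws=10)

    def test_outcome_equal_to_mediator(self):
        """Y = M (beta = 1, tau' = 0, no outcome noise): direct effects
        vanish and the outcome equation fits perfectly."""
        df = f.simulate_study2(500, seed=6, beta=1.0, tau1=0.0, tau2=0.0,
                               lambda2=0.0, sigma2=0.0)
        res = f.fit_mediation(df, n_draws=50, seed=2)
        assert res.paths["beta"].point == pytest.approx(1.0)
        assert res.paths["tau1"].point == pytest.approx(0.0, abs=1e-8)
        assert res.r_squared["log_k"].point == pytest.approx(1.0)

    def test_summary_of_total_is_summary_of_sums(self):
        df = f.simulate_study2(202, seed=7)
        res = f.fit_mediation(df, n_draws=300, seed=4)
        for pred in ("anxiety", "depression"):
            eff = res.effects[pred]
            assert eff["total"].mean == pytest.approx(
                eff["indirect"].mean + eff["direct"].mean)

    def test_interval_ordering(self):
        df = f.simulate_study2(202, seed=8)
        res = f.fit_mediation(df, n_draws=300, seed=5)
        for s in list(res.paths.values()) + [e for d in res.effects.values()
                                             for e in d.values()]:
            assert s.ci95[0] <= s.ci90[0] <= s.ci90[1] <= s.ci95[1]

    def test_directional_pp(self):
        df = f.simulate_study2(500, seed=9, alpha1=1.0, beta=0.5, sigma2=0.5)
        res = f.fit_mediation(df, n_draws=300, seed=6,
                              directions={"anxiety": +1})
        assert res.effects["anxiety"]["indirect"].pp > 0.99
        res_neg = f.fit_mediation(df, n_draws=300, seed=6,
                                  directions={"anxiety": -1})
        assert res_neg.effects["anxiety"]["indirect"].pp < 0.01

    def test_degenerate_inputs_error(self):
        df = f.simulate_study2(50, seed=10)
        with pytest.raises(ValueError, match="complete cases"):
            f.fit_mediation(df.head(5))
        bad = df.copy()
        bad["depression"] = bad["anxiety"]
        with pytest.raises(ValueError, match="collinear"):
            f.fit_mediation(bad, n_draws=10)
        const = df.copy()
        const["anxiety"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            f.fit_mediation(const, n_draws=10)

    def test_standardize_flag(self):
        df = f.simulate_study2(500, seed=11)
        res = f.fit_mediation(df, n_draws=50, seed=7, standardize=True)
        # standardized total effect of anxiety is a correlation-scale quantity
        assert abs(res.effects["anxiety"]["total"].point) < 1.5

    def test_reproducible_under_seed(self):
        df = f.simulate_study2(202, seed=12)
        r1 = f.fit_mediation(df, n_draws=200, seed=9)
        r2 = f.fit_mediation(df, n_draws=200, seed=9)
        assert r1.to_dict() == r2.to_dict()
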