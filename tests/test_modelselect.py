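import numpy as np
import pytest

from steppingstone.modelselect import (
    ModelEvidence,
    build_hawaii_models,
    build_simulation_models,
    count_parameters,
    permutation_t_test,
    posterior_slope_test,
    relative_probabilities,
    select_model,
)

HAWAII = [
    "Hawaii", "Maui", "Oahu", "Kauai", "Niihau",
    "French Frigate Shoals", "Gardner Pinnacles", "Maro Reef",
    "Laysan", "Lisianski", "Pearl & Hermes", "Midway", "Kure",
]


class TestSimulationModels:
    def test_seven_hypotheses_with_expected_parameter_counts(self):
        models = {m.name: m for m in build_simulation_models(10)}
        expected = {
            "panmixia": 1,
            "stepping-stone-5-shared": 2,
            "stepping-stone-5-free": 13,   # 5 Theta + 2*4 rates
            "island": 2,
            "island-5": 2,
            "stepping-stone-2param": 2,
            "stepping-stone-full": 28,     # 10 Theta + 2*10-2 rates
        }
        assert len(models) == 7
        for name, k in expected.items():
            assert count_parameters(models[name]) == k, name

    def test_lumping_maps_adjacent_pairs(self):
        m = {m.name: m for m in build_simulation_models(10)}["island-5"]
        assert list(m.deme_partition) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_odd_deme_count_rejected(self):
        with pytest.raises(ValueError):
            build_simulation_models(9)


class TestHawaiiModels:
    def test_canonical_archipelago_set(self):
        models = {m.name: m for m in build_hawaii_models(HAWAII)}
        n = len(HAWAII)
        # two-currents hypothesis: 3 regions, free pairwise rates
        assert count_parameters(models["two-currents"]) == 3 + 6
        assert count_parameters(models["regional-mhi-nwhi"]) == 2 + 2
        assert count_parameters(models["regional-ffs-gardner"]) == 2 + 2
        assert count_parameters(models["stepping-stone-full"]) == n + 2 * n - 2
        assert count_parameters(models["stepping-stone-2param"]) == 2
        assert count_parameters(models["island"]) == 2
        assert count_parameters(models["panmixia"]) == 1

    def test_two_currents_regions_split_at_the_named_channels(self):
        models = {m.name: m for m in build_hawaii_models(HAWAII)}
        part = models["two-currents"].deme_partition
        ffs = HAWAII.index("French Frigate Shoals")
        lis = HAWAII.index("Lisianski")
        assert part[ffs] == part[0]
        assert part[ffs + 1] == part[0] + 1
        assert part[lis + 1] == part[lis] + 1

    def test_custom_partition_appended(self):
        models = build_hawaii_models(HAWAII, custom_partition=[0] * 6 + [1] * 7)
        assert models[-1].name == "empirical-structure"
        assert count_parameters(models[-1]) == 2 + 2

    def test_boundary_validation(self):
        with pytest.raises(ValueError):
            build_hawaii_models(HAWAII, region_boundaries={"bad": [0]})


class TestRelativeProbabilities:
    def test_equal_evidence_uniform(self):
        p = relative_probabilities({f"m{i}": -50.0 for i in range(7)})
        assert all(v == pytest.approx(1 / 7) for v in p.values())

    def test_dominant_model(self):
        p = relative_probabilities({"a": 0.0, "b": -100.0})
        assert p["a"] >= 1 - 1e-40

    def test_log_half_gap(self):
        p = relative_probabilities({"a": 0.0, "b": -np.log(2)})
        assert p["a"] == pytest.approx(2 / 3)
        assert p["b"] == pytest.approx(1 / 3)

    def test_shift_invariance(self):
        base = {"a": -10.0, "b": -12.5, "c": -11.1}
        shifted = {k: v + 777.0 for k, v in base.items()}
        pa, pb = relative_probabilities(base), relative_probabilities(shifted)
        for k in base:
            assert pa[k] == pytest.approx(pb[k])


class TestPermutationTTest:
    def test_identical_groups_give_one(self):
        assert permutation_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_disjoint_three_vs_three_is_exactly_one_tenth(self):
        # all 20 relabelings enumerated; only the observed split and its
        # mirror reach the observed |t|, hence two-sided p = 2/20
        p = permutation_t_test([10.0, 11.0, 12.0], [20.0, 21.0, 22.0])
        assert p == pytest.approx(0.1)

    def test_p_never_below_reciprocal_of_relabelings(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4) + 50
        assert permutation_t_test(a, b) >= 1 / 70  # C(8,4) = 70

    def test_monte_carlo_fallback_close_to_exhaustive(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(6) + 1.0
        exact = permutation_t_test(a, b)
        approx = permutation_t_test(a, b, max_exhaustive=1, n_mc=20_000,
                                    rng=np.random.default_rng(5))
        assert approx == pytest.approx(exact, abs=0.03)


class TestSelectModel:
    def test_clear_winner_not_ambiguous(self):
        ev = [
            ModelEvidence("best", [-10.0, -11.0, -9.0], 2),
            ModelEvidence("second", [-60.0, -61.0, -59.0], 2),
            ModelEvidence("third", [-90.0, -91.0, -89.0], 1),
        ]
        res = select_model(ev)
        assert res.best == "best"
        assert res.second == "second"
        assert not res.ambiguous
        assert sum(res.probabilities.values()) == pytest.approx(1.0)

    def test_interleaved_replicates_ambiguous(self):
        ev = [
            ModelEvidence("a", [-10.0, -12.0, -11.0], 2),
            ModelEvidence("b", [-10.5, -11.5, -11.0], 2),
        ]
        res = select_model(ev)
        assert res.ambiguous
        assert res.p_value > 0.05

    def test_input_order_invariance(self):
        ev = [
            ModelEvidence("a", [-10.0, -12.0], 3),
            ModelEvidence("b", [-30.0, -31.0], 2),
            ModelEvidence("c", [-20.0, -21.0], 1),
        ]
        r1 = select_model(ev)
        r2 = select_model(ev[::-1])
        assert (r1.best, r1.second) == (r2.best, r2.second)

    def test_mean_ties_break_toward_parsimony(self):
        ev = [
            ModelEvidence("complex", [-10.0, -10.0], 28),
            ModelEvidence("simple", [-10.0, -10.0], 2),
        ]
        assert select_model(ev).best == "simple"

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            select_model([ModelEvidence("only", [-1.0, -2.0], 1)])


class TestPosteriorSlopeTest:
    def test_exchangeable_posteriors_are_null(self, rng):
        post = {f"i{k}": rng.lognormal(0.0, 0.3, 500) for k in range(5)}
        cov = {f"i{k}": float(k) for k in range(5)}
        res = posterior_slope_test(post, cov, n_draws=4000, rng=rng)
        assert 0.3 < res.fraction_positive < 0.7
        assert not res.significant

    def test_strong_positive_trend_detected(self, rng):
        post = {
            f"i{k}": np.exp(0.8 * k + 0.01 * rng.standard_normal(500))
            for k in range(5)
        }
        cov = {f"i{k}": float(k) for k in range(5)}
        res = posterior_slope_test(post, cov, n_draws=4000, rng=rng)
        assert res.fraction_positive > 0.99
        assert res.significant

    def test_single_draw_is_binary(self, rng):
        post = {f"i{k}": rng.random(50) + 0.5 for k in range(3)}
        cov = {f"i{k}": float(k) for k in range(3)}
        res = posterior_slope_test(post, cov, n_draws=1, rng=rng)
        assert res.fraction_positive in (0.0, 1.0)

    def test_constant_covariate_rejected(self, rng):
        post = {f"i{k}": rng.random(50) + 0.5 for k in range(3)}
        with pytest.raises(ValueError):
            posterior_slope_test(post, {f"i{k}": 1.0 for k in range(3)}, rng=rng)
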