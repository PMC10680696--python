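import numpy as np
import pytest

from mgpp import (
    ModelSpec,
    MultitypePointPattern,
    Parameters,
    PatternState,
    Window,
    contribution_decomposition,
    log_density_unnormalized,
    log_papangelou,
    model_from_json,
    model_to_json,
    pair_statistic,
    papangelou,
    saturated_potential,
    short_potential,
)
from conftest import (
    brute_log_density,
    brute_pair_statistic,
    brute_saturated_potential,
    random_small_scene,
)


class TestSaturatedPotential:
    def test_empty_target_is_zero(self):
        assert saturated_potential((0, 0), np.zeros((0, 2)),
                                   short_potential(), 2) == 0.0

    def test_saturation_inactive_gives_plain_sum(self):
        rng = np.random.default_rng(0)
        tgt = rng.uniform(0, 50, (3, 2))
        pot = short_potential(30.0)
        d = np.hypot(tgt[:, 0], tgt[:, 1])
        assert saturated_potential((0, 0), tgt, pot, 10) == pytest.approx(
            float(pot.evaluate(d).sum()))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_subset_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tgt = rng.uniform(0, 100, (5, 2))
        x = rng.uniform(0, 100, 2)
        N = int(rng.integers(1, 4))
        pot = short_potential(30.0)
        assert saturated_potential(x, tgt, pot, N) == \
            brute_saturated_potential(x, tgt, pot, N)

    def test_monotone_in_target_and_bounded_by_N(self):
        rng = np.random.default_rng(4)
        pot = short_potential(30.0)
        x = (50.0, 50.0)
        tgt = rng.uniform(0, 100, (6, 2))
        prev = 0.0
        for k in range(1, 7):
            v = saturated_potential(x, tgt[:k], pot, 2)
            assert v >= prev - 1e-15
            assert v <= 2.0
            prev = v


class TestPairStatistic:
    def test_absent_partner_type_is_zero(self):
        w = Window(0, 100, 0, 100)
        pat = MultitypePointPattern([[10, 10]], ["A"], w, type_set=["A", "B"])
        model = ModelSpec(type_set=["A", "B"])
        assert pair_statistic(pat, "A", "B", "short", model) == 0.0

    def test_two_points_at_radius_give_unity(self):
        # each point contributes 0.5 toward the other (half-at-radius)
        w = Window(0, 100, 0, 100)
        pat = MultitypePointPattern([[10, 10], [40, 10]], ["A", "A"], w)
        model = ModelSpec(type_set=["A"], saturation=2)
        assert pair_statistic(pat, "A", "A", "short", model) == \
            pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("scale", ["short", "medium"])
    def test_matches_brute_force_double_sum(self, seed, scale):
        pattern, model, _ = random_small_scene(seed)
        for t1 in model.type_set:
            for t2 in model.type_set:
                got = pair_statistic(pattern, t1, t2, scale, model)
                want = brute_pair_statistic(pattern, t1, t2, scale, model)
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


class TestLogDensity:
    def test_empty_pattern_is_zero(self):
        w = Window(0, 10, 0, 10)
        pat = MultitypePointPattern(np.zeros((0, 2)), [], w, type_set=["A"])
        model = ModelSpec(type_set=["A"])
        params = Parameters(beta0=[-2.0], alpha=[[1.0]], gamma=[[0.5]])
        assert log_density_unnormalized(pat, model, params) == 0.0

    def test_poisson_limit_is_first_order_only(self):
        pattern, model, _ = random_small_scene(21)
        params = Parameters.zeros(model.n_types)
        params.beta0[:] = [-3.0, -4.0]
        counts = pattern.counts()
        expected = sum(counts[t] * params.beta0[i]
                       for i, t in enumerate(model.type_set))
        assert log_density_unnormalized(pattern, model, params) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_term_by_term_brute_expansion(self, seed):
        pattern, model, params = random_small_scene(seed, max_points=5)
        got = log_density_unnormalized(pattern, model, params)
        assert got == pytest.approx(brute_log_density(pattern, model, params),
                                    rel=1e-12, abs=1e-12)

    def test_invariant_under_type_relabeling(self):
        pattern, model, params = random_small_scene(33)
        # swap the two labels everywhere and transpose the matrices
        swapped_types = [{"T0": "T1", "T1": "T0"}[t] for t in pattern.types]
        pat2 = MultitypePointPattern(pattern.coords, swapped_types,
                                     pattern.window, type_set=["T0", "T1"])
        perm = [1, 0]
        params2 = Parameters(beta0=params.beta0[perm],
                             alpha=params.alpha[np.ix_(perm, perm)],
                             gamma=params.gamma[np.ix_(perm, perm)])
        assert log_density_unnormalized(pattern, model, params) == \
            pytest.approx(log_density_unnormalized(pat2, model, params2),
                          rel=1e-12)


class TestPapangelou:
    def test_empty_pattern_gives_intercept_intensity(self):
        w = Window(0, 10, 0, 10)
        pat = MultitypePointPattern(np.zeros((0, 2)), [], w, type_set=["A"])
        model = ModelSpec(type_set=["A"])
        params = Parameters(beta0=[-2.0], alpha=[[1.5]], gamma=[[0.5]])
        assert papangelou((5, 5), "A", pat, model, params) == \
            pytest.approx(np.exp(-2.0))

    def test_poisson_limit_is_pattern_independent(self):
        pattern, model, _ = random_small_scene(8)
        params = Parameters.zeros(model.n_types)
        params.beta0[:] = [-2.0, -3.0]
        y = (60.0, 60.0)
        full = papangelou(y, "T0", pattern, model, params)
        empty = MultitypePointPattern(np.zeros((0, 2)), [], pattern.window,
                                      type_set=model.type_set)
        assert full == pytest.approx(
            papangelou(y, "T0", empty, model, params))

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_density_ratio_when_saturation_binds(self, seed):
        """The linear-predictor path must include the change in saturated
        potentials of existing points, not only the new point's own."""
        pattern, model, params = random_small_scene(seed, max_points=6,
                                                    saturation=1)
        rng = np.random.default_rng(seed + 1000)
        y = rng.uniform(0, pattern.window.x_max, 2)
        for t in model.type_set:
            ld1 = log_density_unnormalized(pattern.add_point(y[0], y[1], t),
                                           model, params)
            ld0 = log_density_unnormalized(pattern, model, params)
            assert log_papangelou(y, t, pattern, model, params) == \
                pytest.approx(ld1 - ld0, rel=1e-10, abs=1e-10)

    def test_outside_window_is_error(self):
        pattern, model, params = random_small_scene(2)
        with pytest.raises(ValueError):
            papangelou((-5.0, 5.0), "T0", pattern, model, params)


class TestContributionDecomposition:
    def test_zero_parameters_give_zero_contributions(self):
        pattern, model, _ = random_small_scene(3)
        params = Parameters.zeros(model.n_types)
        c = contribution_decomposition((50, 50), "T0", pattern, model, params)
        assert all(v == 0.0 for v in c.values())

    def test_single_nonzero_pair_isolates(self):
        pattern, model, _ = random_small_scene(5)
        params = Parameters.zeros(model.n_types)
        a = np.zeros((2, 2))
        a[0, 1] = a[1, 0] = -0.7
        params = Parameters(beta0=params.beta0, alpha=a,
                            gamma=np.zeros((2, 2)))
        c = contribution_decomposition((50, 50), "T0", pattern, model, params)
        assert c["T0"] == 0.0
        lp = log_papangelou((50, 50), "T0", pattern, model, params)
        assert c["T1"] == pytest.approx(lp - params.beta0[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_contributions_sum_to_interaction_part(self, seed):
        pattern, model, params = random_small_scene(seed)
        y = (40.0, 70.0)
        for t_i, t in enumerate(model.type_set):
            c = contribution_decomposition(y, t, pattern, model, params)
            lp = log_papangelou(y, t, pattern, model, params)
            assert sum(c.values()) == pytest.approx(lp - params.beta0[t_i],
                                                    abs=1e-10)


class TestPatternState:
    """Incremental birth/death bookkeeping must agree with a fresh
    rebuild after any sequence of insertions and deletions."""

    @pytest.mark.parametrize("seed", range(4))
    def test_mutations_match_rebuild(self, seed):
        pattern, model, _ = random_small_scene(seed, max_points=8)
        state = PatternState(pattern, model)
        rng = np.random.default_rng(seed + 50)
        for _ in range(30):
            if state.n_points == 0 or rng.random() < 0.55:
                y = rng.uniform(0, pattern.window.x_max, 2)
                state.apply_birth(y, int(rng.integers(model.n_types)))
            else:
                state.apply_death(int(rng.integers(state.n_points)))
        fresh = PatternState(state.coords, model, type_idx=state.type_idx,
                             window=state.window)
        np.testing.assert_allclose(state.top_short, fresh.top_short,
                                   atol=1e-12)
        np.testing.assert_allclose(state.top_medium, fresh.top_medium,
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_batch_deltas_match_scalar_deltas(self, seed):
        pattern, model, params = random_small_scene(seed)
        state = PatternState(pattern, model)
        rng = np.random.default_rng(seed)
        ys = rng.uniform(0, pattern.window.x_max, (7, 2))
        for t in range(model.n_types):
            Ds, Dm = state.birth_delta_batch(ys, t)
            for r, y in enumerate(ys):
                ds, dm = state.birth_delta(y, t)
                np.testing.assert_allclose(Ds[r], ds, atol=1e-12)
                np.testing.assert_allclose(Dm[r], dm, atol=1e-12)
        idx = np.arange(state.n_points)
        Ds, Dm = state.removal_delta_batch(idx)
        for i in idx:
            ds, dm = state.removal_delta(int(i))
            np.testing.assert_allclose(Ds[i], ds, atol=1e-12)
            np.testing.assert_allclose(Dm[i], dm, atol=1e-12)


class TestSerialization:
    def test_json_round_trip_bit_exact(self):
        _, model, params = random_small_scene(17)
        doc = model_to_json(model, params)
        model2, params2 = model_from_json(doc)
        assert model2.type_set == model.type_set
        assert model2.saturation == model.saturation
        assert model2.short.radii == model.short.radii
        np.testing.assert_array_equal(params2.beta0, params.beta0)
        np.testing.assert_array_equal(params2.alpha, params.alpha)
        np.testing.assert_array_equal(params2.gamma, params.gamma)
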