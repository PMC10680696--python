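import numpy as np
import pandas as pd
import pytest

from mgpp import (
    ModelSpec,
    MultitypePointPattern,
    Parameters,
    Window,
    auc_abundance_correlation,
    contribution_decomposition,
    extract_parameters,
    group_median_difference,
    mad,
    mad_heterogeneity,
    mann_whitney_auc,
    model_auc,
    short_potential,
    medium_potential,
    top_contributor_map,
)
from mgpp.cohort import NO_CONTRIBUTION
from conftest import fitted_from_params


def _three_type_model(**kw):
    return ModelSpec(type_set=["tumor", "B", "C"], **kw)


def _table_from(models_params, meta):
    fits = [(fitted_from_params(m, p), *ids)
            for (m, p), ids in zip(models_params, meta)]
    return extract_parameters(fits)


class TestExtractParameters:
    def test_row_counts_for_three_types(self):
        model = _three_type_model()
        mp = [(model, Parameters.zeros(3))] * 2
        meta = [("img1", "p1", "CLR"), ("img2", "p2", "DII")]
        table = _table_from(mp, meta)
        for img in ("img1", "img2"):
            sub = table[table["image_id"] == img]
            assert (sub["kind"] == "alpha").sum() == 6  # 3 within + 3 between
            assert (sub["kind"] == "gamma").sum() == 6

    def test_filtered_type_rows_absent_not_zero(self):
        full = _three_type_model()
        reduced = ModelSpec(type_set=["tumor", "B"])
        mp = [(full, Parameters.zeros(3)), (reduced, Parameters.zeros(2))]
        meta = [("img1", "p1", "CLR"), ("img2", "p1", "CLR")]
        table = _table_from(mp, meta)
        img2 = table[table["image_id"] == "img2"]
        assert not ((img2["type1"] == "C") | (img2["type2"] == "C")).any()
        assert (img2["kind"] == "alpha").sum() == 3

    def test_duplicate_image_id_is_error(self):
        model = _three_type_model()
        mp = [(model, Parameters.zeros(3))] * 2
        meta = [("img1", "p1", "CLR"), ("img1", "p2", "DII")]
        with pytest.raises(ValueError, match="duplicate"):
            _table_from(mp, meta)

    def test_round_trip_to_matrix_and_back(self):
        model = _three_type_model()
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 3))
        a = (a + a.T) / 2
        params = Parameters(beta0=np.zeros(3), alpha=a,
                            gamma=np.zeros((3, 3)))
        table = _table_from([(model, params)], [("img1", "p1", "CLR")])
        rebuilt = np.zeros((3, 3))
        for _, row in table[table["kind"] == "alpha"].iterrows():
            i, j = model.type_index(row["type1"]), model.type_index(row["type2"])
            rebuilt[i, j] = rebuilt[j, i] = row["estimate"]
        np.testing.assert_allclose(rebuilt, a)


def _pair_rows(values, image_ids, group, t1="A", t2="B"):
    return pd.DataFrame({
        "image_id": image_ids, "patient_id": image_ids, "group": group,
        "kind": "alpha", "type1": t1, "type2": t2, "covariate": None,
        "scale": "short", "estimate": values, "se": 0.1,
        "significant": False,
    })


class TestGroupMedianDifference:
    def test_hand_computed_medians(self):
        tab = pd.concat([
            _pair_rows([1.0, 2.0, 9.0], ["i1", "i2", "i3"], "CLR"),
            _pair_rows([0.0, 1.0], ["i4", "i5"], "DII"),
        ])
        out = group_median_difference(tab, "CLR", "DII")
        assert out.loc["A", "B"] == pytest.approx(2.0 - 0.5)
        assert out.loc["B", "A"] == pytest.approx(1.5)

    def test_identical_groups_give_zero(self):
        tab = pd.concat([
            _pair_rows([1.0, 2.0], ["i1", "i2"], "CLR"),
            _pair_rows([1.0, 2.0], ["i3", "i4"], "DII"),
        ])
        out = group_median_difference(tab, "CLR", "DII")
        assert out.loc["A", "B"] == 0.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        tab = pd.concat([
            _pair_rows(rng.normal(size=4), [f"i{k}" for k in range(4)], "CLR"),
            _pair_rows(rng.normal(size=3), [f"j{k}" for k in range(3)], "DII"),
        ])
        ab = group_median_difference(tab, "CLR", "DII")
        ba = group_median_difference(tab, "DII", "CLR")
        np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy())

    def test_unknown_group_is_error(self):
        tab = _pair_rows([1.0], ["i1"], "CLR")
        with pytest.raises(ValueError):
            group_median_difference(tab, "CLR", "nope")

    def test_pair_missing_in_one_group_is_nan(self):
        tab = pd.concat([
            _pair_rows([1.0], ["i1"], "CLR"),
            _pair_rows([1.0], ["i2"], "DII", t1="A", t2="C"),
        ])
        out = group_median_difference(tab, "CLR", "DII")
        assert np.isnan(out.loc["A", "B"])
        assert np.isnan(out.loc["A", "C"])


class TestMadHeterogeneity:
    @pytest.mark.parametrize("values,expected", [
        ([2.0, 2.0, 2.0], 0.0),
        ([1.0, 2.0, 3.0], 1.0),
        ([0.0, 0.0, 1.0, 4.0], 0.5),  # median 0.5, deviations .5,.5,.5,3.5
    ])
    def test_hand_computed_mad(self, values, expected):
        assert mad(values) == expected

    def test_pooled_and_per_group(self):
        tab = pd.concat([
            _pair_rows([1.0, 2.0, 3.0], ["i1", "i2", "i3"], "CLR"),
            _pair_rows([5.0, 5.0], ["i4", "i5"], "DII"),
        ])
        pooled = mad_heterogeneity(tab, grouping="all")
        assert pooled.loc["A", "B"] == mad([1, 2, 3, 5, 5])
        per = mad_heterogeneity(tab, grouping="per-group")
        assert per["CLR"].loc["A", "B"] == 1.0
        assert per["DII"].loc["A", "B"] == 0.0

    def test_single_estimate_is_missing(self):
        tab = _pair_rows([1.0], ["i1"], "CLR")
        out = mad_heterogeneity(tab, grouping="all")
        assert np.isnan(out.loc["A", "B"])

    def test_mad_nonnegative_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            assert mad(rng.normal(size=rng.integers(2, 12))) >= 0.0


class TestTopContributorMap:
    def _scene(self):
        w = Window(0, 100, 0, 100)
        coords = [[20, 20], [25, 20], [80, 80], [80, 75], [50, 50]]
        labels = ["tumor", "B", "C", "C", "tumor"]
        pat = MultitypePointPattern(coords, labels, w,
                                    type_set=["tumor", "B", "C"])
        return w, pat

    def test_all_zero_parameters_give_sentinel(self):
        _, pat = self._scene()
        model = _three_type_model()
        fitted = fitted_from_params(model, Parameters.zeros(3))
        labels, mag = top_contributor_map(fitted, pat, "tumor", grid=(8, 8))
        assert (labels == NO_CONTRIBUTION).all()
        assert np.all(mag.values == 0.0)

    def test_single_nonzero_pair_isolates_that_type(self):
        _, pat = self._scene()
        model = _three_type_model(
            short=short_potential(30.0, family="step"),
            medium=medium_potential((70.0, 150.0), family="step"))
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = -1.0  # tumor-B only
        fitted = fitted_from_params(model, Parameters(
            beta0=np.zeros(3), alpha=a, gamma=np.zeros((3, 3))))
        labels, _ = top_contributor_map(fitted, pat, "tumor", grid=(10, 10))
        assert set(np.unique(labels)) <= {"B", NO_CONTRIBUTION}
        assert (labels == "B").any()

    def test_matches_per_pixel_decomposition_oracle(self):
        _, pat = self._scene()
        model = _three_type_model()
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 3))
        a = (a + a.T) / 2
        g = rng.normal(size=(3, 3)) * 0.5
        g = (g + g.T) / 2
        fitted = fitted_from_params(model, Parameters(
            beta0=np.zeros(3), alpha=a, gamma=g))
        labels, mag = top_contributor_map(fitted, pat, "tumor", grid=(6, 6))
        xs, ys = mag.pixel_centers()
        for r, y in enumerate(ys):
            for c, x in enumerate(xs):
                contrib = contribution_decomposition(
                    (x, y), "tumor", pat, model, fitted.params)
                contrib.pop("tumor")
                best = max(contrib, key=lambda k: abs(contrib[k]))
                assert labels[r, c] == best
                assert mag.values[r, c] == pytest.approx(contrib[best],
                                                         abs=1e-10)


class TestModelAuc:
    def test_constant_intensity_model_scores_exactly_half(self):
        rng = np.random.default_rng(0)
        w = Window(0, 100, 0, 100)
        pat = MultitypePointPattern(rng.uniform(0, 100, (30, 2)),
                                    ["A"] * 30, w)
        model = ModelSpec(type_set=["A"])
        fitted = fitted_from_params(model, Parameters(
            beta0=[-3.0], alpha=[[0.0]], gamma=[[0.0]]))
        assert model_auc(fitted, pat, "A", n_reference=500, seed=1) == 0.5

    def test_hand_computed_four_pair_example(self):
        # pairs (3>1), (3>2.5), (2>1), (2<2.5) -> 3/4
        assert mann_whitney_auc([3.0, 2.0], [1.0, 2.5]) == 0.75

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        base = mann_whitney_auc(pos, neg)
        assert mann_whitney_auc(np.exp(pos), np.exp(neg)) == base
        assert mann_whitney_auc(3 * pos - 7, 3 * neg - 7) == base

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_clustering_model_discriminates_on_its_own_pattern(self):
        """A model with true within-type attraction scores its own
        clustered realization well above chance."""
        from mgpp import SamplerConfig, mh_sample
        w = Window(0, 500, 0, 500)
        model = ModelSpec(type_set=["A"], saturation=2)
        params = Parameters(beta0=[np.log(2e-4)], alpha=[[1.2]],
                            gamma=[[0.0]])
        pat = mh_sample(model, params, None, w,
                        SamplerConfig(n_steps=2000, burn_in=4000, seed=3))
        fitted = fitted_from_params(model, params)
        auc = model_auc(fitted, pat, "A", n_reference=2000, seed=0)
        assert auc > 0.6

    def test_missing_type_is_error(self):
        w = Window(0, 100, 0, 100)
        pat = MultitypePointPattern([[1, 1]], ["A"], w, type_set=["A", "B"])
        model = ModelSpec(type_set=["A", "B"])
        fitted = fitted_from_params(model, Parameters.zeros(2))
        with pytest.raises(ValueError):
            model_auc(fitted, pat, "B", n_reference=100)


class TestAucAbundanceCorrelation:
    def _tables(self, aucs, counts):
        ids = [f"i{k}" for k in range(len(aucs))]
        auc_t = pd.DataFrame({"image_id": ids, "type": "A", "auc": aucs})
        ab_t = pd.DataFrame({"image_id": ids, "type": "A", "count": counts})
        return auc_t, ab_t

    def test_perfectly_increasing_is_plus_one(self):
        out = auc_abundance_correlation(
            *self._tables([0.5, 0.6, 0.7, 0.8], [10, 20, 30, 40]))
        assert out["A"] == pytest.approx(1.0)

    def test_constant_auc_is_missing(self):
        out = auc_abundance_correlation(
            *self._tables([0.5, 0.5, 0.5], [10, 20, 30]))
        assert np.isnan(out["A"])

    def test_matches_textbook_pearson(self):
        aucs = [0.5, 0.8, 0.6, 0.9]
        counts = [12, 40, 25, 33]
        out = auc_abundance_correlation(*self._tables(aucs, counts))
        a, c = np.asarray(aucs), np.asarray(counts)
        want = (((a - a.mean()) * (c - c.mean())).sum()
                / np.sqrt(((a - a.mean()) ** 2).sum()
                          * ((c - c.mean()) ** 2).sum()))
        assert out["A"] == pytest.approx(want)

    def test_fewer_than_three_pairs_is_missing(self):
        out = auc_abundance_correlation(*self._tables([0.5, 0.9], [10, 20]))
        assert np.isnan(out["A"])
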