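"""Neuron selection, specificity/generalization, RSA, and balance scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specgen import synth, tuning


def _table_from_category_means(means_per_neuron, design):
    """Build a RecordingTable whose per-category means are exactly given."""
    cats = design.table()["category"].to_numpy()
    cat_list = list(design.categories)
    resp = np.zeros((len(means_per_neuron), design.n_conditions))
    for n, means in enumerate(means_per_neuron):
        for c, m in zip(cat_list, means):
            resp[n, cats == c] = m
    return synth.RecordingTable(resp, design)


@pytest.fixture(scope="module")
def three_cat_design():
    return synth.make_stimulus_design(
        categories=("a", "b", "c"), exemplars_per_category=(3, 3, 3), n_views=4, n_spiky=0
    )


class TestSelection:
    def test_boundary_neuron_selected(self, three_cat_design):
        # mean exactly twice the max of the others counts as selected
        rec = _table_from_category_means([(1.0, 0.5, 0.4)] * 7, three_cat_design)
        sel = tuning.select_category_responsive(rec, threshold=2.0, min_neurons=5)
        assert list(sel) == ["a"]
        assert len(sel["a"]) == 7

    def test_sub_threshold_neuron_not_selected(self, three_cat_design):
        rec = _table_from_category_means([(1.0, 0.6, 0.1)] * 7, three_cat_design)
        assert tuning.select_category_responsive(rec) == {}

    def test_exactly_five_qualifying_neurons_dropped(self, three_cat_design):
        # the count must be strictly greater than min_neurons
        means = [(1.0, 0.4, 0.4)] * 5 + [(0.5, 0.6, 0.4)] * 4
        rec = _table_from_category_means(means, three_cat_design)
        assert tuning.select_category_responsive(rec, min_neurons=5) == {}
        assert "a" in tuning.select_category_responsive(rec, min_neurons=4)

    def test_single_category_rejected(self):
        design = synth.make_stimulus_design(
            categories=("a",), exemplars_per_category=(3,), n_views=4, n_spiky=0
        )
        rec = _table_from_category_means([(1.0,)] * 6, design)
        with pytest.raises(ValueError):
            tuning.select_category_responsive(rec)

    @pytest.mark.parametrize("spiky_mean, nonspiky_mean, expected", [(0.9, 0.4, True), (0.9, 0.5, False)])
    def test_feature_selection_threshold(self, spiky_mean, nonspiky_mean, expected, small_design):
        flags = small_design.table()["spiky"].to_numpy().astype(bool)
        resp = np.where(flags, spiky_mean, nonspiky_mean)[None, :].repeat(3, axis=0)
        rec = synth.RecordingTable(resp, small_design)
        sel = tuning.select_feature_responsive(rec, "spiky", 2.0)
        assert (len(sel) == 3) is expected

    def test_noiseless_spiky_generator_all_selected(self, full_design):
        spec = synth.PopulationSpec(
            n_neurons=40, gain_ratio=1.5, spiky_fraction=0.5, spiky_gain=3.0, seed=1
        )
        rec = synth.generate_population(spec, full_design)
        assert len(tuning.select_feature_responsive(rec)) == 20


class TestSpecificityScore:
    def test_flat_ratio(self, three_cat_design):
        rec = _table_from_category_means([(1.0, 0.5, 0.3)] * 6, three_cat_design)
        score = tuning.specificity_score(rec, np.arange(6), "a", n_repeats=5, seed=0)
        assert score == pytest.approx(2.0)

    def test_equal_means_give_one(self, three_cat_design):
        rec = _table_from_category_means([(0.7, 0.7, 0.7)] * 6, three_cat_design)
        assert tuning.specificity_score(rec, np.arange(6), "a", seed=0) == pytest.approx(1.0)

    def test_recovers_generator_gain(self, full_design):
        spec = synth.PopulationSpec(n_neurons=50, gain_ratio=3.0, preferred_category="animal", seed=0)
        rec = synth.generate_population(spec, full_design)
        sel = tuning.select_category_responsive(rec)
        score = tuning.specificity_score(rec, sel["animal"], "animal", n_repeats=20, seed=0)
        assert score == pytest.approx(3.0, abs=0.15)

    def test_empty_neuron_set_rejected(self, three_cat_design):
        rec = _table_from_category_means([(1.0, 0.5, 0.3)] * 6, three_cat_design)
        with pytest.raises(ValueError):
            tuning.specificity_score(rec, np.array([]), "a")


class TestGeneralization:
    def test_equal_exemplar_means_give_one(self, three_cat_design):
        rec = _table_from_category_means([(0.8, 0.2, 0.2)] * 6, three_cat_design)
        g = tuning.generalization_score(rec, np.arange(6), "a", "exemplar", n_repeats=3, seed=0)
        assert g == pytest.approx(1.0)

    def test_min_max_ratio_of_exemplar_means(self, three_cat_design):
        meta = three_cat_design.table()
        resp = np.zeros((4, three_cat_design.n_conditions))
        ex = meta["exemplar"].to_numpy()
        for e, v in zip((0, 1, 2), (0.2, 0.5, 0.8)):
            resp[:, ex == e] = v
        rec = synth.RecordingTable(resp, three_cat_design)
        g = tuning.generalization_score(rec, np.arange(4), "a", "exemplar", n_repeats=3, seed=0)
        assert g == pytest.approx(0.25)

    def test_view_level_equal_views_give_one(self, three_cat_design):
        rec = _table_from_category_means([(0.8, 0.2, 0.2)] * 6, three_cat_design)
        g = tuning.generalization_score(rec, np.arange(6), "a", "view", n_repeats=3, seed=0)
        assert g == pytest.approx(1.0)

    def test_decreases_with_exemplar_variability(self, full_design):
        """Higher exemplar variability strictly lowers the generalization
        ratio (Monte Carlo over seeds)."""
        per_seed = []
        for seed in range(5):
            scores = []
            for esd in (0.0, 0.2, 0.5):
                spec = synth.PopulationSpec(
                    n_neurons=50, gain_ratio=3.0, exemplar_sd=esd,
                    preferred_category="animal", seed=seed,
                )
                rec = synth.generate_population(spec, full_design)
                sel = tuning.select_category_responsive(rec)
                scores.append(
                    tuning.generalization_score(
                        rec, sel["animal"], "animal", "exemplar", n_repeats=10, seed=seed
                    )
                )
            per_seed.append(scores[0] > scores[1] > scores[2])
        assert all(per_seed)

    def test_sd_zero_for_equal_means(self, three_cat_design):
        rec = _table_from_category_means([(0.8, 0.2, 0.2)] * 6, three_cat_design)
        assert tuning.generalization_sd(rec, np.arange(6), "a") == pytest.approx(0.0)

    def test_sd_population_convention(self, three_cat_design):
        meta = three_cat_design.table()
        resp = np.zeros((2, three_cat_design.n_conditions))
        ex = meta["exemplar"].to_numpy()
        resp[:, ex == 0] = 0.0
        resp[:, ex == 1] = 1.0
        resp[:, ex == 2] = 1.0
        # drop exemplar 2 by using a 2-exemplar category instead
        design2 = synth.make_stimulus_design(
            categories=("a", "b"), exemplars_per_category=(2, 2), n_views=4, n_spiky=0
        )
        meta2 = design2.table()
        resp2 = np.zeros((2, design2.n_conditions))
        resp2[:, meta2["exemplar"].to_numpy() == 1] = 1.0
        rec2 = synth.RecordingTable(resp2, design2)
        assert tuning.generalization_sd(rec2, np.arange(2), "a") == pytest.approx(0.5)

    def test_sd_anticorrelates_with_ratio(self, full_design):
        """Across an exemplar-variability grid the SD index orders regions
        exactly opposite to the min/max ratio (rank correlation -1)."""
        from scipy.stats import spearmanr

        ratios, sds = [], []
        for esd in (0.0, 0.2, 0.5):
            spec = synth.PopulationSpec(
                n_neurons=50, gain_ratio=3.0, exemplar_sd=esd,
                preferred_category="animal", seed=11,
            )
            rec = synth.generate_population(spec, full_design)
            ids = np.arange(rec.n_neurons)
            ratios.append(
                tuning.generalization_score(rec, ids, "animal", "exemplar", n_repeats=10, seed=1)
            )
            sds.append(tuning.generalization_sd(rec, ids, "animal"))
        assert spearmanr(ratios, sds).statistic == pytest.approx(-1.0)


class TestRsm:
    def test_duplicated_columns_correlate_perfectly(self, rng):
        x = rng.normal(size=(50, 1))
        r = tuning.rsm(np.hstack([x, x]))
        assert r[0, 1] == pytest.approx(1.0)

    def test_negated_column(self, rng):
        x = rng.normal(size=(50, 1))
        r = tuning.rsm(np.hstack([x, -x]))
        assert r[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        x = rng.normal(size=(1000, 12))
        r = tuning.rsm(x)
        off = r[np.triu_indices(12, 1)]
        assert np.mean(np.abs(off)) < 0.1

    def test_symmetric_unit_diagonal(self, rng):
        x = rng.normal(size=(30, 8))
        r = tuning.rsm(x)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_global_affine_rescaling_invariance(self, rng):
        x = rng.normal(size=(30, 8))
        np.testing.assert_allclose(tuning.rsm(x), tuning.rsm(2.5 * x - 7.0), atol=1e-9)

    def test_constant_column_reported_missing(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 5.0
        r = tuning.rsm(x)
        assert np.isnan(r[1, :]).all() and np.isnan(r[:, 1]).all()
        assert r[0, 0] == 1.0


class TestRsaScores:
    def test_identical_responses_to_everything(self, three_cat_design, rng):
        base = rng.uniform(1, 2, size=(20, 1))
        resp = np.repeat(base, three_cat_design.n_conditions, axis=1)
        rec = synth.RecordingTable(resp, three_cat_design)
        scores = tuning.rsa_scores(rec, np.arange(20), "a", n_repeats=3, seed=0)
        assert scores.between_category_similarity == pytest.approx(1.0)
        assert scores.within_exemplar_similarity == pytest.approx(1.0)
        assert scores.within_view_similarity == pytest.approx(1.0)

    def test_independent_category_patterns_decorrelated(self, three_cat_design, rng):
        # each category drives an independent random population pattern
        cats = three_cat_design.table()["category"].to_numpy()
        resp = np.zeros((200, three_cat_design.n_conditions))
        for c in ("a", "b", "c"):
            resp[:, cats == c] = rng.normal(size=(200, 1)) + 3.0
        rec = synth.RecordingTable(
            np.clip(resp + rng.normal(0, 0.02, resp.shape), 0, None), three_cat_design
        )
        scores = tuning.rsa_scores(rec, np.arange(200), "a", n_repeats=5, seed=0)
        assert abs(scores.between_category_similarity) < 0.15

    def test_shared_latent_raises_within_category_similarity(self, full_design):
        vals = {}
        for w in (0.1, 0.8):
            spec = synth.PopulationSpec(
                n_neurons=100, gain_ratio=3.0, exemplar_sd=0.15, view_sd=0.1,
                noise_sd=0.2, shared_factor_weight=w, preferred_category="animal", seed=4,
            )
            rec = synth.generate_population(spec, full_design)
            vals[w] = tuning.rsa_scores(
                rec, np.arange(100), "animal", n_repeats=5, seed=0
            ).within_exemplar_similarity
        assert vals[0.8] > vals[0.1]


class TestThresholdSensitivity:
    def test_single_threshold_matches_direct_calls(self, full_design):
        spec = synth.PopulationSpec(n_neurons=40, gain_ratio=3.0, preferred_category="animal", seed=2)
        rec = synth.generate_population(spec, full_design)
        table = tuning.threshold_sensitivity(rec, [2.0], n_repeats=5, seed=3)
        sel = tuning.select_category_responsive(rec, 2.0)
        direct = tuning.specificity_score(rec, sel["animal"], "animal", n_repeats=5, seed=3)
        assert table.loc[0, "specificity"] == pytest.approx(direct)

    def test_selected_sets_shrink_with_threshold(self, full_design):
        spec = synth.PopulationSpec(
            n_neurons=60, gain_ratio=3.0, noise_sd=0.3, preferred_category="animal", seed=5
        )
        rec = synth.generate_population(spec, full_design)
        sizes = [
            len(tuning.select_category_responsive(rec, t, min_neurons=0).get("animal", []))
            for t in (1.5, 2.0, 3.0)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]
        # nesting, not just counts
        lo = set(tuning.select_category_responsive(rec, 2.0, min_neurons=0)["animal"])
        hi = set(tuning.select_category_responsive(rec, 3.0, min_neurons=0).get("animal", []))
        assert hi <= lo

    def test_region_ordering_preserved_across_thresholds(self, full_design):
        """A sparsely-interconnected table keeps higher specificity than a
        densely-interconnected one at every selection threshold."""
        recs = {}
        for name, w in (("sparse", 0.05), ("dense", 0.35)):
            spec = synth.PopulationSpec(
                n_neurons=80, gain_ratio=3.0, exemplar_sd=0.1, view_sd=0.1,
                noise_sd=0.2, shared_factor_weight=w, preferred_category="animal", seed=6,
            )
            recs[name] = synth.generate_population(spec, full_design)
        tables = {
            name: tuning.threshold_sensitivity(
                rec, [1.2, 1.35, 1.5], min_neurons=0, n_repeats=5, seed=0
            )
            for name, rec in recs.items()
        }
        spec_sparse = tables["sparse"]["specificity"].to_numpy()
        spec_dense = tables["dense"]["specificity"].to_numpy()
        valid = ~(np.isnan(spec_sparse) | np.isnan(spec_dense))
        assert valid.any()
        assert np.all(spec_sparse[valid] > spec_dense[valid])

    def test_thresholds_must_exceed_one(self, full_design):
        spec = synth.PopulationSpec(n_neurons=10, seed=0)
        rec = synth.generate_population(spec, full_design)
        with pytest.raises(ValueError):
            tuning.threshold_sensitivity(rec, [0.9, 2.0])


class TestBalanceScore:
    def test_opposite_extremes(self):
        res = tuning.balance_score(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        np.testing.assert_allclose(res.balance, [1.0, 1.0])

    def test_condition_with_both_maxima_scores_two(self):
        res = tuning.balance_score(np.array([0.0, 1.0, 0.5]), np.array([0.2, 1.0, 0.2]))
        assert res.balance[1] == pytest.approx(2.0)

    def test_constant_array_rejected(self):
        with pytest.raises(ValueError):
            tuning.balance_score(np.array([1.0, 1.0]), np.array([0.0, 1.0]))

    @given(
        spec=st.lists(st.floats(0, 10), min_size=3, max_size=8),
        gen=st.lists(st.floats(0, 1), min_size=3, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization_bounds(self, spec, gen):
        n = min(len(spec), len(gen))
        s, g = np.asarray(spec[:n]), np.asarray(gen[:n])
        if s.max() == s.min() or g.max() == g.min():
            return
        res = tuning.balance_score(s, g)
        for arr in (res.normalized_specificity, res.normalized_generalization):
            assert arr.min() == pytest.approx(0.0)
            assert arr.max() == pytest.approx(1.0)
        assert np.all((res.balance >= 0) & (res.balance <= 2 + 1e-12))
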