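import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dubas_sdm import ensemble as ens
from dubas_sdm import sdm, synthdata
from dubas_sdm.geodata import RasterGrid, split_by_longitude

from conftest import make_occ


class TestTSS:
    def test_perfect_prediction_is_one(self):
        assert ens.tss(ens.ConfusionTable(10, 0, 0, 10)) == 1.0

    def test_no_skill_is_zero(self):
        assert ens.tss(ens.ConfusionTable(25, 25, 25, 25)) == 0.0

    def test_hand_computed_quotient(self):
        # (40*40 - 10*10) / (50 * 50) = 1500/2500
        assert ens.tss(ens.ConfusionTable(40, 10, 10, 40)) == pytest.approx(0.6)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ens.tss(ens.ConfusionTable(0, 5, 0, 5))

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(st.integers(1, 200), st.integers(0, 200),
                     st.integers(0, 200), st.integers(1, 200)))
    def test_quotient_equals_sens_plus_spec_minus_one(self, abcd):
        a, b, c, d = abcd
        ct = ens.ConfusionTable(a, b, c, d)
        assert ens.tss(ct) == pytest.approx(ct.sensitivity + ct.specificity - 1,
                                            abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert ens.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert ens.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_four_point_pairwise_count(self):
        # pos {0.9, 0.6}, neg {0.7, 0.2}: 3 of 4 pairs concordant
        assert ens.auc([0.9, 0.6, 0.7, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 1, 0
        a = ens.auc(scores, labels)
        b = ens.auc(np.exp(5 * scores) - 2, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ens.auc([0.1, 0.2], [1, 1])


class TestMaxSSThreshold:
    def test_perfect_separation_gives_perfect_rates(self):
        thr, rep = ens.max_ss_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(6, 40)
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr, rep = ens.max_ss_threshold(scores, labels)
            best = -np.inf
            for cand in np.unique(scores):
                ct = ens.confusion_at(scores, labels, cand)
                best = max(best, ct.sensitivity + ct.specificity)
            assert rep.sensitivity + rep.specificity == pytest.approx(best, abs=1e-12)

    def test_identical_scores_return_that_score(self):
        thr, rep = ens.max_ss_threshold([0.4] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert thr == 0.4
        assert rep.sensitivity + rep.specificity == pytest.approx(1.0)

    def test_tie_breaks_toward_lowest_threshold(self):
        # thresholds 0.2 and 0.8 both achieve the optimum here
        scores = np.array([0.8, 0.2, 0.8, 0.2])
        labels = np.array([1, 1, 0, 0])
        thr, _ = ens.max_ss_threshold(scores, labels)
        assert thr == 0.2


class TestClassification:
    @pytest.fixture
    def grid(self):
        rng = np.random.default_rng(2)
        return RasterGrid(rng.uniform(size=(6, 8)), np.zeros((6, 8), bool),
                          56.0, 23.0, 0.1)

    def test_all_above_threshold_is_all_high(self, grid):
        g = grid.copy_with(np.full(grid.shape, 0.9))
        classes, areas = ens.classify_suitability(g, 0.4)
        assert areas.set_index("class").loc["high", "percent"] == 100.0

    def test_interval_rule(self, grid):
        g = grid.copy_with(np.full(grid.shape, 0.3))
        g.values[0, 0] = 0.1
        classes, _ = ens.classify_suitability(g, 0.4, marginal_fraction=0.5)
        assert classes.values[0, 0] == ens.CLASS_UNSUITABLE
        assert classes.values[1, 1] == ens.CLASS_MARGINAL

    def test_areas_match_per_cell_oracle(self, grid):
        thr, mf = 0.6, 0.5
        classes, areas = ens.classify_suitability(grid, thr, mf)
        v = grid.values
        n_high = int((v >= thr).sum())
        n_marg = int(((v >= mf * thr) & (v < thr)).sum())
        n_uns = int((v < mf * thr).sum())
        t = areas.set_index("class")
        assert t.loc["high", "cells"] == n_high
        assert t.loc["marginal", "cells"] == n_marg
        assert t.loc["unsuitable", "cells"] == n_uns
        assert t.cells.sum() == v.size


class TestEnsemble:
    def test_two_members_equal_weight_average(self):
        a = np.full((2, 2), 0.2)
        b = np.full((2, 2), 0.6)
        out = ens.combine_members(np.stack([a, b]), [0.5, 0.5], "tss_weighted")
        np.testing.assert_allclose(out, 0.4)
        out = ens.combine_members(np.stack([a, b]), [0.5, 0.5], "median")
        np.testing.assert_allclose(out, 0.4)

    def test_identical_members_give_identical_consensus(self):
        a = np.random.default_rng(3).uniform(size=(3, 4))
        out = ens.combine_members(np.stack([a, a, a]), [0.2, 0.5, 0.9], "median")
        np.testing.assert_allclose(out, a)

    def test_run_ensemble_deterministic_and_bounded(self, small_stack, small_occ):
        kwargs = dict(models=("glm", "brt"), replicates=2, seed=5, n_background=200)
        r1 = ens.run_ensemble(small_stack, small_occ, **kwargs)
        r2 = ens.run_ensemble(small_stack, small_occ, **kwargs)
        np.testing.assert_array_equal(r1.consensus.values, r2.consensus.values)
        vals = np.stack([m.prediction.values for m in r1.members])
        ok = ~r1.consensus.nodata_mask
        assert (r1.consensus.values[ok] >= vals.min(axis=0)[ok] - 1e-12).all()
        assert (r1.consensus.values[ok] <= vals.max(axis=0)[ok] + 1e-12).all()

    def test_consensus_tracks_truth_at_least_as_well_as_average_member(
            self, small_stack, small_truth, small_occ):
        from scipy.stats import spearmanr

        res = ens.run_ensemble(small_stack, small_occ, replicates=2, seed=9,
                               n_background=300)
        ok = ~small_truth.nodata_mask
        tv = small_truth.values[ok]
        rho_c = spearmanr(tv, res.consensus.values[ok]).statistic
        rho_m = np.mean([spearmanr(tv, m.prediction.values[ok]).statistic
                         for m in res.members])
        assert rho_c >= rho_m
        assert rho_c > 0.8

    def test_too_few_presences_rejected(self, small_stack):
        occ = make_occ([56.5] * 5, [23.2] * 5)
        with pytest.raises(Exception, match="20"):
            ens.run_ensemble(small_stack, occ)


class TestEvaluation:
    def test_perfectly_separated_grid_gives_auc_and_tss_one(self):
        geom = RasterGrid(np.zeros((10, 10)), np.zeros((10, 10), bool),
                          56.0, 23.0, 0.1)
        v = np.zeros((10, 10))
        v[:, 5:] = 1.0
        grid = geom.copy_with(v)
        test = make_occ([56.85, 56.95, 56.75], [23.5, 23.4, 23.3])
        bg = np.column_stack([np.full(20, 56.25), np.linspace(23.05, 23.95, 20)])
        rep = ens.evaluate_on_split(grid, test, bg)
        assert rep.auc == 1.0
        assert rep.tss == pytest.approx(1.0)

    def test_random_labels_give_half_auc(self):
        rng = np.random.default_rng(11)
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            scores = r.uniform(size=1000)
            labels = r.integers(0, 2, 1000)
            labels[:2] = [0, 1]
            aucs.append(ens.auc(scores, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_all_test_points_masked_is_error(self):
        geom = RasterGrid(np.full((4, 4), np.nan), np.ones((4, 4), bool),
                          56.0, 23.0, 0.1)
        test = make_occ([56.2], [23.2])
        with pytest.raises(ValueError):
            ens.evaluate_on_split(geom, test, [(56.1, 23.1)])
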