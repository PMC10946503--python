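"""Block CV design, holdouts, performance metrics and threshold choice."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from guildshift import validation
from guildshift.habitat import HabitatModel


def _white_noise_fields(rng, ny=24, nx=24):
    ds = xr.Dataset(
        {"a": (("year", "y", "x"), rng.normal(size=(1, ny, nx))),
         "b": (("year", "y", "x"), rng.normal(size=(1, ny, nx)))},
        coords={"year": [2000], "y": np.arange(ny), "x": np.arange(nx)})
    ds.attrs["cell_km"] = 10.0
    return ds


class TestBuildBlocks:
    def test_white_noise_gives_single_cell_blocks(self, rng):
        design = validation.build_blocks(_white_noise_fields(rng), seed=0)
        assert design.block_edge_cells == 1

    def test_folds_partition_all_cells(self, small_fields):
        design = validation.build_blocks(small_fields, seed=1)
        folds = np.unique(design.fold_of_cell)
        assert set(folds) == set(range(1, 9))
        assert design.fold_of_cell.shape == (20, 20)

    def test_same_seed_identical_design(self, small_fields):
        a = validation.build_blocks(small_fields, seed=5)
        b = validation.build_blocks(small_fields, seed=5)
        assert np.array_equal(a.fold_of_cell, b.fold_of_cell)
        c = validation.build_blocks(small_fields, seed=6)
        assert not np.array_equal(a.fold_of_cell, c.fold_of_cell)


def _toy_model(rng, n=400, ny=20, nx=20, separable=True):
    """Presence driven by one predictor, placed at random cells."""
    X = pd.DataFrame({"t": rng.normal(size=n), "junk": rng.normal(size=n)})
    if separable:
        p = 1 / (1 + np.exp(-6 * X["t"]))
    else:
        p = np.full(n, 0.4)
    y = rng.random(n) < p
    meta = pd.DataFrame({"y": rng.integers(0, ny, n), "x": rng.integers(0, nx, n),
                         "year": rng.integers(2000, 2020, n)})
    return HabitatModel(y.astype(int), X, meta=meta, min_presences=1)


class TestSpatialCV:
    def test_each_observation_predicted_once_by_foreign_fold(self, rng):
        model = _toy_model(rng)
        design = validation.build_blocks(_white_noise_fields(rng), seed=0)
        pooled = validation.spatial_cv(model, design, random_state=0)
        assert sorted(pooled["row"]) == list(range(len(model.presence)))
        # the fold tag of each prediction matches the cell's own fold,
        # i.e. the model that predicted it excluded that fold from training
        folds = design.fold_for(model.meta["y"], model.meta["x"])
        assert (pooled.sort_values("row")["fold"].to_numpy()
                == folds[np.argsort(pooled["row"].to_numpy(), kind="stable")
                         ][np.arange(len(folds))]).all() or \
               (pooled.set_index("row")["fold"].sort_index().to_numpy() == folds).all()

    def test_separable_data_recovers_high_auc(self, rng):
        model = _toy_model(rng, n=600)
        design = validation.build_blocks(_white_noise_fields(rng), seed=1)
        pooled = validation.spatial_cv(model, design, random_state=1)
        assert validation.roc_auc(pooled["obs"], pooled["pred"]) >= 0.9


class TestTemporalHoldout:
    def _model_with_years(self, rng, years, presence_years):
        n = len(years)
        X = pd.DataFrame({"t": rng.normal(size=n)})
        y = np.array([1 if yr in presence_years else 0 for yr in years])
        # ensure enough 1s pre-split for training
        meta = pd.DataFrame({"y": np.zeros(n, int), "x": np.zeros(n, int), "year": years})
        return HabitatModel(y, X, meta=meta, min_presences=1)

    def test_split_stays_when_enough_validation_presences(self, rng):
        years = np.r_[np.repeat(np.arange(2000, 2015), 10), np.repeat([2016, 2018], 30)]
        rng2 = np.random.default_rng(0)
        y = (rng2.random(len(years)) < 0.4).astype(int)
        model = HabitatModel(y, pd.DataFrame({"t": rng.normal(size=len(years))}),
                             meta=pd.DataFrame({"year": years}), min_presences=1)
        _, split = validation.temporal_holdout(model, split_year=2015)
        assert split == 2015

    def test_split_lowered_to_reach_presences(self, rng):
        # two presences per year, only in 2010-2014: accumulating the ten
        # required validation presences forces the split down to 2010
        years = np.repeat(np.arange(2000, 2015), 20)
        y = np.zeros(len(years), int)
        for yr in range(2010, 2015):
            y[np.flatnonzero(years == yr)[:2]] = 1
        y[:3] = 1  # early presences so training keeps both classes
        model = HabitatModel(y, pd.DataFrame({"t": rng.normal(size=len(years))}),
                             meta=pd.DataFrame({"year": years}), min_presences=1)
        _, split = validation.temporal_holdout(model, split_year=2015)
        assert split == 2010

    def test_untestable_when_no_split_works(self, rng):
        years = np.repeat(np.arange(2000, 2005), 4)
        y = np.zeros(len(years), int)
        y[0] = 1  # a single presence can never satisfy the rule
        model = HabitatModel(y, pd.DataFrame({"t": rng.normal(size=len(years))}),
                             meta=pd.DataFrame({"year": years}), min_presences=1)
        with pytest.raises(validation.UntestableTemporalSplit):
            validation.temporal_holdout(model, split_year=2015)


class TestROCAUC:
    def test_perfect_separation_is_one(self):
        assert validation.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        assert abs(validation.roc_auc(y, s) - 0.5) < 0.03

    def test_equals_ordered_pair_fraction(self, rng):
        """Mann-Whitney normalisation equals the exhaustive fraction of
        correctly ordered presence/absence pairs (ties half) for n<=50."""
        for _ in range(20):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            pos, neg = s[y == 1], s[y == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                     for a in pos for b in neg]
            assert validation.roc_auc(y, s) == pytest.approx(np.mean(pairs))

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        a = validation.roc_auc(y, s)
        b = validation.roc_auc(y, np.exp(5 * s))
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            validation.roc_auc([1, 1], [0.5, 0.6])


class TestPRAUC:
    def test_perfect_separation_near_one(self):
        assert validation.pr_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) > 0.99

    def test_bounded_in_unit_interval(self, rng):
        y = rng.integers(0, 2, 300)
        s = rng.random(300)
        assert 0.0 <= validation.pr_auc(y, s) <= 1.0


class TestMillerSlope:
    def test_calibrated_predictions_slope_near_one(self, rng):
        p = rng.uniform(0.02, 0.98, 5000)
        y = rng.random(5000) < p
        slope = validation.miller_slope(y.astype(int), p)
        assert 0.9 <= slope <= 1.1

    def test_overconfident_predictions_halve_slope(self, rng):
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < p).astype(int)
        logit = np.log(p / (1 - p))
        over = 1 / (1 + np.exp(-2 * logit))
        slope = validation.miller_slope(y, over)
        assert slope == pytest.approx(0.5, abs=0.1)

    def test_row_order_invariance(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(int)
        a = validation.miller_slope(y, p)
        idx = rng.permutation(500)
        b = validation.miller_slope(y[idx], p[idx])
        assert a == pytest.approx(b, rel=1e-9)


class TestThreshold:
    def test_separated_example(self):
        y = [1, 1, 0, 0]
        p = [0.9, 0.9, 0.1, 0.1]
        assert validation.choose_threshold(y, p) == pytest.approx(0.9)

    def test_matches_bruteforce_scan(self, rng):
        """Maximiser over observed values + {0,1} equals an exhaustive scan
        over the same candidate set for n<=100."""
        for _ in range(20):
            n = int(rng.integers(10, 101))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)
            got = validation.choose_threshold(y, p)
            cands = np.unique(np.r_[p, 0.0, 1.0])
            scores = [( (p[y == 1] >= t).mean() + (p[y == 0] < t).mean(), -t)
                      for t in cands]
            best = max(scores)
            assert (p[y == 1] >= got).mean() + (p[y == 0] < got).mean() \
                == pytest.approx(best[0])
            assert got == pytest.approx(-max(s for s in scores if
                                             abs(s[0] - best[0]) < 1e-12)[1])

    def test_duplication_invariance(self, rng):
        y = rng.integers(0, 2, 50)
        y[:5], y[5:10] = 1, 0
        p = rng.random(50)
        a = validation.choose_threshold(y, p)
        b = validation.choose_threshold(np.r_[y, y], np.r_[p, p])
        assert a == pytest.approx(b)


class TestValidationReport:
    @pytest.mark.parametrize("s,t,expected", [
        (0.7, 0.7, True), (0.65, 0.65, True), (0.64, 0.9, False),
        (0.9, 0.6, False)])
    def test_pass_flag_is_dual_auc_gate(self, s, t, expected):
        rep = validation.ValidationReport(s, 0.5, 1.0, t, 0.5, 1.0, 2015)
        assert rep.passed is expected

    def test_untestable_never_passes(self):
        rep = validation.ValidationReport(0.9, 0.5, 1.0, float("nan"), float("nan"),
                                          float("nan"), None, temporal_untestable=True)
        assert rep.passed is False
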