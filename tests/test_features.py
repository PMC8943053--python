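"""Per-well feature summaries and the feature-matrix pipeline."""

import numpy as np
import pandas as pd
import pytest

from plateworm.features import (FeatureTable, cluster_fingerprints,
                                concatenate_periods, kw_by_significance,
                                kw_exact_p_two_groups, lmm_screen, pca_project,
                                qc_impute_normalize, summarize_features,
                                track_features)
from plateworm.synthetic import (PlateConfig, make_feature_table, make_screen_table)
from plateworm.tracking import PutativeObject, Track
from plateworm.wells import mark_bad_well


def straight_worm_track(length=80.0, n_frames=30, x0=100.0, y0=100.0, n_pts=9):
    objs = []
    xs = np.linspace(x0 - length / 2, x0 + length / 2, n_pts)
    ml = np.stack([xs, np.full(n_pts, y0)], axis=1)[::-1]  # head first
    for f in range(n_frames):
        objs.append(PutativeObject(f, (x0, y0), int(length * 7), (0, 0, 1, 1),
                                   np.ones((1, 1), bool), midline=ml.copy()))
    t = Track(0, objs)
    t.modes = ["st"] * n_frames
    return t


class TestSummarize:
    def test_straight_static_worm_length_and_speed(self):
        t = straight_worm_track(length=80.0)
        feats = track_features(t, frame_rate=25.0)
        assert feats["length"] == pytest.approx(80.0, abs=2.0)
        assert feats["speed"] == pytest.approx(0.0, abs=1e-9)
        assert feats["frac_st"] == 1.0 and feats["frac_fw"] == 0.0

    def test_averaging_idempotence(self):
        grid = PlateConfig().truth_grid()
        t1 = straight_worm_track()
        t1.well = "A1"
        t2 = straight_worm_track()
        t2.well = "A1"
        one = summarize_features([t1], grid, 25.0)
        two = summarize_features([t1, t2], grid, 25.0)
        pd.testing.assert_frame_equal(one.values, two.values)

    def test_bad_well_row_emitted_with_flag(self):
        grid = mark_bad_well(PlateConfig().truth_grid(), "A1", "liquid")
        t = straight_worm_track()
        t.well = "A1"
        table = summarize_features([t], grid, 25.0)
        assert bool(table.row_meta.loc["A1", "bad_well"]) is True
        assert not table.values.loc["A1"].isna().all()

    def test_empty_well_is_all_missing(self):
        grid = PlateConfig().truth_grid()
        table = summarize_features([], grid, 25.0)
        assert table.values.isna().all().all()
        assert table.mask.all().all()


class TestConcatenatePeriods:
    def _table(self, n_wells, n_feats, period):
        idx = pd.Index([f"w{i}" for i in range(n_wells)], name="well_name")
        cols = [f"f{j}" for j in range(n_feats)]
        v = pd.DataFrame(np.zeros((n_wells, n_feats)), index=idx, columns=cols)
        return FeatureTable(v, v.isna(), pd.DataFrame({"bad_well": False}, index=idx),
                            pd.DataFrame({"period": period, "base_feature": cols},
                                         index=cols))

    @pytest.mark.parametrize("width,total", [(3076, 9228), (256, 768)])
    def test_three_period_width_contract(self, width, total):
        tables = {p: self._table(2, width, p)
                  for p in ("prestim", "bluelight", "poststim")}
        combined = concatenate_periods(tables)
        assert combined.shape == (2, total)
        assert combined.values.columns.is_unique

    def test_well_mismatch_rejected(self):
        t1 = self._table(3, 4, "prestim")
        t2 = self._table(2, 4, "bluelight")
        with pytest.raises(ValueError, match="same wells"):
            concatenate_periods({"prestim": t1, "bluelight": t2})

    def test_empty_period_rejected(self):
        t1 = self._table(2, 4, "prestim")
        empty = self._table(2, 4, "bluelight")
        empty.values = empty.values.iloc[:, :0]
        empty.mask = empty.mask.iloc[:, :0]
        with pytest.raises(ValueError, match="empty"):
            concatenate_periods({"prestim": t1, "bluelight": empty})


def _table_from_values(values, interval=None):
    idx = pd.Index([f"s{i}" for i in range(len(values))], name="well_id")
    cols = [f"f{j}" for j in range(values.shape[1])]
    v = pd.DataFrame(values, index=idx, columns=cols)
    meta = pd.DataFrame({"bad_well": False}, index=idx)
    if interval is not None:
        meta["interval"] = interval
    return FeatureTable(v, v.isna(), meta,
                        pd.DataFrame({"period": "prestim", "base_feature": cols},
                                     index=cols))


class TestQcImputeNormalize:
    def test_sample_drop_above_40_percent(self):
        vals = np.random.default_rng(0).normal(size=(10, 10))
        vals[0, :5] = np.nan  # 50% missing
        clean, report = qc_impute_normalize(_table_from_values(vals))
        assert report.dropped_samples == ["s0"]
        assert clean.values.shape[0] == 9

    def test_feature_drop_above_20_percent_within_interval(self):
        vals = np.random.default_rng(1).normal(size=(10, 5))
        vals[:3, 0] = np.nan  # 30% of samples in the single interval
        clean, report = qc_impute_normalize(_table_from_values(vals))
        assert report.dropped_features == ["f0"]

    def test_imputation_uses_within_interval_mean(self):
        rng = np.random.default_rng(7)
        vals = np.hstack([
            np.array([[1.0], [3.0], [np.nan], [7.0], [9.0], [np.nan]]),
            rng.normal(size=(6, 4)),
        ])
        table = _table_from_values(vals, interval=["a"] * 3 + ["b"] * 3)
        # 1/3 missing > 20%: use a laxer feature threshold to reach imputation
        clean, _ = qc_impute_normalize(table, feature_miss_max=0.5, interval="interval")
        # the missing entries are filled by their interval means (2 and 8)
        imputed = np.array([1, 3, 2, 7, 9, 8], dtype=float)
        z = (imputed - imputed.mean()) / imputed.std()
        assert np.allclose(clean.values["f0"].to_numpy(), z)

    def test_no_missing_values_only_rescaled(self):
        vals = np.random.default_rng(2).normal(size=(8, 6)) * 5 + 3
        clean, report = qc_impute_normalize(_table_from_values(vals))
        assert not report.dropped_samples and not report.dropped_features
        got = clean.values.to_numpy()
        assert np.allclose(got.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(got.std(axis=0), 1.0, atol=1e-6)
        # z-scaling preserves ordering within each feature
        assert np.array_equal(np.argsort(got, axis=0), np.argsort(vals, axis=0))

    def test_row_order_invariance(self):
        vals = np.random.default_rng(3).normal(size=(12, 7))
        vals[vals > 1.5] = np.nan
        t = _table_from_values(vals)
        clean1, _ = qc_impute_normalize(t)
        perm = np.random.default_rng(4).permutation(12)
        t2 = FeatureTable(t.values.iloc[perm], t.mask.iloc[perm],
                          t.row_meta.iloc[perm], t.col_meta)
        clean2, _ = qc_impute_normalize(t2)
        pd.testing.assert_frame_equal(clean1.values,
                                      clean2.values.loc[clean1.values.index])


class TestPca:
    def test_single_varying_feature_explains_everything(self):
        vals = np.zeros((10, 5))
        vals[:, 2] = np.arange(10)
        vals += np.random.default_rng(0).normal(0, 1e-12, vals.shape)
        df = pd.DataFrame(vals, columns=list("abcde"))
        _, evr, _ = pca_project(df, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_two_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (20, 10))
        b = rng.normal(0, 1, (20, 10))
        a[:, 0] += 8
        df = pd.DataFrame(np.vstack([a, b]))
        df.columns = [str(c) for c in df.columns]
        scores, _, _ = pca_project(df, 2)
        labels = np.array([0] * 20 + [1] * 20)
        assert silhouette_score(scores[["PC1"]], labels) > 0.5

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(8, 5)),
                          columns=[f"f{j}" for j in range(5)])
        scores, _, pca = pca_project(df, 5)
        recon = scores.to_numpy() @ pca.components_ + pca.mean_
        assert np.abs(recon - df.to_numpy()).max() < 1e-9

    def test_k_beyond_rank_rejected(self):
        df = pd.DataFrame(np.ones((6, 4)), columns=list("abcd"))
        df["a"] = np.arange(6)
        with pytest.raises(ValueError, match="rank"):
            pca_project(df, 3)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(15, 6)),
                          columns=[f"f{j}" for j in range(6)])
        _, _, pca = pca_project(df, 3)
        for comp in pca.components_:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestKwBy:
    def test_by_adjustment_matches_stepup_hand_computation(self):
        """BY on (0.001, 0.01, 0.04, 0.8), m=4: harmonic factor
        c(4) = 1 + 1/2 + 1/3 + 1/4 = 25/12; adjusted values follow the
        monotone step-up from the largest p."""
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.01, 0.04, 0.8])
        c4 = 25 / 12
        raw = 4 * c4 * p / np.array([1, 2, 3, 4])
        expected = np.minimum.accumulate(np.minimum(raw, 1.0)[::-1])[::-1]
        _, p_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_by")
        assert np.allclose(p_adj, expected)

    def test_constant_feature_gets_p_one(self):
        df = pd.DataFrame({"flat": np.ones(12), "varying": np.arange(12.0)})
        groups = ["a"] * 6 + ["b"] * 6
        res = kw_by_significance(df, groups)
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["varying", "p"] < 0.01

    def test_exact_permutation_matches_mannwhitney_oracle(self):
        """Dual route: exact KW permutation tail vs scipy's exact
        Mann-Whitney two-sided p (equivalent statistics for 2 groups)."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(5)
        for shift in (0.0, 1.0, 5.0, 100.0):
            x = rng.normal(0, 1, 10)
            y = rng.normal(shift, 1, 10)
            p_kw = kw_exact_p_two_groups(x, y)
            p_mwu = mannwhitneyu(x, y, method="exact",
                                 alternative="two-sided").pvalue
            assert p_kw == pytest.approx(p_mwu, rel=0.10)

    def test_significant_set_under_real_effects(self):
        table, labels = make_feature_table(4, 15, 20, effect_size=2.0,
                                           missing_frac=0.0, seed=9)
        res = kw_by_significance(table.values, labels.to_numpy(), q=0.05)
        assert res["significant"].mean() > 0.5


class TestCluster:
    def test_duplicated_row_merges_first_at_zero_distance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 8))
        x[1] = x[0]
        df = pd.DataFrame(x, index=[f"r{i}" for i in range(5)],
                          columns=[f"c{j}" for j in range(8)])
        res = cluster_fingerprints(df)
        assert set(res.row_linkage[0, :2]) == {0.0, 1.0}
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_blocks_split_at_top(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=12)
        rows = [base + rng.normal(0, 0.1, 12) for _ in range(4)]
        rows += [-base + rng.normal(0, 0.1, 12) for _ in range(4)]
        df = pd.DataFrame(rows, index=[f"r{i}" for i in range(8)],
                          columns=[f"c{j}" for j in range(12)])
        res = cluster_fingerprints(df)
        # the root split separates the two blocks
        from scipy.cluster.hierarchy import fcluster
        two = fcluster(res.row_linkage, 2, criterion="maxclust")
        assert len(set(two[:4])) == 1 and len(set(two[4:])) == 1
        assert two[0] != two[4]

    def test_zero_variance_row_rejected_by_name(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(4, 6)),
                          index=["a", "b", "flatrow", "d"],
                          columns=[f"c{j}" for j in range(6)])
        df.loc["flatrow"] = 1.0
        with pytest.raises(ValueError, match="flatrow"):
            cluster_fingerprints(df)

    def test_leaf_order_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(10, 6)),
                          index=[f"r{i}" for i in range(10)],
                          columns=[f"c{j}" for j in range(6)])
        r1 = cluster_fingerprints(df)
        r2 = cluster_fingerprints(df)
        assert np.array_equal(r1.row_order, r2.row_order)
        assert np.array_equal(r1.col_order, r2.col_order)


class TestLmmScreen:
    def test_injected_effect_detected(self):
        table = make_screen_table(n_compounds=2, wells_per_compound=16,
                                  n_features=6, n_days=4, effect_size=3.0,
                                  day_sd=0.5, seed=0, n_hit_features=3)
        res = lmm_screen(table, q=0.05)
        assert res["hit"].all()
        assert (res["n_significant"] >= 3).all()

    def test_single_day_compound_unestimable(self):
        table = make_screen_table(n_compounds=1, wells_per_compound=12,
                                  n_features=4, n_days=3, effect_size=0.0,
                                  day_sd=0.5, seed=1)
        table.row_meta.loc[table.row_meta["compound"] == "cmpd_00", "day"] = "day_0"
        res = lmm_screen(table, q=0.05)
        assert not res.loc["cmpd_00", "estimable"]
        assert not res.loc["cmpd_00", "hit"]

    def test_missing_control_rejected(self):
        table = make_screen_table(1, 8, 3, 2, 0.0, 0.5, seed=2)
        with pytest.raises(ValueError, match="control"):
            lmm_screen(table, control="WATER")

    def test_day_variance_recovered_in_calibration_mean(self):
        """Average MixedLM day-variance estimate over replicates lands
        within 30% of the simulated variance (8 days x 12 wells)."""
        import warnings

        from statsmodels.regression.mixed_linear_model import MixedLM
        true_var = 1.0
        estimates = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            day_eff = rng.normal(0, np.sqrt(true_var), 8)
            days = np.repeat(np.arange(8), 12)
            y = day_eff[days] + rng.normal(0, 1, 96)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y, np.ones((96, 1)), groups=days).fit(reml=True)
            estimates.append(float(np.asarray(fit.cov_re)[0, 0]))
        assert np.mean(estimates) == pytest.approx(true_var, rel=0.30)


def test_pipeline_separates_strains_with_effect_size():
    """Between/within distance ratio grows with simulated effect size."""
    ratios = []
    for effect in (0.0, 0.8, 2.0):
        table, labels = make_feature_table(4, 10, 30, effect_size=effect,
                                           missing_frac=0.05, seed=3)
        clean, _ = qc_impute_normalize(table)
        x = clean.values.to_numpy()
        lab = labels.loc[clean.values.index].to_numpy()
        centroids = np.stack([x[lab == g].mean(axis=0) for g in np.unique(lab)])
        between = np.mean([np.linalg.norm(a - b)
                           for i, a in enumerate(centroids)
                           for b in centroids[i + 1:]])
        within = np.mean([np.linalg.norm(r - centroids[list(np.unique(lab)).index(g)])
                          for r, g in zip(x, lab)])
        ratios.append(between / within)
    assert ratios[0] < ratios[1] < ratios[2]
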