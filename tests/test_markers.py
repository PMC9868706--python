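"""Four-criterion chemomarker screen and its component statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemotyper import (MarkerThresholds, exclusive_markers, fold_change,
                        marker_table, marker_validation, rf_mda,
                        screen_markers, t_test, volcano_table)


def _stats_frame(vip, p, log2fc, mda):
    idx = [f"F{i}" for i in range(len(vip))]
    fc = pd.DataFrame({"fc": 2.0 ** np.asarray(log2fc),
                       "log2fc": log2fc}, index=idx)
    return (pd.Series(vip, index=idx), pd.Series(p, index=idx), fc,
            pd.Series(mda, index=idx))


class TestFoldChange:
    def test_identical_groups_unity(self):
        m = pd.DataFrame(np.ones((10, 3)), columns=list("abc"))
        out = fold_change(m, np.arange(10) < 5)
        assert np.allclose(out["fc"], 1.0)
        assert np.allclose(out["log2fc"], 0.0)

    def test_known_ratio(self):
        m = pd.DataFrame({"f": [4.0, 4.0, 2.0, 2.0]})
        out = fold_change(m, np.array([True, True, False, False]))
        assert out.loc["f", "fc"] == pytest.approx(2.0)
        assert out.loc["f", "log2fc"] == pytest.approx(1.0)

    def test_swap_inverts(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(1, 10, (12, 4)))
        mask = np.arange(12) < 5
        a = fold_change(m, mask)
        b = fold_change(m, ~mask)
        assert np.allclose(a["fc"], 1 / b["fc"])

    def test_empty_group_rejected(self):
        m = pd.DataFrame(np.ones((4, 1)))
        with pytest.raises(ValueError):
            fold_change(m, np.zeros(4, dtype=bool))


class TestTTest:
    def test_closed_form_strong_separation(self):
        """means 0 vs 3 at sd 1, n=30/30: the pooled t exceeds 11, so
        p < 1e-10 by the t distribution."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)
        Z = pd.DataFrame({"f": np.concatenate([a, b])})
        p = t_test(Z, np.arange(60) < 30)
        assert p["f"] < 1e-10
        # cross-check against the closed-form scipy value
        assert p["f"] == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue)

    def test_zero_variance_reports_one(self):
        Z = pd.DataFrame({"f": np.ones(10)})
        p = t_test(Z, np.arange(10) < 5)
        assert p["f"] == 1.0

    def test_null_p_uniform(self):
        """Permuting labels on null data yields approximately uniform p."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        ps = []
        for _ in range(300):
            mask = np.zeros(40, dtype=bool)
            mask[rng.choice(40, 20, replace=False)] = True
            ps.append(float(t_test(pd.DataFrame({"f": x}), mask)["f"]))
        ps = np.asarray(ps)
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert abs(np.mean(ps < 0.25) - 0.25) < 0.1


class TestRfMda:
    def test_label_copy_feature_tops_ranking(self):
        rng = np.random.default_rng(3)
        n = 80
        mask = np.arange(n) < 40
        X = pd.DataFrame(rng.standard_normal((n, 10)))
        X["label"] = mask.astype(float)
        mda = rf_mda(X, mask, n_trees=300, seed=0)
        assert mda.idxmax() == "label"
        assert mda["label"] >= 2.0

    def test_noise_features_centered_and_mostly_below_threshold(self):
        """Pure-noise features score near zero on average.  The SE-scaled
        z is overdispersed relative to N(0,1) — spurious finite-sample
        feature-label association is shared across trees, and R's
        randomForest scaled importance shows the same heavy tail — so
        only a clear majority, not ~95%, falls inside +/-2."""
        rng = np.random.default_rng(4)
        n = 60
        mask = np.arange(n) < 30
        vals = []
        for seed in range(10):
            X = pd.DataFrame(rng.standard_normal((n, 8)))
            vals.append(rf_mda(X, mask, n_trees=200, seed=seed).to_numpy())
        v = np.concatenate(vals)
        assert abs(v.mean()) < 0.5
        assert (np.abs(v) < 2.0).mean() >= 0.6

    def test_vector_length_matches_features(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((40, 7)))
        mda = rf_mda(X, np.arange(40) < 20, n_trees=100, seed=0)
        assert len(mda) == 7

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.standard_normal((40, 5)))
        mask = np.arange(40) < 20
        a = rf_mda(X, mask, n_trees=100, seed=3)
        b = rf_mda(X, mask, n_trees=100, seed=3)
        assert a.equals(b)


class TestScreenMarkers:
    def test_all_criteria_pass(self):
        vip, p, fc, mda = _stats_frame([3.0], [0.001], [1.2], [4.0])
        recs = screen_markers(vip, p, fc, mda, 1)
        assert recs[0].is_marker and recs[0].direction == "up"

    @pytest.mark.parametrize("vip,p,log2fc,mda,expect", [
        (1.9, 0.001, 1.2, 4.0, False),   # VIP below inclusive boundary
        (2.0, 0.001, 1.2, 4.0, True),    # VIP exactly at boundary passes
        (3.0, 0.05, 1.2, 4.0, False),    # p boundary is exclusive
        (3.0, 0.001, 0.5, 4.0, False),   # |log2FC| boundary exclusive
        (3.0, 0.001, -1.2, 4.0, True),   # down-regulated markers allowed
        (3.0, 0.001, 1.2, 1.99, False),  # MDA below threshold
    ])
    def test_boundaries(self, vip, p, log2fc, mda, expect):
        v, pp, fc, m = _stats_frame([vip], [p], [log2fc], [mda])
        rec = screen_markers(v, pp, fc, m, 1)[0]
        assert rec.is_marker is expect

    def test_joint_screen_equals_single_criterion_intersection(self):
        """Oracle identity: the four-criterion screen is exactly the
        intersection of the four single-criterion feature sets."""
        rng = np.random.default_rng(7)
        n = 400
        vip, p, fc, mda = _stats_frame(
            rng.uniform(0, 4, n), rng.uniform(0, 0.2, n),
            rng.uniform(-2, 2, n), rng.uniform(-1, 6, n))
        th = MarkerThresholds()
        recs = screen_markers(vip, p, fc, mda, 1, th)
        joint = {r.feature_id for r in recs if r.is_marker}
        brute = (set(vip.index[vip >= th.vip_min])
                 & set(p.index[p < th.p_max])
                 & set(fc.index[fc["log2fc"].abs() > th.log2fc_min])
                 & set(mda.index[mda >= th.mda_min]))
        assert joint == brute

    def test_screen_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        n = 200
        vip, p, fc, mda = _stats_frame(
            rng.uniform(0, 4, n), rng.uniform(0, 0.2, n),
            rng.uniform(-2, 2, n), rng.uniform(-1, 6, n))
        base = {r.feature_id for r in
                screen_markers(vip, p, fc, mda, 1, MarkerThresholds())
                if r.is_marker}
        for kwargs in ({"vip_min": 2.5}, {"p_max": 0.01},
                       {"log2fc_min": 1.0}, {"mda_min": 3.0}):
            tighter = {r.feature_id for r in
                       screen_markers(vip, p, fc, mda, 1,
                                      MarkerThresholds(**kwargs))
                       if r.is_marker}
            assert tighter <= base

    def test_raw_fc_mode(self):
        vip, p, fc, mda = _stats_frame([3.0], [0.001], [-0.2], [4.0])
        th = MarkerThresholds(fc_mode="raw")
        # fc = 2^-0.2 = 0.87 > 0.5 passes the literal raw-ratio rule
        assert screen_markers(vip, p, fc, mda, 1, th)[0].is_marker

    def test_mismatched_features_rejected(self):
        vip, p, fc, mda = _stats_frame([3.0, 2.0], [0.001, 0.2],
                                       [1.2, 0.1], [4.0, 0.0])
        with pytest.raises(ValueError, match="differ"):
            screen_markers(vip.iloc[:1], p, fc, mda, 1)


class TestExclusivity:
    def test_disjoint_sets_all_exclusive(self):
        excl, venn = exclusive_markers({1: {"a", "b"}, 2: {"c"}})
        assert excl == {1: {"a", "b"}, 2: {"c"}}
        assert (venn["n_chemotypes"] == 1).all()

    def test_identical_sets_none_exclusive(self):
        excl, venn = exclusive_markers({1: {"a"}, 2: {"a"}})
        assert excl == {1: set(), 2: set()}
        assert venn.loc[0, "pattern"] == "1+2"

    def test_exclusive_never_exceeds_markers(self):
        rng = np.random.default_rng(9)
        feats = [f"F{i}" for i in range(30)]
        sets = {c: set(rng.choice(feats, rng.integers(3, 15), replace=False))
                for c in range(1, 5)}
        excl, _ = exclusive_markers(sets)
        for c in sets:
            assert excl[c] <= sets[c]


class TestValidationAndVolcano:
    def test_marker_only_validation_runs(self):
        rng = np.random.default_rng(10)
        n = 60
        labels = pd.Series(np.repeat([1, 2], 30),
                           index=[f"C{i}" for i in range(n)])
        X = pd.DataFrame(rng.standard_normal((n, 6)),
                         index=labels.index,
                         columns=[f"F{i}" for i in range(6)])
        X["F0"] += 8 * (labels == 1)
        ev = marker_validation(X, ["F0", "F1", "F2", "F3"], labels,
                               n_trees=100, seed=0)
        assert ev.test_accuracy > 0.9

    def test_empty_marker_set_rejected(self):
        X = pd.DataFrame(np.ones((10, 2)))
        with pytest.raises(ValueError, match="empty"):
            marker_validation(X, [], pd.Series(np.repeat([1, 2], 5)))

    def test_volcano_consistency(self):
        rng = np.random.default_rng(11)
        vip, p, fc, mda = _stats_frame(
            rng.uniform(0, 4, 50), rng.uniform(0, 1, 50),
            rng.uniform(-2, 2, 50), rng.uniform(-1, 6, 50))
        recs = screen_markers(vip, p, fc, mda, 1)
        v = volcano_table(fc, p, recs)
        assert len(v) == 50
        assert np.allclose(v["neg_log10_p"], -np.log10(p.to_numpy()))
        marked = set(v.loc[v["is_marker"], "feature_id"])
        assert marked == {r.feature_id for r in recs if r.is_marker}
        # p = 1 maps to zero
        p1 = p.copy()
        p1.iloc[0] = 1.0
        assert volcano_table(fc, p1).loc[0, "neg_log10_p"] == 0.0

    def test_marker_table_round_trips_records(self):
        vip, p, fc, mda = _stats_frame([3.0, 0.5], [0.001, 0.9],
                                       [1.2, 0.0], [4.0, 0.0])
        recs = screen_markers(vip, p, fc, mda, 2)
        tbl = marker_table(recs)
        assert tbl["is_marker"].tolist() == [True, False]
        assert (tbl["chemotype"] == 2).all()
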