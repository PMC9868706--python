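"""Filtering, imputation, drift correction, outliers, standardization."""

import numpy as np
import pandas as pd
import pytest

from chemotyper import (FeatureTable, correct_drift, filter_features,
                        generate_dataset, impute_knn,
                        log_standardize_and_average,
                        remove_replicate_outliers, rsd, select_correction)
from chemotyper.preprocess import CorrectionReport, collection_means

from conftest import small_config


def _table(values, roles=None, orders=None, collections=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    idx = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({
        "role": roles or ["biological"] * n,
        "injection_order": orders or list(range(1, n + 1)),
        "collection_id": collections or ["C1"] * n,
        "replicate_id": [f"R{i}" for i in range(n)],
        "platform": "lcms_pos"}, index=idx)
    cols = [f"F{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=idx, columns=cols), meta)


class TestFilterFeatures:
    def test_boundary_inclusive(self):
        # F0 missing in 8/10 biologicals (0.80) -> removed;
        # F1 missing in 7/10 -> kept
        v = np.ones((10, 2))
        v[:8, 0] = np.nan
        v[:7, 1] = np.nan
        out = filter_features(_table(v), max_undetected=0.80)
        assert list(out.intensities.columns) == ["F1"]

    def test_qc_missingness_ignored(self):
        v = np.ones((4, 1))
        v[3, 0] = np.nan
        t = _table(v, roles=["biological"] * 3 + ["qc"])
        out = filter_features(t, max_undetected=0.3)
        assert out.n_features == 1

    def test_all_removed_is_error(self):
        v = np.full((5, 2), np.nan)
        v[0] = 1.0  # missing in 4/5 = 0.8
        with pytest.raises(ValueError, match="every feature"):
            filter_features(_table(v), max_undetected=0.5)


class TestImputeKnn:
    def test_no_missing_identity(self, clean_dataset):
        t, _, _ = clean_dataset
        out = impute_knn(t, k=3)
        assert out.intensities.equals(t.intensities)

    def test_nearest_duplicate_forces_value(self):
        # S0 and S1 identical; S2 missing F2 and closest to them
        v = np.array([[1.0, 2.0, 9.0],
                      [1.0, 2.0, 9.0],
                      [1.0, 2.0, np.nan],
                      [50.0, 60.0, 70.0]])
        out = impute_knn(_table(v), k=1)
        assert out.intensities.iloc[2, 2] == pytest.approx(9.0)

    def test_observed_cells_untouched(self, small_dataset):
        t, _, _ = small_dataset
        out = impute_knn(filter_features(t), k=5)
        obs = ~t.intensities.isna()
        cols = out.intensities.columns
        assert np.allclose(out.intensities[cols][obs[cols]].fillna(0),
                           t.intensities[cols][obs[cols]].fillna(0))
        assert not out.intensities.isna().any().any()

    def test_beats_column_mean_on_mcar_mask(self):
        """KNN imputation should exploit replicate/chemotype correlation
        that column means ignore."""
        from chemotyper import mask_missing
        cfg = small_config(missing_rate=0.0, seed=11)
        t, _, _ = generate_dataset(cfg)
        masked = mask_missing(t, 0.1, seed=12)
        hidden = masked.intensities.isna() & ~t.intensities.isna()
        truth = np.log(t.intensities.to_numpy())
        knn = np.log(impute_knn(masked, k=10).intensities.to_numpy())
        colmean = masked.intensities.copy()
        colmean = colmean.fillna(colmean.mean(axis=0))
        cm = np.log(colmean.to_numpy())
        h = hidden.to_numpy()
        rmse_knn = np.sqrt(((knn[h] - truth[h]) ** 2).mean())
        rmse_cm = np.sqrt(((cm[h] - truth[h]) ** 2).mean())
        assert rmse_knn < rmse_cm

    def test_all_missing_sample_is_error(self):
        v = np.ones((5, 2))
        v[0] = np.nan
        with pytest.raises(ValueError, match="S0"):
            impute_knn(_table(v), k=2)


class TestRsd:
    @pytest.mark.parametrize("values,expected", [
        ([5.0, 5.0, 5.0], 0.0),
        ([1.0, 2.0, 3.0], 0.5),        # sd = 1 (n-1 denominator), mean = 2
    ])
    def test_known_values(self, values, expected):
        assert rsd(np.array(values)) == pytest.approx(expected)

    def test_scale_invariance(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        assert rsd(v) == pytest.approx(rsd(17.3 * v))

    def test_zero_mean_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            rsd(np.array([-1.0, 1.0]))


def _drift_table(curve, n_bio=40, n_qc=10, noise=0.0, seed=0):
    """Biological + interleaved QC samples sharing a drift curve g(order)."""
    rng = np.random.default_rng(seed)
    n = n_bio + n_qc
    orders = np.arange(1, n + 1)
    qc_pos = np.linspace(0, n - 1, n_qc).astype(int)
    roles = np.array(["biological"] * n, dtype=object)
    roles[qc_pos] = "qc"
    base = np.array([100.0, 5000.0])
    g = curve(orders.astype(float))
    v = base[None, :] * g[:, None] * np.exp(rng.normal(0, noise, (n, 2)))
    idx = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({
        "role": roles, "injection_order": orders,
        "collection_id": np.where(roles == "qc", "QC", "C1"),
        "replicate_id": idx, "platform": "lcms_pos"}, index=idx)
    return FeatureTable(pd.DataFrame(v, index=idx, columns=["F0", "F1"]),
                        meta)


class TestCorrectDrift:
    def test_constant_qc_unchanged(self):
        t = _drift_table(lambda o: np.ones_like(o))
        out, rep = correct_drift(t, method="loess", seed=0)
        assert np.allclose(out.intensities, t.intensities)

    def test_loess_exact_on_linear_drift(self):
        """A log-linear trend is inside the local-linear model class, so
        LOESS correction restores constant QC intensity exactly."""
        t = _drift_table(lambda o: 1.0 + 0.004 * o)
        out, rep = correct_drift(t, method="loess", seed=0)
        qc = out.intensities.loc[out.qc_mask]
        assert all(rsd(qc[c].to_numpy()) < 1e-6 for c in qc.columns)

    def test_rf_reduces_rsd_on_smooth_curve(self):
        t = _drift_table(lambda o: 1.0 + 0.3 * np.sin(o / 40.0), n_bio=160,
                         n_qc=40)
        out, rep = correct_drift(t, method="rf", seed=0)
        reduction = 1 - rep.rsd_after / rep.rsd_before
        assert (reduction >= 0.8).all()

    def test_group_ratios_preserved_under_shared_drift(self):
        """Feature-independent drift cancels in group mean ratios."""
        rng = np.random.default_rng(3)
        n_bio, n_qc = 60, 12
        n = n_bio + n_qc
        orders = np.arange(1, n + 1)
        qc_pos = np.linspace(0, n - 1, n_qc).astype(int)
        roles = np.array(["biological"] * n, dtype=object)
        roles[qc_pos] = "qc"
        group = np.array([("A" if i % 2 else "B") for i in range(n)])
        base = np.where(group == "A", 200.0, 100.0)
        g = 1.0 + 0.25 * np.sin(orders / 10.0)
        v = np.column_stack([base * g, base * 2 * g])
        idx = [f"S{i}" for i in range(n)]
        meta = pd.DataFrame({
            "role": roles, "injection_order": orders,
            "collection_id": np.where(roles == "qc", "QC", group),
            "replicate_id": idx, "platform": "lcms_pos"}, index=idx)
        t = FeatureTable(pd.DataFrame(v, index=idx, columns=["F0", "F1"]), meta)
        out, _ = correct_drift(t, method="loess", seed=0)
        for tab in (t, out):
            pass
        bio = out.sample_meta["role"] == "biological"
        for fid in ["F0", "F1"]:
            before = (t.intensities.loc[bio & (t.sample_meta.collection_id == "A"), fid].mean()
                      / t.intensities.loc[bio & (t.sample_meta.collection_id == "B"), fid].mean())
            after = (out.intensities.loc[bio & (out.sample_meta.collection_id == "A"), fid].mean()
                     / out.intensities.loc[bio & (out.sample_meta.collection_id == "B"), fid].mean())
            assert after == pytest.approx(before, rel=0.01)

    def test_too_few_qc_error(self):
        t = _drift_table(lambda o: np.ones_like(o), n_bio=10, n_qc=3)
        with pytest.raises(ValueError, match="QC"):
            correct_drift(t)


class TestSelectCorrection:
    def test_tie_prefers_rf(self):
        reports = {m: CorrectionReport(m, pd.Series([0.4]), pd.Series([0.1]))
                   for m in ("rf", "loess", "svr")}
        # force via the public API on a drift-free noisy table where all
        # methods leave QC RSD below threshold (reserved fraction ties at 1)
        t = _drift_table(lambda o: np.ones_like(o), noise=0.05, seed=1)
        _, reps = select_correction(t, seed=0)
        selected = [r.method for r in reps if r.selected]
        fracs = {r.method: r.reserved_fraction for r in reps}
        assert len(set(fracs.values())) == 1  # a genuine tie
        assert selected == ["rf"]

    def test_zero_drift_correction_is_nearly_identity(self):
        t = _drift_table(lambda o: np.ones_like(o), noise=0.05, seed=2)
        out, _ = select_correction(t, seed=0)
        rel = np.abs(out.intensities / t.intensities - 1.0)
        assert rel.max().max() < 0.05

    def test_reserved_fraction_improves_on_drifting_data(self):
        cfg = small_config(seed=21, missing_rate=0.0)
        t, _, _ = generate_dataset(cfg)
        out, reps = select_correction(t, seed=0)
        sel = [r for r in reps if r.selected][0]
        before = float((sel.rsd_before < sel.rsd_threshold).mean())
        assert sel.reserved_fraction >= 0.70
        assert sel.reserved_fraction > before
        assert sel.rsd_after.median() < sel.rsd_before.median()


class TestReplicateOutliers:
    def _replicated(self, n_coll=5, n_rep=6, displace=None, seed=0):
        rng = np.random.default_rng(seed)
        profiles = np.exp(rng.normal(5, 1, (n_coll, 8)))
        rows, colls = [], []
        for i in range(n_coll):
            for r in range(n_rep):
                rows.append(profiles[i] * np.exp(rng.normal(0, 0.05, 8)))
                colls.append(f"C{i}")
        v = np.array(rows)
        if displace is not None:
            v[displace] = v[displace] * np.exp(10 * 0.05)
        return _table(v, collections=colls)

    def test_removes_n_per_collection(self):
        t = self._replicated()
        out = remove_replicate_outliers(t, n_remove=3)
        counts = out.sample_meta.groupby("collection_id").size()
        assert (counts == 3).all()

    def test_displaced_replicate_always_removed(self):
        t = self._replicated(displace=2)
        out = remove_replicate_outliers(t, n_remove=3)
        assert "S2" not in out.intensities.index

    def test_small_collection_kept_intact(self):
        t = self._replicated(n_rep=3)
        with pytest.warns(UserWarning, match="skipped"):
            out = remove_replicate_outliers(t, n_remove=3)
        assert out.n_samples == t.n_samples


class TestLogStandardizeAndAverage:
    def test_feature_columns_centered_before_averaging(self, clean_dataset):
        t, _, _ = clean_dataset
        bio = t.intensities.loc[t.biological_mask]
        z = np.log10(bio.to_numpy())
        z = (z - z.mean(0)) / z.std(0)
        assert np.abs(z.mean(axis=0)).max() < 1e-9

    def test_output_shape_and_no_qc(self, clean_dataset):
        t, _, _ = clean_dataset
        Z = log_standardize_and_average(t)
        n_coll = t.sample_meta.loc[t.biological_mask, "collection_id"].nunique()
        assert Z.shape == (n_coll, t.n_features)
        assert "QC" not in Z.index

    def test_single_replicate_averaging_is_identity(self):
        v = np.exp(np.random.default_rng(0).normal(5, 1, (4, 3)))
        t = _table(v, collections=["C1", "C2", "C3", "C4"])
        Z = log_standardize_and_average(t)
        z = np.log10(v)
        z = (z - z.mean(0)) / z.std(0)
        assert np.allclose(Z.to_numpy(), z)

    def test_scaled_replicates_constant_log_offset(self):
        """Two collections that are x2 scaled copies differ by a constant
        per feature after log, so their standardized distance follows in
        closed form: every feature contributes the same difference."""
        base = np.exp(np.random.default_rng(1).normal(5, 1, 3))
        v = np.vstack([base, base * 2])
        t = _table(v, collections=["C1", "C2"])
        Z = log_standardize_and_average(t)
        diff = Z.loc["C2"] - Z.loc["C1"]
        assert np.allclose(diff, diff.iloc[0])
        # log10(2) offset, autoscaled to sd 1 over two samples -> diff = 2
        assert np.allclose(diff, 2.0)

    def test_non_positive_error(self):
        v = np.ones((3, 2))
        v[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            log_standardize_and_average(_table(v))

    def test_collection_means_linear_scale(self, clean_dataset):
        t, _, _ = clean_dataset
        means = collection_means(t)
        coll = t.sample_meta.loc[t.biological_mask, "collection_id"]
        one = t.intensities.loc[t.biological_mask].groupby(coll).mean()
        assert np.allclose(means, one.loc[means.index])
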