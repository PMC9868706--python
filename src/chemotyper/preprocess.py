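"""QC-anchored conditioning of raw feature tables.

The chain is: drop features undetected in most biological samples, fill
the remaining gaps by k-nearest-neighbour imputation, regress out
injection-order drift using the pooled-QC injections (choosing among
random-forest, LOESS and SVR calibration by the reserved-feature
criterion), optionally remove replicate outliers in PCA space, then
log-standardize and average replicates into a collection x feature matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer
from sklearn.svm import SVR
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import FeatureTable

log = logging.getLogger(__name__)

#: QC-RSD thresholds per platform for the reserved-feature criterion
PLATFORM_RSD_THRESHOLDS = {"gcms": 0.50, "lcms_pos": 0.30, "lcms_neg": 0.30,
                           "lcms": 0.30, "merged": 0.30}

DRIFT_FACTOR_CLIP = (0.1, 10.0)


@dataclass
class CorrectionReport:
    """Per-method QC calibration diagnostics.

    ``reserved_fraction`` is the fraction of features whose post-correction
    QC RSD falls below the platform threshold; a method qualifies when it
    reaches ``proportion_min`` (default 0.70) and the best qualifier is
    selected.
    """

    method: str
    rsd_before: pd.Series
    rsd_after: pd.Series
    rsd_threshold: float = 0.30
    selected: bool = False
    uncorrected: list[str] = field(default_factory=list)

    @property
    def reserved_fraction(self) -> float:
        ok = self.rsd_after.dropna() < self.rsd_threshold
        return float(ok.mean()) if len(ok) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.rsd_before.index,
            "method": self.method,
            "rsd_before": self.rsd_before.to_numpy(),
            "rsd_after": self.rsd_after.to_numpy(),
            "selected": self.selected,
        })


# ---------------------------------------------------------------------------
# filtering and imputation
# ---------------------------------------------------------------------------

def filter_features(table: FeatureTable,
                    max_undetected: float = 0.80) -> FeatureTable:
    """Drop features missing in >= ``max_undetected`` of biological samples.

    QC samples do not count toward the missing fraction.  The inclusive
    boundary means a feature undetected in exactly 80% of biologicals is
    removed.  Feature order is preserved.
    """
    bio = table.intensities.loc[table.biological_mask]
    if bio.shape[0] == 0:
        raise ValueError("table has no biological samples")
    frac_missing = bio.isna().mean(axis=0)
    keep = frac_missing[frac_missing < max_undetected].index
    if len(keep) == 0:
        raise ValueError("feature filter removed every feature")
    out = table.copy()
    out.intensities = out.intensities[keep]
    out.feature_meta = out.feature_meta.loc[keep]
    return out


def impute_knn(table: FeatureTable, k: int = 10) -> FeatureTable:
    """Fill missing cells with the mean over the k nearest samples.

    Distances are Euclidean over features observed in both samples,
    normalized by the shared-feature count (nan-Euclidean).  Observed
    cells are never altered.
    """
    vals = table.intensities.to_numpy(dtype=float)
    if k >= vals.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    if np.isnan(vals).all(axis=1).any():
        bad = table.intensities.index[np.isnan(vals).all(axis=1)][0]
        raise ValueError(f"sample {bad!r} has no observed features")
    if np.isnan(vals).all(axis=0).any():
        bad = table.intensities.columns[np.isnan(vals).all(axis=0)][0]
        raise ValueError(f"feature {bad!r} has no observed values")
    if not np.isnan(vals).any():
        return table.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(vals)
    out = table.copy()
    out.intensities = pd.DataFrame(filled, index=table.intensities.index,
                                   columns=table.intensities.columns)
    return out


def rsd(values: np.ndarray) -> float:
    """Relative standard deviation: sample sd (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError("rsd needs at least 2 observed values")
    m = v.mean()
    if m == 0:
        raise ValueError("rsd undefined for zero mean")
    return float(v.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def _rf_regress_1d(x: np.ndarray, Y: np.ndarray, x_pred: np.ndarray,
                   n_trees: int = 500, min_leaf: int = 5,
                   seed: int = 0, chunk: int = 64) -> np.ndarray:
    """Random-forest regression of many responses on one shared predictor.

    Bagged CART regression trees (variance-reduction splits, both children
    >= ``min_leaf``), fully vectorized over (response, tree) pairs — a
    single-predictor tree partitions the sorted x axis into intervals, so
    every split reduces to a prefix-sum scan.  Returns the forest-mean
    prediction at ``x_pred`` for every column of ``Y``, shape
    ``(len(x_pred), Y.shape[1])``.  Statistically equivalent to fitting an
    independent n_trees-forest per response.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(x):
        Y = Y.T
    n, n_feat = Y.shape
    order = np.argsort(x, kind="stable")
    xs, Ys = x[order], Y[order]
    q = np.asarray(x_pred, dtype=float)
    qo = np.argsort(q, kind="stable")
    qs = q[qo]
    rng = np.random.default_rng(seed)
    out = np.empty((len(q), n_feat))

    for f0 in range(0, n_feat, chunk):
        f1 = min(f0 + chunk, n_feat)
        nf = f1 - f0
        U = nf * n_trees                       # independent tree units
        boot = np.sort(rng.integers(0, n, size=(U, n)), axis=1)
        feat_of = np.repeat(np.arange(nf), n_trees)
        xb = xs[boot]                          # (U, n) sorted by construction
        yb = Ys[boot, (f0 + feat_of)[:, None]]
        c1 = np.concatenate([np.zeros((U, 1)), np.cumsum(yb, axis=1)], axis=1)
        c2 = np.concatenate([np.zeros((U, 1)), np.cumsum(yb ** 2, axis=1)],
                            axis=1)
        # worklist recursion over (unit, lo, hi) segments
        acc = np.zeros((nf, len(q) + 1))       # difference-array accumulator
        units = np.arange(U)
        lo = np.zeros(U, dtype=int)
        hi = np.full(U, n, dtype=int)
        while len(units):
            L = hi - lo
            splittable = L >= 2 * min_leaf
            best_k = np.full(len(units), -1, dtype=int)
            if splittable.any():
                su, slo, shi = units[splittable], lo[splittable], hi[splittable]
                sL = shi - slo
                maxc = int(sL.max()) - 2 * min_leaf + 1
                ks = min_leaf + np.arange(maxc)[None, :]          # left sizes
                valid = ks <= (sL - min_leaf)[:, None]
                cut = np.minimum(slo[:, None] + ks, shi[:, None] - 1)
                left_n = ks.astype(float)
                right_n = (sL[:, None] - ks).astype(float)
                s_all = c1[su, shi] - c1[su, slo]
                sl = c1[su[:, None], cut] - c1[su, slo][:, None]
                sr = s_all[:, None] - sl
                # maximizing sum of squared child means = variance reduction
                with np.errstate(divide="ignore", invalid="ignore"):
                    gain = sl ** 2 / left_n + sr ** 2 / right_n
                distinct = xb[su[:, None], cut - 1] < xb[su[:, None], cut]
                gain = np.where(valid & distinct, gain, -np.inf)
                gbest = np.argmax(gain, axis=1)
                has = gain[np.arange(len(su)), gbest] > -np.inf
                best_k[splittable] = np.where(has, min_leaf + gbest, -1)
            is_leaf = best_k < 0
            if is_leaf.any():
                lu, llo, lhi = units[is_leaf], lo[is_leaf], hi[is_leaf]
                mean = (c1[lu, lhi] - c1[lu, llo]) / (lhi - llo)
                # leaf x-interval -> query index range [a, b)
                left_edge = np.where(llo == 0, -np.inf,
                                     0.5 * (xb[lu, np.maximum(llo - 1, 0)]
                                            + xb[lu, llo]))
                right_edge = np.where(lhi == n, np.inf,
                                      0.5 * (xb[lu, lhi - 1]
                                             + xb[lu, np.minimum(lhi, n - 1)]))
                a = np.searchsorted(qs, left_edge, side="left")
                b = np.searchsorted(qs, right_edge, side="left")
                np.add.at(acc, (feat_of[lu], a), mean)
                np.add.at(acc, (feat_of[lu], b), -mean)
            keep = ~is_leaf
            ku, klo, khi = units[keep], lo[keep], hi[keep]
            kcut = klo + best_k[keep]
            units = np.concatenate([ku, ku])
            lo = np.concatenate([klo, kcut])
            hi = np.concatenate([kcut, khi])
        pred_sorted = np.cumsum(acc, axis=1)[:, :-1] / n_trees
        out[qo, f0:f1] = pred_sorted.T
    return out


def _fit_drift_curve(method: str, qc_orders: np.ndarray, qc_vals: np.ndarray,
                     all_orders: np.ndarray, seed: int,
                     rf_trees: int = 500, rf_min_leaf: int = 5,
                     loess_span: float = 0.75, svr_epsilon: float = 0.1
                     ) -> np.ndarray:
    """Fitted QC trend, evaluated at ``all_orders``, on the QC-median scale."""
    y = qc_vals / np.median(qc_vals)
    x = qc_orders.astype(float)
    if method == "rf":
        return _rf_regress_1d(x, y[:, None], all_orders.astype(float),
                              n_trees=rf_trees, min_leaf=rf_min_leaf,
                              seed=seed)[:, 0]
    if method == "loess":
        fitted = lowess(y, x, frac=loess_span, return_sorted=True)
        fx, fy = fitted[:, 0], fitted[:, 1]
        q = all_orders.astype(float)
        out = np.interp(q, fx, fy)
        # linear extrapolation beyond the QC range
        if len(fx) >= 2:
            left = q < fx[0]
            right = q > fx[-1]
            if left.any():
                s = (fy[1] - fy[0]) / (fx[1] - fx[0])
                out[left] = fy[0] + s * (q[left] - fx[0])
            if right.any():
                s = (fy[-1] - fy[-2]) / (fx[-1] - fx[-2])
                out[right] = fy[-1] + s * (q[right] - fx[-1])
        return out
    if method == "svr":
        span = max(x.max() - x.min(), 1.0)
        xs = (x - x.min()) / span
        reg = SVR(kernel="rbf", epsilon=svr_epsilon, gamma="scale", C=1.0)
        reg.fit(xs[:, None], y)
        return reg.predict(((all_orders - x.min()) / span)[:, None])
    raise ValueError(f"unknown drift-correction method {method!r}")


def _rf_kwargs(params: dict) -> dict:
    out = {}
    if "rf_trees" in params:
        out["n_trees"] = params["rf_trees"]
    if "rf_min_leaf" in params:
        out["min_leaf"] = params["rf_min_leaf"]
    return out


def _cv_r2_1d(method: str, x: np.ndarray, Y: np.ndarray, seed: int,
              n_folds: int = 5, **params) -> np.ndarray:
    """Cross-validated R^2 of the drift regressor on the QC series.

    Interleaved folds over the injection-order-sorted QC points so every
    fold spans the whole run.  Y is (n_qc, n_features) on the
    QC-median-normalized scale; returns one R^2 per feature.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    pred = np.full_like(Y, np.nan)
    for f in range(n_folds):
        te = order[f::n_folds]
        tr = np.setdiff1d(order, te)
        if len(tr) < 3:
            continue
        if method == "rf":
            pred[te] = _rf_regress_1d(x[tr], Y[tr], x[te], seed=seed + f,
                                      **_rf_kwargs(params))
        else:
            for j in range(Y.shape[1]):
                pred[te, j] = _fit_drift_curve(method, x[tr], Y[tr, j],
                                               x[te], seed + f, **params)
    sse = np.nansum((Y - pred) ** 2, axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    sst[sst == 0] = np.inf
    return 1.0 - sse / sst


def _reliability_weight(cv_r2: np.ndarray, full_at: float = 0.9) -> np.ndarray:
    """Correction weight from the QC-trend CV R^2: none at <= 0, full at
    >= ``full_at``, proportional in between."""
    return np.clip(np.asarray(cv_r2, dtype=float) / full_at, 0.0, 1.0)


def correct_drift(table: FeatureTable, method: str = "rf",
                  params: dict | None = None, seed: int = 0,
                  rsd_threshold: float = 0.30,
                  min_cv_r2: float = 0.0
                  ) -> tuple[FeatureTable, CorrectionReport]:
    """Divide out the QC-fitted injection-order trend, feature by feature.

    For each feature the chosen regressor is fitted to QC intensity versus
    injection order (QC samples only); the drift factor at any order is
    the fitted value divided by the median fitted value at the QC orders,
    clipped to [0.1, 10].  Corrections are reliability-weighted: the factor
    is raised to a power that ramps with the regressor's cross-validated
    predictive power on the QC series — full correction for CV R^2 >= 0.9,
    proportional shrinkage below, none at CV R^2 <= ``min_cv_r2``.  A
    feature whose QC trend cannot predict held-out QC values carries no
    detectable drift and keeps factor 1, so a drift-free table passes
    through (nearly) untouched.
    Features whose QC values are all missing are passed through and
    flagged in the report.
    """
    params = params or {}
    qc_mask = table.qc_mask
    if qc_mask.sum() < 5:
        raise ValueError("drift correction needs at least 5 QC samples")
    orders = table.sample_meta["injection_order"].to_numpy().astype(float)
    qc_orders = orders[qc_mask]
    vals = table.intensities.to_numpy(dtype=float).copy()
    qc_vals = vals[qc_mask]
    cols = table.intensities.columns

    rsd_before = np.full(len(cols), np.nan)
    uncorrected: list[str] = []
    fittable = np.zeros(len(cols), dtype=bool)
    for j, fid in enumerate(cols):
        col_qc = qc_vals[:, j]
        obs = ~np.isnan(col_qc)
        if obs.sum() >= 2:
            rsd_before[j] = rsd(col_qc[obs])
        if obs.sum() >= 5 and np.median(col_qc[obs]) != 0:
            fittable[j] = True
        else:
            uncorrected.append(fid)

    complete = fittable & ~np.isnan(qc_vals).any(axis=0)
    med = np.nanmedian(qc_vals, axis=0)

    # complete-QC features: one batched fit + CV gate
    cidx = np.flatnonzero(complete)
    if len(cidx):
        Yn = qc_vals[:, cidx] / med[cidx]
        cv_r2 = _cv_r2_1d(method, qc_orders, Yn, seed, **params)
        keep = cv_r2 > min_cv_r2
        kidx = cidx[keep]
        if len(kidx):
            if method == "rf":
                fitted = _rf_regress_1d(
                    qc_orders, qc_vals[:, kidx] / med[kidx], orders,
                    seed=seed, **_rf_kwargs(params))
            else:
                fitted = np.column_stack([
                    _fit_drift_curve(method, qc_orders,
                                     qc_vals[:, j] / med[j], orders, seed,
                                     **params)
                    for j in kidx])
            qc_fit_med = np.median(fitted[qc_mask], axis=0)
            qc_fit_med[qc_fit_med == 0] = 1.0
            factor = np.clip(fitted / qc_fit_med, *DRIFT_FACTOR_CLIP)
            w = _reliability_weight(cv_r2[keep])
            vals[:, kidx] = vals[:, kidx] / factor ** w

    # features with partially-missing QC: per-feature path
    for j in np.flatnonzero(fittable & ~complete):
        col_qc = qc_vals[:, j]
        obs = ~np.isnan(col_qc)
        yn = (col_qc[obs] / np.median(col_qc[obs]))[:, None]
        cv_r2 = _cv_r2_1d(method, qc_orders[obs], yn, seed, **params)[0]
        if cv_r2 <= min_cv_r2:
            continue
        fitted = _fit_drift_curve(method, qc_orders[obs], col_qc[obs],
                                  orders, seed, **params)
        factor = fitted / np.median(fitted[qc_mask][obs])
        factor = np.clip(factor, *DRIFT_FACTOR_CLIP)
        vals[:, j] = vals[:, j] / factor ** _reliability_weight(cv_r2)

    qc_after = vals[qc_mask]
    rsd_after = np.full(len(cols), np.nan)
    for j in range(len(cols)):
        obs = ~np.isnan(qc_after[:, j])
        if obs.sum() >= 2 and np.nanmean(qc_after[obs, j]) != 0:
            rsd_after[j] = rsd(qc_after[obs, j])

    out = table.copy()
    out.intensities = pd.DataFrame(vals, index=table.intensities.index,
                                   columns=cols)
    report = CorrectionReport(
        method=method,
        rsd_before=pd.Series(rsd_before, index=cols),
        rsd_after=pd.Series(rsd_after, index=cols),
        rsd_threshold=rsd_threshold,
        uncorrected=uncorrected,
    )
    return out, report


#: tie-break preference among qualifying correction methods
_METHOD_ORDER = {"rf": 0, "loess": 1, "svr": 2}


def select_correction(table: FeatureTable,
                      thresholds: dict[str, float] | None = None,
                      proportion_min: float = 0.70, seed: int = 0,
                      params: dict | None = None
                      ) -> tuple[FeatureTable, list[CorrectionReport]]:
    """Run rf/loess/svr drift calibration and keep the best method.

    A method qualifies when its reserved fraction (features with QC RSD
    under the platform threshold) reaches ``proportion_min``; among
    qualifiers the highest reserved fraction wins, ties preferring
    rf, then loess, then svr.  If no method qualifies the best reserved
    fraction is used anyway, with a warning.
    """
    thresholds = thresholds or PLATFORM_RSD_THRESHOLDS
    platforms = table.sample_meta["platform"].unique()
    plat = platforms[0] if len(platforms) == 1 else "merged"
    thr = thresholds.get(plat, thresholds.get("lcms", 0.30))

    results = {}
    for method in ("rf", "loess", "svr"):
        results[method] = correct_drift(table, method=method, params=params,
                                        seed=seed, rsd_threshold=thr)

    def _rank(m: str) -> tuple:
        return (-results[m][1].reserved_fraction, _METHOD_ORDER[m])

    qualifiers = [m for m in results
                  if results[m][1].reserved_fraction >= proportion_min]
    pool = qualifiers or list(results)
    best = min(pool, key=_rank)
    if not qualifiers:
        warnings.warn("no drift-correction method reached the reserved-"
                      f"fraction criterion {proportion_min:.2f}; using "
                      f"{best!r} anyway")
    reports = []
    for m in ("rf", "loess", "svr"):
        rep = results[m][1]
        rep.selected = (m == best)
        reports.append(rep)
    log.info("drift correction selected %s (reserved fraction %.3f at RSD<%.2f)",
             best, results[best][1].reserved_fraction, thr)
    return results[best][0], reports


# ---------------------------------------------------------------------------
# replicate outliers, standardization, averaging
# ---------------------------------------------------------------------------

def remove_replicate_outliers(table: FeatureTable,
                              n_remove: int = 3) -> FeatureTable:
    """Drop the ``n_remove`` replicates farthest from their collection
    centroid in the global top-2 PC plane.

    The plane is computed once on log10, per-feature autoscaled biological
    samples.  Collections with <= ``n_remove`` replicates are kept intact
    (with a warning).  QC samples are never removed.
    """
    bio_mask = table.biological_mask
    bio = table.intensities.loc[bio_mask]
    if bio.isna().any().any() or (bio <= 0).any().any():
        raise ValueError("outlier removal expects imputed, positive intensities")
    z = np.log10(bio.to_numpy(dtype=float))
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) == 0, 1.0, z.std(axis=0))
    scores = PCA(n_components=2).fit_transform(z)
    meta = table.sample_meta.loc[bio_mask]

    drop: list[str] = []
    for coll, grp in meta.groupby("collection_id", sort=False):
        if len(grp) <= n_remove:
            warnings.warn(f"collection {coll!r} has {len(grp)} replicates; "
                          "outlier removal skipped")
            continue
        pos = bio.index.get_indexer(grp.index)
        centroid = scores[pos].mean(axis=0)
        dist = np.linalg.norm(scores[pos] - centroid, axis=1)
        worst = np.argsort(-dist, kind="stable")[:n_remove]
        drop.extend(grp.index[worst])

    keep = table.intensities.index.difference(drop, sort=False)
    out = table.copy()
    out.intensities = out.intensities.loc[keep]
    out.sample_meta = out.sample_meta.loc[keep]
    return out


def log_standardize_and_average(table: FeatureTable) -> pd.DataFrame:
    """log10 -> per-feature autoscale (over biologicals) -> replicate means.

    Returns the collection x feature matrix downstream stages consume; QC
    samples are dropped.  Raises on non-positive intensities (impute and
    drift-correct first).
    """
    bio = table.intensities.loc[table.biological_mask]
    vals = bio.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values present; run imputation first")
    if (vals <= 0).any():
        raise ValueError("non-positive intensities; check imputation/correction")
    z = np.log10(vals)
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=0)) / sd
    zdf = pd.DataFrame(z, index=bio.index, columns=bio.columns)
    coll = table.sample_meta.loc[table.biological_mask, "collection_id"]
    out = zdf.groupby(coll, sort=False).mean()
    out.index.name = "collection_id"
    return out


def collection_means(table: FeatureTable) -> pd.DataFrame:
    """Linear-scale replicate-mean intensities per collection (for fold
    changes, which are ratios of linear means)."""
    bio = table.intensities.loc[table.biological_mask]
    coll = table.sample_meta.loc[table.biological_mask, "collection_id"]
    out = bio.groupby(coll, sort=False).mean()
    out.index.name = "collection_id"
    return out
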