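"""Chemomarker screening.

A metabolite is a chemomarker of a chemotype when it jointly satisfies
four one-vs-rest criteria: OPLS-DA VIP >= 2, Student's t-test p < 0.05,
|log2 fold change| > 0.5, and random-forest mean decrease accuracy >= 2
(per-tree out-of-bag accuracy drop divided by its standard error, the
z-like convention under which a fixed threshold of 2 is meaningful).
Exclusivity partitions the per-chemotype marker sets, and a marker-only
random forest re-validates the labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .evaluate import RfEval, rf_discriminant_eval


@dataclass
class MarkerThresholds:
    """Joint screening criteria (defaults: VIP>=2, p<0.05, |log2FC|>0.5,
    MDA>=2).  ``fc_mode='raw'`` switches to the literal raw-ratio rule
    FC > threshold instead of the two-sided log2 rule."""

    vip_min: float = 2.0
    p_max: float = 0.05
    log2fc_min: float = 0.5
    mda_min: float = 2.0
    fc_mode: str = "log2"


@dataclass
class MarkerRecord:
    feature_id: str
    chemotype: int
    vip: float
    p_value: float
    fc: float
    log2fc: float
    mda: float
    passes: dict = field(default_factory=dict)
    direction: str = "up"
    exclusive: bool = False

    @property
    def is_marker(self) -> bool:
        return all(self.passes.values())


# ---------------------------------------------------------------------------
# single criteria
# ---------------------------------------------------------------------------

def fold_change(linear_means: pd.DataFrame,
                group_mask: np.ndarray) -> pd.DataFrame:
    """Per-feature group/rest ratio of linear-scale collection means."""
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.all() or not group_mask.any():
        raise ValueError("both groups must be non-empty")
    g = linear_means.loc[group_mask].mean(axis=0)
    r = linear_means.loc[~group_mask].mean(axis=0)
    if (r == 0).any():
        bad = r.index[r == 0][0]
        raise ValueError(f"zero rest-group mean for feature {bad!r}")
    fc = g / r
    return pd.DataFrame({"fc": fc, "log2fc": np.log2(fc)})


def t_test(Z: pd.DataFrame, group_mask: np.ndarray,
           welch: bool = False) -> pd.Series:
    """Two-sided Student's t (pooled variance; ``welch=True`` for Welch).

    Degenerate zero-variance comparisons report p = 1.0.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    a = Z.loc[group_mask].to_numpy(dtype=float)
    b = Z.loc[~group_mask].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 collections")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, equal_var=not welch, axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=Z.columns, name="p_value")


def _oob_indices(forest: RandomForestClassifier, n: int) -> list[np.ndarray]:
    out = []
    for sampled in forest.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        out.append(np.flatnonzero(mask))
    return out


def rf_mda(X: pd.DataFrame, group_mask: np.ndarray, n_trees: int = 1000,
           seed: int = 0) -> pd.Series:
    """SE-scaled mean decrease accuracy for a one-vs-rest contrast.

    For each tree, the out-of-bag accuracy drop is measured when each
    feature column is permuted (one shared row permutation per tree,
    applied column-wise); MDA = mean drop over trees / (sd / sqrt(T)).
    """
    Xa = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
    y = np.asarray(group_mask, dtype=int)
    n, p = Xa.shape
    forest = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                    bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(Xa, y)
    rng = np.random.default_rng(seed)
    drops = np.full((n_trees, p), np.nan, dtype=np.float64)
    buf = None
    for ti, (tree, oob) in enumerate(zip(forest.estimators_,
                                         _oob_indices(forest, n))):
        m = len(oob)
        if m == 0:
            continue
        Xo = Xa[oob]
        yo = y[oob]
        base = (tree.predict(Xo).astype(int) == yo).mean()
        perm = rng.permutation(m)
        # stack: p copies of Xo; copy j gets column j permuted
        if buf is None or buf.shape[0] < m * p:
            buf = np.empty((m * p, p), dtype=np.float32)
        stack = buf[:m * p].reshape(p, m, p)
        stack[:] = Xo[None, :, :]
        stack[np.arange(p), :, np.arange(p)] = Xo[perm].T
        preds = tree.predict(buf[:m * p]).astype(int).reshape(p, m)
        drops[ti] = base - (preds == yo[None, :]).mean(axis=1)
    mean = np.nanmean(drops, axis=0)
    sd = np.nanstd(drops, axis=0, ddof=1)
    t_eff = np.sum(~np.isnan(drops[:, 0]))
    se = sd / np.sqrt(max(t_eff, 1))
    mda = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                   np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
    cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    return pd.Series(mda, index=cols, name="mda")


# ---------------------------------------------------------------------------
# the joint screen
# ---------------------------------------------------------------------------

def screen_markers(vip: pd.Series, p: pd.Series, fc_table: pd.DataFrame,
                   mda: pd.Series, chemotype: int,
                   thresholds: MarkerThresholds | None = None
                   ) -> list[MarkerRecord]:
    """Apply the four-criterion screen to one chemotype's statistics.

    All inputs must cover the identical feature set.  Returns one record
    per feature; markers are the records whose four criteria all pass.
    """
    th = thresholds or MarkerThresholds()
    idx = vip.index
    for other in (p, mda):
        if not idx.equals(other.index):
            raise ValueError("feature sets of the four statistics differ")
    if not idx.equals(fc_table.index):
        raise ValueError("feature sets of the four statistics differ")

    records = []
    for fid in idx:
        log2fc = float(fc_table.loc[fid, "log2fc"])
        if th.fc_mode == "log2":
            fc_pass = abs(log2fc) > th.log2fc_min
        elif th.fc_mode == "raw":
            fc_pass = float(fc_table.loc[fid, "fc"]) > th.log2fc_min
        else:
            raise ValueError(f"unknown fc_mode {th.fc_mode!r}")
        passes = {
            "vip": float(vip[fid]) >= th.vip_min,
            "p": float(p[fid]) < th.p_max,
            "fc": bool(fc_pass),
            "mda": float(mda[fid]) >= th.mda_min,
        }
        records.append(MarkerRecord(
            feature_id=fid, chemotype=chemotype, vip=float(vip[fid]),
            p_value=float(p[fid]), fc=float(fc_table.loc[fid, "fc"]),
            log2fc=log2fc, mda=float(mda[fid]), passes=passes,
            direction="up" if log2fc > 0 else "down"))
    return records


def marker_table(records: list[MarkerRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({"feature_id": r.feature_id, "chemotype": r.chemotype,
                     "vip": r.vip, "p_value": r.p_value, "fc": r.fc,
                     "log2fc": r.log2fc, "mda": r.mda,
                     "pass_vip": r.passes["vip"], "pass_p": r.passes["p"],
                     "pass_fc": r.passes["fc"], "pass_mda": r.passes["mda"],
                     "is_marker": r.is_marker, "direction": r.direction,
                     "exclusive": r.exclusive})
    return pd.DataFrame(rows)


def exclusive_markers(marker_sets: dict[int, set[str]]
                      ) -> tuple[dict[int, set[str]], pd.DataFrame]:
    """Per-chemotype exclusive markers plus the full Venn partition.

    A marker is exclusive to a chemotype when no other chemotype's set
    contains it.  The partition table has one row per feature with its
    membership pattern.
    """
    all_feats = sorted(set().union(*marker_sets.values())) if marker_sets else []
    chems = sorted(marker_sets)
    rows = []
    exclusive: dict[int, set[str]] = {c: set() for c in chems}
    for f in all_feats:
        member = [c for c in chems if f in marker_sets[c]]
        if len(member) == 1:
            exclusive[member[0]].add(f)
        rows.append({"feature_id": f,
                     "pattern": "+".join(str(c) for c in member),
                     "n_chemotypes": len(member)})
    return exclusive, pd.DataFrame(rows)


def marker_validation(X: pd.DataFrame, marker_union: list[str],
                      labels: pd.Series, seed: int = 0,
                      n_trees: int = 1000, n_repeats: int = 1) -> RfEval:
    """Random-forest re-evaluation of the labelling on markers only."""
    if len(marker_union) == 0:
        raise ValueError("empty marker set")
    return rf_discriminant_eval(X[list(marker_union)], labels, seed=seed,
                                n_trees=n_trees, n_repeats=n_repeats)


def volcano_table(fc_table: pd.DataFrame, p: pd.Series,
                  records: list[MarkerRecord] | None = None) -> pd.DataFrame:
    """Plot-ready volcano export: log2FC, -log10 p, marker flag."""
    out = pd.DataFrame({"feature_id": fc_table.index,
                        "log2fc": fc_table["log2fc"].to_numpy(),
                        "neg_log10_p": -np.log10(
                            p.loc[fc_table.index].to_numpy())})
    flagged = {r.feature_id for r in records or [] if r.is_marker}
    out["is_marker"] = out["feature_id"].isin(flagged)
    return out
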