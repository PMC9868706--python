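"""Adjudication of candidate chemotype classifications.

A random-forest discriminant protocol scores each candidate labelling:
stratified 75/25 split, 1,000 trees, out-of-bag training accuracy,
independent-set accuracy, and macro one-vs-rest AUC, averaged over
repeated seeded splits.  PCA summarizes global structure.  One-vs-rest
OPLS-DA (single predictive component plus orthogonal components) with
R2Y/Q2 and permutation testing validates each chemotype and supplies the
per-feature VIP used by marker screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

# ---------------------------------------------------------------------------
# random-forest discriminant evaluation
# ---------------------------------------------------------------------------


@dataclass
class RfEval:
    """Discriminant scores for one candidate labelling (means over repeats)."""

    train_accuracy: float       # out-of-bag accuracy on the training split
    test_accuracy: float        # accuracy on the held-out 25%
    auc: float                  # macro one-vs-rest AUC on the held-out set
    per_class_accuracy: pd.Series
    n_trees: int = 1000
    split: float = 0.75
    n_repeats: int = 1


def rf_discriminant_eval(X: pd.DataFrame, labels: pd.Series,
                         split: float = 0.75, n_trees: int = 1000,
                         seed: int = 0, n_repeats: int = 1) -> RfEval:
    """Score a labelling by a seeded stratified-split random forest.

    With ``n_repeats > 1`` all scores are means over independently seeded
    splits (the forest itself is reseeded per repeat as well).
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")

    rng = np.random.default_rng(seed)
    tr_acc, te_acc, aucs = [], [], []
    per_class = pd.Series(0.0, index=classes)
    for _ in range(n_repeats):
        s = int(rng.integers(2 ** 31 - 1))
        for attempt in range(10):
            Xtr, Xte, ytr, yte = train_test_split(
                Xa, y, train_size=split, stratify=y, random_state=s + attempt)
            if len(np.unique(ytr)) == len(classes):
                break
            warnings.warn("a class was absent from the training split; re-drawing")
        clf = RandomForestClassifier(n_estimators=n_trees,
                                     max_features="sqrt", oob_score=True,
                                     random_state=s, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # oob on small splits
            clf.fit(Xtr, ytr)
        tr_acc.append(clf.oob_score_)
        pred = clf.predict(Xte)
        te_acc.append(float((pred == yte).mean()))
        proba = clf.predict_proba(Xte)
        if len(classes) == 2:
            aucs.append(float(roc_auc_score(yte, proba[:, 1])))
        else:
            aucs.append(float(roc_auc_score(yte, proba, multi_class="ovr",
                                            average="macro",
                                            labels=clf.classes_)))
        for c in classes:
            m = yte == c
            per_class[c] += float((pred[m] == c).mean()) if m.any() else np.nan

    return RfEval(float(np.mean(tr_acc)), float(np.mean(te_acc)),
                  float(np.mean(aucs)), per_class / n_repeats,
                  n_trees, split, n_repeats)


def compare_classifications(X: pd.DataFrame,
                            candidates: list[tuple[str, "ChemotypeAssignment"]],
                            split: float = 0.75, n_trees: int = 1000,
                            seed: int = 0, n_repeats: int = 20
                            ) -> pd.DataFrame:
    """Score every candidate labelling; one row per candidate.

    The winner (flagged in the ``best`` column) maximizes the mean of
    training and independent-set accuracy.
    """
    if not candidates:
        raise ValueError("no candidate classifications given")
    rows = []
    for name, assignment in candidates:
        try:
            ev = rf_discriminant_eval(X, assignment.label_of.loc[X.index],
                                      split=split, n_trees=n_trees,
                                      seed=seed, n_repeats=n_repeats)
            scores = {"train_accuracy": ev.train_accuracy,
                      "test_accuracy": ev.test_accuracy,
                      "mean_accuracy": (ev.train_accuracy
                                        + ev.test_accuracy) / 2,
                      "auc": ev.auc}
        except ValueError as err:
            warnings.warn(f"candidate {name!r} not scorable: {err}")
            scores = {"train_accuracy": np.nan, "test_accuracy": np.nan,
                      "mean_accuracy": np.nan, "auc": np.nan}
        rows.append({"name": name, "method": assignment.method,
                     "k": assignment.k, **scores})
    out = pd.DataFrame(rows)
    out["best"] = out["mean_accuracy"] == out["mean_accuracy"].max()
    return out


def pca_summary(X: pd.DataFrame, n_components: int = 12
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA scores and explained-variance fractions (descending)."""
    Xa = np.asarray(X, dtype=float)
    n_components = min(n_components, min(Xa.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xa)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xa))
    return pd.DataFrame(scores, index=idx, columns=cols), \
        pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """One-vs-rest OPLS-DA model: a single predictive component after
    removal of ``n_orth`` y-orthogonal components.

    VIP combines the predictive component (weighted by the fraction of
    class variance it explains) with the orthogonal components (weighted
    by their X-variance shares), normalized so that sum(VIP^2) equals the
    number of features.
    """

    w_pred: np.ndarray
    t_pred: np.ndarray
    p_pred: np.ndarray
    q: float
    w_orth: np.ndarray          # n_orth x p
    t_orth: np.ndarray          # n x n_orth
    p_orth: np.ndarray          # n_orth x p
    r2y_cum: float
    q2_cum: float
    vip: pd.Series
    x_mean: np.ndarray
    y_mean: float


def _opls_decompose(Xc: np.ndarray, yc: np.ndarray, n_orth: int):
    """Orthogonal-signal-corrected decomposition; returns the filtered X
    plus predictive and orthogonal loadings/weights."""
    Xr = Xc.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orth):
        w = Xr.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-10:
            break
        w_o /= n_o
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        W_o.append(w_o); P_o.append(p_o); T_o.append(t_o)

    w = Xr.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("response carries no covariance with X")
    w /= nw
    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    p_dim = Xc.shape[1]
    W_o = np.asarray(W_o) if W_o else np.zeros((0, p_dim))
    P_o = np.asarray(P_o) if P_o else np.zeros((0, p_dim))
    T_o = np.column_stack(T_o) if T_o else np.zeros((len(yc), 0))
    return Xr, w, t, p, q, W_o, P_o, T_o


def _apply_orth_filter(Xc: np.ndarray, W_o: np.ndarray,
                       P_o: np.ndarray) -> np.ndarray:
    Xr = Xc.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xr @ w_o
        Xr = Xr - np.outer(t_o, p_o)
    return Xr


def opls_fit(X: pd.DataFrame, y: np.ndarray | pd.Series, n_orth: int = 1,
             cv_folds: int = 7, seed: int = 0) -> OplsModel:
    """Fit one-vs-rest OPLS-DA on a +/-1 response.

    R2Y(cum) is the fraction of response variance the predictive
    component explains after orthogonal filtering; Q2(cum) is
    1 - PRESS/TSS over stratified ``cv_folds``-fold cross-validation.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    classes = np.unique(ya)
    if len(classes) != 2:
        raise ValueError("y must be binary (+1/-1 one-vs-rest coding)")
    if n_orth >= min(Xa.shape) - 1:
        raise ValueError("n_orth must be below rank(X)")
    strat = (ya == classes[1]).astype(int)
    if min(np.bincount(strat)) < cv_folds:
        raise ValueError(f"both classes need >= cv_folds={cv_folds} members")

    x_mean = Xa.mean(axis=0)
    y_mean = float(ya.mean())
    Xc, yc = Xa - x_mean, ya - y_mean

    Xr, w, t, p, q, W_o, P_o, T_o = _opls_decompose(Xc, yc, n_orth)
    yhat = q * t
    ssy = float(yc @ yc)
    r2y = 1.0 - float(((yc - yhat) ** 2).sum()) / ssy

    # cross-validated Q2
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    press = tss = 0.0
    for tr, te in skf.split(Xa, strat):
        xm, ym = Xa[tr].mean(axis=0), float(ya[tr].mean())
        try:
            _, wf, tf, pf, qf, Wof, Pof, _ = _opls_decompose(
                Xa[tr] - xm, ya[tr] - ym, n_orth)
        except ValueError:
            continue
        Xte = _apply_orth_filter(Xa[te] - xm, Wof, Pof)
        pred = qf * (Xte @ wf) + ym
        press += float(((ya[te] - pred) ** 2).sum())
        tss += float(((ya[te] - ym) ** 2).sum())
    q2 = 1.0 - press / tss if tss > 0 else np.nan

    # VIP over predictive + orthogonal components
    p_feat = Xa.shape[1]
    comps = [w]
    ssx_total = float((Xc ** 2).sum())
    weights = [max(r2y, 0.0)]
    for i in range(W_o.shape[0]):
        ssx_i = float((T_o[:, i] @ T_o[:, i]) * (P_o[i] @ P_o[i]))
        comps.append(W_o[i])
        weights.append((1.0 - max(r2y, 0.0)) * ssx_i / ssx_total)
    wts = np.asarray(weights)
    if wts.sum() <= 0:
        wts = np.ones_like(wts)
    wts = wts / wts.sum()
    vip2 = p_feat * sum(wt * c ** 2 for wt, c in zip(wts, comps))
    cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p_feat)
    vip = pd.Series(np.sqrt(vip2), index=cols, name="vip")

    return OplsModel(w, t, p, q, W_o, T_o, P_o, r2y, q2, vip, x_mean, y_mean)


@dataclass
class PermutationResult:
    """Observed vs label-permuted R2Y/Q2 with empirical p-values."""

    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_r2y: float
    p_q2: float


def opls_permutation(X: pd.DataFrame, y: np.ndarray | pd.Series,
                     n_perm: int = 200, n_orth: int = 1, cv_folds: int = 7,
                     seed: int = 0) -> PermutationResult:
    """Response-permutation validation of an OPLS-DA model.

    Empirical p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ya = np.asarray(y, dtype=float)
    obs = opls_fit(X, ya, n_orth=n_orth, cv_folds=cv_folds, seed=seed)
    r2s, q2s = [], []
    for _ in range(n_perm):
        yp = rng.permutation(ya)
        s = int(rng.integers(2 ** 31 - 1))
        try:
            m = opls_fit(X, yp, n_orth=n_orth, cv_folds=cv_folds, seed=s)
            r2s.append(m.r2y_cum)
            q2s.append(m.q2_cum)
        except ValueError:
            r2s.append(np.nan)
            q2s.append(np.nan)
    r2s, q2s = np.asarray(r2s), np.asarray(q2s)
    p_r2 = (1 + np.nansum(r2s >= obs.r2y_cum)) / (n_perm + 1)
    p_q2 = (1 + np.nansum(q2s >= obs.q2_cum)) / (n_perm + 1)
    return PermutationResult(obs.r2y_cum, obs.q2_cum, r2s, q2s,
                             float(p_r2), float(p_q2))
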