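"""Linking chemomarkers to leaf morphology.

Weighted metabolite co-expression analysis: an unsigned adjacency
|r|^beta with beta picked by the scale-free-fit rule, topological-overlap
similarity, average-linkage module detection (static cut, small clusters
to module 0), module eigenmetabolites, and module-trait Pearson
correlation.  Per-chemotype morphological markers are the traits most
strongly correlated with the module that absorbs most of that chemotype's
up-regulated markers.  Random-forest %IncMSE and cross-validated LASSO
R^2 quantify how predictable each trait is from metabolite abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core_io import TraitTable
from .chemotype import ChemotypeAssignment

#: conventional size-ordered module colour names (module 0 is grey)
MODULE_COLORS = ["turquoise", "blue", "brown", "yellow", "green", "red",
                 "black", "pink", "magenta", "purple", "greenyellow", "tan",
                 "salmon", "cyan", "midnightblue", "lightcyan"]


@dataclass
class ModuleResult:
    """Co-expression modules and their eigenmetabolites."""

    beta: int
    scale_free_fit: float
    module_of: pd.Series                  # feature -> module id (0 = grey)
    module_colors: dict[int, str]
    eigenmetabolites: pd.DataFrame        # collection x module (unit variance)
    module_trait_cor: pd.DataFrame | None = None
    module_trait_p: pd.DataFrame | None = None

    @property
    def module_sizes(self) -> pd.Series:
        return self.module_of[self.module_of > 0].value_counts().sort_index()


def _adjacency(X: np.ndarray, beta: int) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) vs log10 k over connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2), float(res.slope)


DEFAULT_UNSIGNED_POWER = 6


def pick_soft_threshold(X: pd.DataFrame, powers=range(1, 21),
                        fit_min: float = 0.80,
                        min_mean_k: float = 1.0) -> tuple[int, float]:
    """Smallest power whose unsigned network is approximately scale-free.

    For each power the adjacency is |pearson r|^beta; the fit index is the
    R^2 of the log-log degree distribution regression (taken as 0 when the
    slope is non-negative).  A power qualifies only while the network
    retains substance — mean connectivity >= ``min_mean_k`` — because at
    extreme powers the fit index can cross the threshold spuriously on a
    network whose adjacency has all but vanished.  Returns the smallest
    qualifying power with fit >= ``fit_min``.  When none qualifies —
    typical when co-expression is organized in a few comparable-size
    modules, whose degree distribution is bimodal rather than scale-free —
    the conventional unsigned-network default power 6 is used.
    """
    Xa = np.asarray(X, dtype=float)
    for beta in powers:
        a = _adjacency(Xa, beta)
        k = a.sum(axis=0)
        fit, slope = _scale_free_fit(k)
        if slope >= 0:
            fit = 0.0
        if fit >= fit_min and k.mean() >= min_mean_k:
            return int(beta), float(fit)
    beta = DEFAULT_UNSIGNED_POWER
    fit, slope = _scale_free_fit(_adjacency(Xa, beta).sum(axis=0))
    warnings.warn("no soft-threshold power reached the scale-free fit "
                  f"criterion {fit_min:.2f}; using the unsigned default "
                  f"power {beta}")
    return beta, float(fit if slope < 0 else 0.0)


def _tom(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of an adjacency with zero diag."""
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(X: pd.DataFrame, beta: int, min_module_size: int = 10,
                   cut_height: float = 0.99,
                   scale_free_fit: float = np.nan) -> ModuleResult:
    """Cluster features into co-expression modules via TOM dissimilarity.

    Average-linkage tree on 1 - TOM, cut at ``cut_height``; clusters
    smaller than ``min_module_size`` fall into module 0.  Modules are
    renumbered by descending size and named by the conventional colour
    sequence.  Eigenmetabolites are the sign-oriented unit-variance first
    principal components of each module's standardized submatrix.
    """
    Xa = np.asarray(X, dtype=float)
    features = X.columns
    if len(features) < min_module_size:
        module_of = pd.Series(0, index=features, name="module")
        return ModuleResult(beta, scale_free_fit, module_of, {0: "grey"},
                            pd.DataFrame(index=X.index))
    a = _adjacency(Xa, beta)
    dist = 1.0 - _tom(a)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    module_of = pd.Series([mapping.get(c, 0) for c in raw], index=features,
                          name="module")

    colors = {0: "grey"}
    for mid in range(1, len(order) + 1):
        colors[mid] = MODULE_COLORS[(mid - 1) % len(MODULE_COLORS)]

    eig = {}
    for mid in sorted(set(module_of) - {0}):
        eig[mid] = _eigenmetabolite(Xa[:, (module_of == mid).to_numpy()])
    eigen = pd.DataFrame(eig, index=X.index)
    eigen.columns = [f"ME{colors[m]}" for m in eigen.columns]
    return ModuleResult(beta, scale_free_fit, module_of, colors, eigen)


def _eigenmetabolite(sub: np.ndarray) -> np.ndarray:
    """Unit-variance first PC of the standardized submatrix, sign-fixed
    to a positive mean loading."""
    z = sub - sub.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0]
    loadings = np.array([np.corrcoef(z[:, j], scores)[0, 1]
                         for j in range(z.shape[1])])
    if np.nanmean(loadings) < 0:
        scores = -scores
    return scores / scores.std(ddof=0)


def module_trait_correlation(modules: ModuleResult, traits: TraitTable
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p between each eigenmetabolite and trait,
    over collections present in both tables.  Also stored on ``modules``."""
    common = modules.eigenmetabolites.index.intersection(traits.values.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared collections")
    E = modules.eigenmetabolites.loc[common]
    T = traits.values.loc[common]
    r = pd.DataFrame(index=E.columns, columns=T.columns, dtype=float)
    p = r.copy()
    for me in E.columns:
        for tr in T.columns:
            res = stats.pearsonr(E[me], T[tr])
            r.loc[me, tr] = res.statistic
            p.loc[me, tr] = res.pvalue
    modules.module_trait_cor = r
    modules.module_trait_p = p
    return r, p


def select_morph_markers(up_markers: dict[int, list[str]],
                         modules: ModuleResult,
                         cor: pd.DataFrame | None = None,
                         pval: pd.DataFrame | None = None,
                         p_max: float = 0.05) -> pd.DataFrame:
    """Morphological marker per chemotype.

    For each chemotype: the module holding the most of its up-regulated
    chemomarkers, then that module's most strongly correlated trait
    (max |r| among p < ``p_max``).  Chemotypes with no up markers, or
    whose module has no significant trait, report trait ``None``.
    """
    cor = cor if cor is not None else modules.module_trait_cor
    pval = pval if pval is not None else modules.module_trait_p
    if cor is None or pval is None:
        raise ValueError("run module_trait_correlation first")
    rows = []
    for chem in sorted(up_markers):
        feats = [f for f in up_markers[chem] if f in modules.module_of.index]
        mods = modules.module_of.loc[feats]
        mods = mods[mods > 0]
        if len(mods) == 0:
            rows.append({"chemotype": chem, "module": None, "trait": None,
                         "n_markers_in_module": 0, "r": np.nan, "p": np.nan})
            continue
        mid = int(mods.value_counts().idxmax())
        me = f"ME{modules.module_colors[mid]}"
        sig = pval.loc[me] < p_max
        if not sig.any():
            warnings.warn(f"chemotype {chem}: module {me} has no trait with "
                          f"p < {p_max}")
            rows.append({"chemotype": chem, "module": me, "trait": None,
                         "n_markers_in_module": int((mods == mid).sum()),
                         "r": np.nan, "p": np.nan})
            continue
        trait = cor.loc[me][sig].abs().idxmax()
        rows.append({"chemotype": chem, "module": me, "trait": trait,
                     "n_markers_in_module": int((mods == mid).sum()),
                     "r": float(cor.loc[me, trait]),
                     "p": float(pval.loc[me, trait])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait predictability
# ---------------------------------------------------------------------------

def rf_regression_importance(X_module: pd.DataFrame, trait: pd.Series,
                             n_trees: int = 1000, seed: int = 0) -> pd.Series:
    """%IncMSE: mean per-tree percent increase of out-of-bag MSE when a
    feature is permuted (one shared permutation per tree)."""
    Xa = np.ascontiguousarray(np.asarray(X_module, dtype=np.float32))
    y = np.asarray(trait.loc[X_module.index], dtype=float)
    n, p = Xa.shape
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   max_features=max(p // 3, 1), n_jobs=1)
    forest.fit(Xa, y)
    rng = np.random.default_rng(seed)
    inc = np.full((n_trees, p), np.nan)
    for ti, tree in enumerate(forest.estimators_):
        sampled = forest.estimators_samples_[ti]
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        oob = np.flatnonzero(mask)
        if len(oob) == 0:
            continue
        Xo, yo = Xa[oob], y[oob]
        base = float(((tree.predict(Xo) - yo) ** 2).mean())
        if base == 0:
            base = 1e-12
        perm = rng.permutation(len(oob))
        stack = np.repeat(Xo[None, :, :], p, axis=0)
        stack[np.arange(p), :, np.arange(p)] = Xo[perm].T
        preds = tree.predict(stack.reshape(-1, p)).reshape(p, len(oob))
        mse = ((preds - yo[None, :]) ** 2).mean(axis=1)
        inc[ti] = 100.0 * (mse - base) / base
    out = np.nanmean(inc, axis=0)
    return pd.Series(out, index=X_module.columns, name="pct_inc_mse")


@dataclass
class TraitPrediction:
    """LASSO predictability of one trait from metabolite abundances."""

    trait: str
    predictability: float                 # out-of-fold R^2 (can be negative)
    coefficients: pd.Series               # nonzero LASSO coefficients
    alpha: float
    pct_inc_mse: pd.Series | None = None


def _lasso_1se(X: np.ndarray, y: np.ndarray, seed: int,
               inner_folds: int = 10) -> Lasso:
    """Lasso at the one-standard-error lambda from inner cross-validation."""
    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    lcv = LassoCV(cv=cv, alphas=60, random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lcv.fit(X, y)
    mean_mse = lcv.mse_path_.mean(axis=1)
    se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
    i_min = int(np.argmin(mean_mse))
    limit = mean_mse[i_min] + se[i_min]
    # alphas_ are descending; the largest qualifying alpha is the sparsest
    candidates = np.flatnonzero(mean_mse <= limit)
    alpha = float(lcv.alphas_[candidates.min()])
    model = Lasso(alpha=alpha, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def lasso_predictability(X: pd.DataFrame, trait: pd.Series, folds: int = 10,
                         seed: int = 0) -> TraitPrediction:
    """Out-of-fold LASSO R^2 of a trait predicted from the feature matrix.

    Outer ``folds``-fold CV produces held-out predictions; within each
    outer training set the penalty is chosen by inner CV with the 1-SE
    rule.  Predictability = 1 - SSE/SST over the pooled held-out
    predictions; it is not clamped and can be negative.
    """
    y = np.asarray(trait.loc[X.index], dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero-variance trait")
    Xa = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    outer = KFold(n_splits=folds, shuffle=True,
                  random_state=int(rng.integers(2 ** 31 - 1)))
    pred = np.empty_like(y)
    for tr, te in outer.split(Xa):
        model = _lasso_1se(Xa[tr], y[tr], seed=int(rng.integers(2 ** 31 - 1)))
        pred[te] = model.predict(Xa[te])
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst

    final = _lasso_1se(Xa, y, seed=int(rng.integers(2 ** 31 - 1)))
    coefs = pd.Series(final.coef_, index=X.columns)
    return TraitPrediction(trait=str(trait.name), predictability=r2,
                           coefficients=coefs[coefs != 0],
                           alpha=float(final.alpha))


def anova_traits(traits: TraitTable, assignment: ChemotypeAssignment
                 ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA of each trait across chemotypes plus Tukey HSD.

    Returns the per-trait (F, p, per-chemotype means) table and a dict of
    Tukey pairwise-comparison tables keyed by trait.
    """
    common = traits.values.index.intersection(assignment.label_of.index)
    T = traits.values.loc[common]
    labels = assignment.label_of.loc[common]
    rows, tukey = [], {}
    for tr in T.columns:
        groups = [T.loc[labels == c, tr].to_numpy()
                  for c in sorted(labels.unique())]
        f, p = stats.f_oneway(*groups)
        means = {f"mean_chemotype_{c}": T.loc[labels == c, tr].mean()
                 for c in sorted(labels.unique())}
        rows.append({"trait": tr, "F": float(f), "p": float(p), **means})
        res = pairwise_tukeyhsd(T[tr].to_numpy(), labels.to_numpy())
        tukey[tr] = pd.DataFrame(res.summary().data[1:],
                                 columns=res.summary().data[0])
    return pd.DataFrame(rows), tukey
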