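"""Unsupervised chemotype discovery.

Two routes to a sample -> chemotype map over the collection x feature
matrix: (a) K-means with the number of clusters selected by the gap
statistic, and (b) a self-organizing map (default 7x7 rectangular grid,
100 training epochs) whose codebook vectors are themselves clustered into
chemotype groups; each collection is then labelled by its best-matching
unit's group.  Chemotypes are numbered I, II, ... by descending size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

# ---------------------------------------------------------------------------
# gap statistic
# ---------------------------------------------------------------------------


@dataclass
class GapResult:
    """Gap-statistic curve and the selected cluster count."""

    k_range: np.ndarray
    log_wk: np.ndarray
    expected_log_wk: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray
    k_hat: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_range, "log_wk": self.log_wk,
                             "expected_log_wk": self.expected_log_wk,
                             "gap": self.gap, "s_k": self.s_k})


def _within_dispersion(X: np.ndarray, k: int, seed: int,
                       n_init: int = 10) -> float:
    """Total within-cluster sum of squares of the best of ``n_init``
    seeded K-means restarts (for k=1, total sum of squares)."""
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def gap_statistic(X: np.ndarray | pd.DataFrame, k_range=range(1, 11),
                  B: int = 50, seed: int = 0) -> GapResult:
    """Tibshirani gap statistic with a uniform bounding-box reference.

    gap(k) = mean_b log(Wk*_b) - log(Wk).  k is selected by the
    first-SE-max rule (the default of R's cluster::clusGap): locate the
    first local maximum of the gap curve, then take the smallest k whose
    gap is within one s_k of that maximum (ties resolve toward smaller k
    by construction).  The original sequential one-SE rule stalls at k=1
    on symmetric multi-cluster data, where gap(1) ~ gap(2) ~ 0 despite a
    dominant gap peak at the true k.
    """
    X = np.asarray(X, dtype=float)
    ks = np.asarray(list(k_range), dtype=int)
    if X.shape[0] < ks.max() + 1:
        raise ValueError("need more rows than the largest candidate k")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate input: zero variance in every column")
    rng = np.random.default_rng(seed)

    log_wk = np.array([np.log(_within_dispersion(X, k, seed)) for k in ks])

    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        sb = int(rng.integers(2 ** 31 - 1))
        ref[b] = [np.log(_within_dispersion(Xb, k, sb)) for k in ks]
    expected = ref.mean(axis=0)
    s_k = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    gap = expected - log_wk

    loc = len(ks) - 1
    for i in range(len(ks) - 1):
        if gap[i] > gap[i + 1]:
            loc = i
            break
    k_hat = int(ks[loc])
    for i in range(loc + 1):
        if gap[i] >= gap[loc] - s_k[loc]:
            k_hat = int(ks[i])
            break
    return GapResult(ks, log_wk, expected, gap, s_k, k_hat)


# ---------------------------------------------------------------------------
# assignments
# ---------------------------------------------------------------------------

@dataclass
class ChemotypeAssignment:
    """collection -> chemotype labels (contiguous 1..k, size-ordered)."""

    label_of: pd.Series
    method: str
    k: int
    bmu: pd.DataFrame | None = None     # SOM only: bmu_row, bmu_col

    @property
    def sizes(self) -> pd.Series:
        return self.label_of.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"collection_id": self.label_of.index,
                            "chemotype": self.label_of.to_numpy()})
        if self.bmu is not None:
            out["bmu_row"] = self.bmu["bmu_row"].to_numpy()
            out["bmu_col"] = self.bmu["bmu_col"].to_numpy()
        return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by descending size, ties by first
    occurrence in the data."""
    uniq = pd.Series(labels)
    order = sorted(uniq.unique(),
                   key=lambda c: (-(uniq == c).sum(),
                                  int(np.argmax(labels == c))))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def kmeans_classify(X: pd.DataFrame, k: int, seed: int = 0,
                    n_init: int = 10) -> ChemotypeAssignment:
    """Best-of-``n_init`` K-means; labels renumbered by descending size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of collections")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(np.asarray(X, dtype=float))
    labels = _relabel_by_size(raw)
    return ChemotypeAssignment(pd.Series(labels, index=X.index,
                                         name="chemotype"), "kmeans", k)


# ---------------------------------------------------------------------------
# self-organizing map
# ---------------------------------------------------------------------------

@dataclass
class SomModel:
    """Trained SOM: codebook on a rectangular grid plus training diagnostics.

    ``qe`` is the quantization error (mean sample -> best-matching-unit
    distance); ``te`` the topographic error (fraction of samples whose two
    best units are not 4-adjacent on the grid).  The stored codebook is
    the epoch snapshot minimizing qe + te.
    """

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray                  # (rows*cols) x features
    qe: float
    te: float
    trace: pd.DataFrame                   # epoch, qe, te
    node_cluster: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def node_position(self, node: int) -> tuple[int, int]:
        return divmod(node, self.grid_cols)


def _bmu2(X: np.ndarray, codebook: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best and second-best matching units for each row of X."""
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    part = np.argpartition(d2, 1, axis=1)[:, :2]
    first_is_min = d2[np.arange(len(X)), part[:, 0]] <= \
        d2[np.arange(len(X)), part[:, 1]]
    bmu = np.where(first_is_min, part[:, 0], part[:, 1])
    second = np.where(first_is_min, part[:, 1], part[:, 0])
    return bmu, second


def _qe_te(X: np.ndarray, codebook: np.ndarray, rows: int, cols: int
           ) -> tuple[float, float]:
    bmu, second = _bmu2(X, codebook)
    d = np.linalg.norm(X - codebook[bmu], axis=1)
    r1, c1 = np.divmod(bmu, cols)
    r2, c2 = np.divmod(second, cols)
    adjacent = (np.abs(r1 - r2) + np.abs(c1 - c2)) == 1
    return float(d.mean()), float(1.0 - adjacent.mean())


def train_som(X: pd.DataFrame | np.ndarray, rows: int = 7, cols: int = 7,
              n_epochs: int = 100, seed: int = 0,
              init: str = "pca") -> SomModel:
    """Train a rectangular SOM with sequential BMU updates.

    The codebook is initialized on the top-2 principal-component plane
    (deterministic given X; ``init='random'`` samples data rows instead).
    Per epoch, samples are presented in a seeded random order; the
    Gaussian neighbourhood width decays linearly from max(rows, cols)/2
    to 0.1 (an effectively neighbourhood-free fine-tuning phase, so the
    codebook can converge onto the data) and the learning rate from 0.5
    to 0.01.  The (qe, te) pair is recorded after every epoch and the
    returned codebook is the snapshot minimizing qe + te.
    """
    Xa = np.asarray(X, dtype=float)
    if not np.isfinite(Xa).all():
        raise ValueError("input matrix must be finite")
    n, p = Xa.shape
    n_nodes = rows * cols
    rng = np.random.default_rng(seed)

    if init == "pca":
        pca = PCA(n_components=min(2, p, n))
        pca.fit(Xa)
        comps = pca.components_
        sds = np.sqrt(pca.explained_variance_)
        gr = np.linspace(-2, 2, rows)
        gc = np.linspace(-2, 2, cols)
        codebook = np.empty((n_nodes, p))
        for i in range(rows):
            for j in range(cols):
                vec = Xa.mean(axis=0) + gr[i] * sds[0] * comps[0]
                if comps.shape[0] > 1:
                    vec = vec + gc[j] * sds[1] * comps[1]
                codebook[i * cols + j] = vec
    elif init == "random":
        codebook = Xa[rng.choice(n, size=n_nodes, replace=True)].copy()
    else:
        raise ValueError(f"unknown init {init!r}")

    grid = np.array([(i, j) for i in range(rows) for j in range(cols)], float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    sigma0, sigma1 = max(rows, cols) / 2.0, 0.1
    lr0, lr1 = 0.5, 0.01
    best = None
    records = []
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        sigma = sigma0 + (sigma1 - sigma0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        for idx in rng.permutation(n):
            x = Xa[idx]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook += (lr * h)[:, None] * (x - codebook)
        qe, te = _qe_te(Xa, codebook, rows, cols)
        records.append((epoch + 1, qe, te))
        if best is None or qe + te < best[0]:
            best = (qe + te, qe, te, codebook.copy())

    _, qe, te, codebook = best
    trace = pd.DataFrame(records, columns=["epoch", "qe", "te"])
    return SomModel(rows, cols, codebook, qe, te, trace)


def cluster_codebook(model: SomModel, k: int) -> SomModel:
    """Group codebook vectors by average-linkage hierarchical clustering
    (Euclidean), cut at ``k`` groups; sets ``model.node_cluster``."""
    if k > model.n_nodes:
        raise ValueError("k exceeds the number of SOM nodes")
    Z = linkage(model.codebook, method="average", metric="euclidean")
    model.node_cluster = fcluster(Z, t=k, criterion="maxclust")
    return model


def assign_chemotypes(model: SomModel, X: pd.DataFrame) -> ChemotypeAssignment:
    """Label each collection by its BMU's codebook group, renumbered by
    descending group size."""
    if model.node_cluster is None:
        raise ValueError("cluster_codebook must be called first")
    Xa = np.asarray(X, dtype=float)
    bmu, _ = _bmu2(Xa, model.codebook)
    raw = model.node_cluster[bmu]
    labels = _relabel_by_size(raw)
    r, c = np.divmod(bmu, model.grid_cols)
    bmu_df = pd.DataFrame({"bmu_row": r, "bmu_col": c}, index=X.index)
    k = len(np.unique(labels))
    return ChemotypeAssignment(pd.Series(labels, index=X.index,
                                         name="chemotype"), "som", k, bmu_df)
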