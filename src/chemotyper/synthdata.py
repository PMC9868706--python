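"""Synthetic feature/trait tables with planted ground truth.

The generator emulates the statistical structure a leaf-chemotyping study
produces: collections measured in replicate, pooled-QC injections every
``qc_interval`` runs, smooth injection-order drift, abundance-linked
missingness, latent chemotypes with group-specific marker metabolites,
correlated metabolite modules, and morphology traits linearly coupled to
module latent factors.  Every planted quantity is returned as
:class:`GroundTruth` so downstream stages can be scored.

Intensity model (log scale, per biological replicate of collection ``i``
and feature ``j``)::

    log x = b_j + s_c * log(2) * marker_log2fc   (if j marks chemotype c(i))
          + module deviation d_ij
          + replicate noise N(0, noise_sd)

then multiplied by the platform drift factor at the sample's injection
order.  Module deviations share a standard-Gaussian latent factor per
module and collection, with loading sqrt(intra_module_cor) so the planted
intra-module correlation is ``intra_module_cor``.  QC samples are the
arithmetic mean biological profile (a pooled sample) with technical noise
``qc_noise_sd`` only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core_io import FeatureTable, TraitTable, TRAIT_NAMES


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror a mid-sized germplasm screen: 160 collections x 3
    replicates, 600 annotated features, four chemotypes (60/50/30/20)
    each with 25 up-regulated markers at |log2FC| = 1, QC every 10
    injections, 20% injection-order drift amplitude and 15% missing cells.
    """

    n_collections: int = 160
    n_replicates: int = 3
    n_features: int = 600
    n_chemotypes: int = 4
    chemotype_sizes: tuple[int, ...] = (60, 50, 30, 20)
    markers_per_chemotype: int = 25
    marker_log2fc: float = 1.0
    marker_sign: int = 1                  # +1 up-regulated, -1 down
    baseline_log_mean: tuple[float, float] = (9.0, 14.0)  # U[lo,hi] of ln-intensity
    noise_sd: float = 0.2                 # replicate noise, ln scale
    qc_noise_sd: float = 0.05             # QC technical noise, ln scale
    drift_amplitude: float = 0.2
    drift_smoothness: float = 50.0        # decorrelation scale in injections;
    #                                       instrument drift evolves over many
    #                                       QC intervals, so the QC cadence
    #                                       samples it densely
    qc_interval: int = 10
    missing_rate: float = 0.15
    n_modules: int = 0
    module_size: int = 30
    module_sd: float = 0.3                # ln-scale sd of the module deviation
    intra_module_cor: float = 0.5
    markers_in_modules: bool = False      # plant markers inside modules
    #                                       (enables the marker->module->trait
    #                                       chain the trait-linkage stage uses)
    trait_links: tuple[tuple[int, str, float, float], ...] = ()
    trait_noise_sd: float = 1.0           # sd of traits not linked to any module
    platform: str = "lcms_pos"
    seed: int = 1

    def __post_init__(self) -> None:
        if sum(self.chemotype_sizes) != self.n_collections:
            raise ValueError("chemotype_sizes must sum to n_collections")
        if len(self.chemotype_sizes) != self.n_chemotypes:
            raise ValueError("need one size per chemotype")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_modules * self.module_size > self.n_features:
            raise ValueError("modules do not fit into n_features")
        if self.n_chemotypes * self.markers_per_chemotype > self.n_features:
            raise ValueError("markers do not fit into n_features")
        for m, t, _, _ in self.trait_links:
            if t not in TRAIT_NAMES:
                raise ValueError(f"unknown trait {t!r} in trait_links")
            if self.n_modules and m >= self.n_modules:
                raise ValueError(f"trait link refers to missing module {m}")


def demo_config(seed: int = 1) -> SyntheticConfig:
    """Full-story configuration: chemotypes with markers planted inside
    correlated metabolite modules, and six traits coupled to module latent
    factors — the complete marker -> module -> trait chain every pipeline
    stage can be demonstrated on."""
    return SyntheticConfig(
        n_modules=6, module_size=30, markers_in_modules=True,
        trait_links=((0, "LL", 0.6, 0.8), (1, "CRV", 0.6, 0.8),
                     (2, "LDH", 0.6, 0.8), (3, "LT", 0.6, 0.8),
                     (4, "LA", 0.6, 0.8), (5, "LP", 0.6, 0.8)),
        seed=seed)


@dataclass
class GroundTruth:
    """Planted structure: the scoring surface for every pipeline stage."""

    chemotype_of: pd.Series                 # collection -> 1..k
    marker_ids: dict[int, dict[str, int]]   # chemotype -> {feature_id: sign}
    drift_curve: pd.DataFrame               # injection_order x feature factors
    module_of: pd.Series                    # feature -> module id (0 = none)
    trait_coefficients: list[tuple[int, str, float, float]]
    module_factors: pd.DataFrame = None     # collection x module latent factors


def _drift_factors(n_orders: int, n_features: int, amplitude: float,
                   smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive per-feature drift factors, mean 1 over the run.

    Each feature's log-factor mixes a shared monotone+random-walk base
    curve (weight 0.7) with its own smoothed random walk, scaled to unit
    sd and multiplied by ``amplitude``.
    """
    if amplitude == 0 or n_orders < 2:
        return np.ones((n_orders, n_features))

    def _curve(k: int) -> np.ndarray:
        trend = np.linspace(-1.0, 1.0, n_orders)[:, None] * rng.uniform(0.5, 1.5, k)
        walk = gaussian_filter1d(rng.standard_normal((n_orders, k)),
                                 sigma=smoothness, axis=0, mode="nearest")
        c = trend * rng.choice([-1.0, 1.0], k) + walk * 3.0
        c -= c.mean(axis=0)
        sd = c.std(axis=0)
        sd[sd == 0] = 1.0
        return c / sd

    base = _curve(1)
    own = _curve(n_features)
    w = 0.7
    logf = amplitude * (w * base + np.sqrt(1 - w * w) * own)
    f = np.exp(logf)
    return f / f.mean(axis=0, keepdims=True)


def _injection_schedule(n_bio: int, qc_interval: int) -> tuple[np.ndarray, np.ndarray]:
    """Injection orders for biological and QC runs: one QC leads every
    block of ``qc_interval`` biological injections, plus a closing QC."""
    orders, roles = [], []
    order = 1
    for start in range(0, n_bio, qc_interval):
        orders.append(order); roles.append("qc"); order += 1
        for _ in range(start, min(start + qc_interval, n_bio)):
            orders.append(order); roles.append("bio"); order += 1
    orders.append(order); roles.append("qc")
    orders = np.asarray(orders)
    roles = np.asarray(roles)
    return orders[roles == "bio"], orders[roles == "qc"]


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[FeatureTable, TraitTable, GroundTruth]:
    """Generate a feature table, trait table and ground truth from ``config``.

    A pure function of ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_coll, n_rep, p = cfg.n_collections, cfg.n_replicates, cfg.n_features
    n_bio = n_coll * n_rep

    collections = [f"C{i + 1:03d}" for i in range(n_coll)]
    features = [f"F{j + 1:04d}" for j in range(p)]

    # chemotype labels
    labels = np.repeat(np.arange(1, cfg.n_chemotypes + 1), cfg.chemotype_sizes)
    chemotype_of = pd.Series(labels, index=collections, name="chemotype")

    # module membership: first n_modules*module_size features, in blocks
    module_of = np.zeros(p, dtype=int)
    for m in range(cfg.n_modules):
        module_of[m * cfg.module_size:(m + 1) * cfg.module_size] = m + 1

    # markers: disjoint per-chemotype feature sets.  By default they are
    # drawn outside the modules so the chemotype signal is free of shared
    # module-factor noise; with markers_in_modules, chemotype c draws from
    # module ((c-1) mod n_modules), planting the marker->module->trait chain
    marker_ids: dict[int, dict[str, int]] = {}
    marker_effect = np.zeros((cfg.n_chemotypes, p))
    used: set[int] = set()
    for c in range(1, cfg.n_chemotypes + 1):
        if cfg.n_modules and cfg.markers_in_modules:
            pool = np.flatnonzero(module_of == ((c - 1) % cfg.n_modules) + 1)
        elif cfg.n_modules:
            pool = np.flatnonzero(module_of == 0)
        else:
            pool = np.arange(p)
        pool = [j for j in pool if j not in used]
        if len(pool) < cfg.markers_per_chemotype:
            extra = [j for j in range(p) if j not in used and j not in pool]
            pool = pool + extra
        chosen = pool[:cfg.markers_per_chemotype]
        used.update(chosen)
        marker_ids[c] = {features[j]: cfg.marker_sign for j in chosen}
        marker_effect[c - 1, chosen] = cfg.marker_sign * np.log(2.0) * cfg.marker_log2fc

    # baselines and module structure
    b = rng.uniform(*cfg.baseline_log_mean, size=p)
    factors = rng.standard_normal((n_coll, cfg.n_modules)) if cfg.n_modules else \
        np.zeros((n_coll, 0))
    load = np.sqrt(cfg.intra_module_cor)
    uniq = rng.standard_normal((n_coll, p))
    dev = np.empty((n_coll, p))
    for j in range(p):
        m = module_of[j]
        if m:
            dev[:, j] = load * factors[:, m - 1] + np.sqrt(1 - load ** 2) * uniq[:, j]
        else:
            dev[:, j] = uniq[:, j]
    dev *= cfg.module_sd

    # collection-level log profile
    log_mu = b[None, :] + marker_effect[labels - 1] + dev

    # replicate-level biological samples
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_bio, p))
    log_bio = np.repeat(log_mu, n_rep, axis=0) + noise
    bio = np.exp(log_bio)

    # injection schedule and QC profile (pooled mean of biological samples,
    # pre-drift), with technical noise only
    bio_orders, qc_orders = _injection_schedule(n_bio, cfg.qc_interval)
    n_qc = len(qc_orders)
    qc_profile = bio.mean(axis=0)
    qc = qc_profile[None, :] * np.exp(
        rng.normal(0.0, cfg.qc_noise_sd, size=(n_qc, p)))

    # biological samples are injected in randomized order
    order_of_sample = bio_orders[rng.permutation(n_bio)]

    # drift
    n_orders = int(max(bio_orders.max(), qc_orders.max()))
    drift = _drift_factors(n_orders, p, cfg.drift_amplitude,
                           cfg.drift_smoothness, rng)
    bio *= drift[order_of_sample - 1]
    qc *= drift[qc_orders - 1]

    sample_ids = [f"{collections[i // n_rep]}_R{i % n_rep + 1}" for i in range(n_bio)]
    bio_meta = pd.DataFrame({
        "role": "biological",
        "injection_order": order_of_sample,
        "collection_id": np.repeat(collections, n_rep),
        "replicate_id": [f"R{i % n_rep + 1}" for i in range(n_bio)],
        "platform": cfg.platform,
    }, index=sample_ids)
    qc_ids = [f"QC{i + 1:02d}" for i in range(n_qc)]
    qc_meta = pd.DataFrame({
        "role": "qc", "injection_order": qc_orders,
        "collection_id": "QC", "replicate_id": qc_ids,
        "platform": cfg.platform,
    }, index=qc_ids)

    intensities = pd.DataFrame(np.vstack([bio, qc]),
                               index=sample_ids + qc_ids, columns=features)
    meta = pd.concat([bio_meta, qc_meta])

    # missingness: half MCAR, half preferentially in the lowest-intensity decile
    if cfg.missing_rate > 0:
        vals = intensities.to_numpy()
        n_cells = vals.size
        n_mask = int(round(cfg.missing_rate * n_cells))
        n_mcar = n_mask // 2
        flat = rng.choice(n_cells, size=n_mcar, replace=False)
        low = np.argsort(vals, axis=None)[:max(n_cells // 10, n_mask - n_mcar)]
        low = low[~np.isin(low, flat)]
        n_low = min(n_mask - n_mcar, len(low))
        flat = np.concatenate([flat, rng.choice(low, size=n_low, replace=False)])
        vals.flat[flat] = np.nan
        intensities = pd.DataFrame(vals, index=intensities.index,
                                   columns=intensities.columns)

    table = FeatureTable(intensities, meta)

    # traits
    tvals = rng.normal(0.0, cfg.trait_noise_sd, size=(n_coll, len(TRAIT_NAMES)))
    coef = []
    for m, tname, c_eff, sd in cfg.trait_links:
        ti = TRAIT_NAMES.index(tname)
        tvals[:, ti] = c_eff * factors[:, m] + rng.normal(0.0, sd, size=n_coll)
        coef.append((m, tname, c_eff, sd))
    traits = TraitTable(pd.DataFrame(tvals, index=collections, columns=TRAIT_NAMES))

    truth = GroundTruth(
        chemotype_of=chemotype_of,
        marker_ids=marker_ids,
        drift_curve=pd.DataFrame(drift, index=np.arange(1, n_orders + 1),
                                 columns=features),
        module_of=pd.Series(module_of, index=features, name="module"),
        trait_coefficients=coef,
        module_factors=pd.DataFrame(factors, index=collections,
                                    columns=[f"M{m + 1}" for m in
                                             range(cfg.n_modules)]),
    )
    return table, traits, truth


def inject_drift(table: FeatureTable, amplitude: float,
                 smoothness: float = 50.0, seed: int = 0) -> FeatureTable:
    """Multiply each feature by a smooth positive injection-order curve.

    The curve mixes a monotone trend with a low-frequency random walk and
    is normalized to mean factor 1 per feature across the run.
    ``amplitude = 0`` returns the table unchanged.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = table.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    orders = out.sample_meta["injection_order"].to_numpy()
    n_orders = int(orders.max())
    f = _drift_factors(n_orders, out.n_features, amplitude, smoothness, rng)
    out.intensities = out.intensities * f[orders - 1]
    return out


def mask_missing(table: FeatureTable, rate: float, seed: int = 0) -> FeatureTable:
    """Mask exactly ``round(rate * n_cells)`` observed cells MCAR."""
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    vals = out.intensities.to_numpy()
    n_mask = int(round(rate * vals.size))
    idx = rng.choice(vals.size, size=n_mask, replace=False)
    vals.flat[idx] = np.nan
    out.intensities = pd.DataFrame(vals, index=out.intensities.index,
                                   columns=out.intensities.columns)
    return out
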