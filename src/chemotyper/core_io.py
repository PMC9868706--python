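"""Data model and file I/O for feature and trait tables.

The pipeline's universal currency is the :class:`FeatureTable`: a
sample x feature intensity matrix plus per-sample metadata (biological vs
pooled-QC role, injection order, collection/replicate identity, instrument
platform).  Trait tables carry the fixed 13-trait leaf-morphology
vocabulary.  Missing intensities are NaN; zeros are measured values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ["sample_id", "role", "injection_order", "collection_id",
                "replicate_id", "platform"]
ROLES = {"biological", "qc"}
PLATFORMS = {"gcms", "lcms_pos", "lcms_neg", "merged"}

#: Fixed leaf-morphology trait vocabulary: leaf length, length/width ratio,
#: dentate height/width/number, width, area, chlorophyll reference value,
#: perimeter, thickness, stipe length, specific leaf fresh/dry weight.
TRAIT_NAMES = ["LL", "LTWR", "LDH", "LDW", "LDN", "LW", "LA",
               "CRV", "LP", "LT", "SL", "SLFW", "SLDW"]


class ValidationError(ValueError):
    """Input data violates a FeatureTable/TraitTable invariant."""


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


@dataclass
class FeatureTable:
    """Intensity matrix with sample and feature metadata.

    Parameters
    ----------
    intensities
        samples x features, indexed by sample_id / feature_id.  NaN marks a
        missing (undetected) cell; all observed values must be >= 0.
    sample_meta
        One row per sample (same index as ``intensities``), columns
        ``role``, ``injection_order``, ``collection_id``, ``replicate_id``,
        ``platform``.
    feature_meta
        One row per feature (same index as ``intensities.columns``),
        columns ``name`` and ``category``.  Defaults to name = feature_id.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"name": self.intensities.columns,
                 "category": ""},
                index=self.intensities.columns)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        cols = self.intensities.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if not idx.equals(self.sample_meta.index):
            raise ValidationError("sample_meta index does not match intensities")
        missing = [c for c in META_COLUMNS[1:] if c not in self.sample_meta.columns]
        if missing:
            raise SchemaError(f"sample metadata column(s) missing: {missing}")
        bad_roles = set(self.sample_meta["role"]) - ROLES
        if bad_roles:
            raise ValidationError(f"unknown sample role(s): {sorted(bad_roles)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("intensities must be finite or missing (NaN)")
        if (vals < 0).any():
            raise ValidationError("negative intensities are not allowed")
        # injection order unique within a platform
        for plat, grp in self.sample_meta.groupby("platform"):
            order = grp["injection_order"]
            if order.duplicated().any():
                raise ValidationError(
                    f"duplicate injection order on platform {plat!r}")
            if (order <= 0).any():
                raise ValidationError("injection_order must be positive")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def biological_mask(self) -> np.ndarray:
        return (self.sample_meta["role"] == "biological").to_numpy()

    @property
    def qc_mask(self) -> np.ndarray:
        return (self.sample_meta["role"] == "qc").to_numpy()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.sample_meta.copy(),
                            self.feature_meta.copy())

    def equals(self, other: "FeatureTable") -> bool:
        return (self.intensities.equals(other.intensities)
                and self.sample_meta.equals(other.sample_meta))


@dataclass
class TraitTable:
    """Collection x trait matrix over the 13-trait leaf-morphology set."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate collection id {dup!r}")
        unknown = [c for c in self.values.columns if c not in TRAIT_NAMES]
        if unknown:
            raise SchemaError(f"unknown trait column(s): {unknown}")
        if self.values.isna().any().any():
            raise ValidationError("trait table contains missing values")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep(dialect: str) -> str:
    if dialect not in {"csv", "tsv"}:
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def _feature_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".features" + path.suffix)


def read_feature_table(path: str | Path, dialect: str = "csv") -> FeatureTable:
    """Read a feature table (samples as rows, metadata columns first).

    Empty cells become NaN (missing).  A sidecar ``<stem>.features.<ext>``
    file with feature name/category annotations is merged when present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"sample_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata column(s) missing from {path.name}: {missing}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    intensities = df[feature_cols].astype(float)
    sample_meta = df[META_COLUMNS[1:]].copy()
    sample_meta["injection_order"] = sample_meta["injection_order"].astype(int)

    feature_meta = None
    sidecar = _feature_sidecar(path)
    if sidecar.exists():
        fm = pd.read_csv(sidecar, sep=_sep(dialect), index_col="feature_id")
        feature_meta = fm.reindex(intensities.columns)
        feature_meta["name"] = feature_meta["name"].fillna(
            pd.Series(intensities.columns, index=intensities.columns))
        feature_meta["category"] = feature_meta["category"].fillna("")
    return FeatureTable(intensities, sample_meta, feature_meta)


def write_feature_table(table: FeatureTable, path: str | Path,
                        dialect: str = "csv") -> None:
    """Write a feature table plus its feature-annotation sidecar."""
    path = Path(path)
    out = table.sample_meta.copy()
    out.insert(0, "sample_id", out.index)
    out = pd.concat([out, table.intensities], axis=1)
    out.to_csv(path, sep=_sep(dialect), index=False)
    fm = table.feature_meta.copy()
    fm.index.name = "feature_id"
    fm.to_csv(_feature_sidecar(path), sep=_sep(dialect))


def read_trait_table(path: str | Path, dialect: str = "csv") -> TraitTable:
    """Read a collection x trait table; rejects unknown traits and missing cells."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"collection_id": str})
    if "collection_id" not in df.columns:
        raise SchemaError(f"'collection_id' column missing from {path.name}")
    df = df.set_index("collection_id")
    return TraitTable(df.astype(float))


def write_trait_table(table: TraitTable, path: str | Path,
                      dialect: str = "csv") -> None:
    out = table.values.copy()
    out.insert(0, "collection_id", out.index)
    out.to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# platform merging
# ---------------------------------------------------------------------------

#: preference order when QC RSDs tie on a duplicated annotation
_PLATFORM_PRIORITY = {"lcms_pos": 0, "lcms_neg": 1, "merged": 2, "gcms": 3}


def merge_platform_tables(tables: list[FeatureTable],
                          qc_rsd: dict[str, float]) -> FeatureTable:
    """Merge per-platform tables into one table of uniquely-named features.

    Sample ids are suffixed ``@<platform>`` to avoid collisions.  When two
    platforms annotate the same metabolite name, the copy with the lower QC
    RSD (``qc_rsd`` keyed by feature_id) is kept — the more reproducible
    measurement; ties prefer the LC-MS/MS copy.  Provenance of the kept
    copy is recorded in ``feature_meta['source_platform']``.
    """
    if not tables:
        raise ValueError("merge_platform_tables: empty input list")

    frames, metas, feat_meta_rows = [], [], []
    kept: dict[str, tuple[float, int, str]] = {}  # name -> (rsd, prio, fid)
    for t in tables:
        plats = t.sample_meta["platform"].unique()
        plat = plats[0] if len(plats) == 1 else "merged"
        for fid in t.intensities.columns:
            name = t.feature_meta.loc[fid, "name"]
            rsd = float(qc_rsd.get(fid, np.inf))
            cand = (rsd, _PLATFORM_PRIORITY.get(plat, 9), fid)
            if name not in kept or cand < kept[name]:
                kept[name] = cand

    kept_fids = {fid for (_, _, fid) in kept.values()}
    for t in tables:
        plats = t.sample_meta["platform"].unique()
        plat = plats[0] if len(plats) == 1 else "merged"
        cols = [f for f in t.intensities.columns if f in kept_fids]
        ints = t.intensities[cols].copy()
        ints.index = [f"{s}@{p}" for s, p in
                      zip(t.intensities.index, t.sample_meta["platform"])]
        sm = t.sample_meta.copy()
        sm.index = ints.index
        frames.append(ints)
        metas.append(sm)
        fm = t.feature_meta.loc[cols].copy()
        fm["source_platform"] = plat
        feat_meta_rows.append(fm)

    intensities = pd.concat(frames, axis=0).sort_index(axis=0)
    sample_meta = pd.concat(metas, axis=0).loc[intensities.index]
    feature_meta = pd.concat(feat_meta_rows, axis=0)
    intensities = intensities[feature_meta.index]
    return FeatureTable(intensities, sample_meta, feature_meta)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All pipeline stage parameters, serialized next to every run's outputs."""

    seed: int = 1
    # preprocessing
    max_undetected: float = 0.80
    knn_k: int = 10
    rsd_threshold_gcms: float = 0.50
    rsd_threshold_lcms: float = 0.30
    proportion_min: float = 0.70
    n_outliers_removed: int = 3
    screen_outliers: bool = True
    # chemotyping
    som_rows: int = 7
    som_cols: int = 7
    som_epochs: int = 100
    gap_k_max: int = 10
    gap_b: int = 50
    # evaluation
    rf_trees: int = 1000
    train_fraction: float = 0.75
    eval_repeats: int = 20
    opls_n_orth: int = 1
    cv_folds: int = 7
    n_permutations: int = 200
    # marker screening
    vip_min: float = 2.0
    p_max: float = 0.05
    log2fc_min: float = 0.5
    mda_min: float = 2.0
    fc_mode: str = "log2"          # "log2" (|log2FC| rule) or "raw"
    welch: bool = False
    # trait linkage
    scale_free_fit_min: float = 0.80
    min_module_size: int = 10
    cut_height: float = 0.99
    lasso_folds: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the global seed."""
    import zlib
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2 ** 31 - 1)
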