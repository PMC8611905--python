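"""Reading, filtering, imputing, scaling and stacking of multi-omics matrices.

The pipeline consumes one numeric matrix per omics type (samples x features,
TSV/CSV with a header row of feature identifiers and sample identifiers in the
first column) plus a clinical table with survival time in days and an event
indicator (0 = alive/censored, 1 = dead).  Preprocessing follows the order:
feature filter -> sample filter -> KNN imputation -> sample intersection ->
stacking, with model-specific scaling (unit-norm or min-max) applied last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.preprocessing import MinMaxScaler, normalize

logger = logging.getLogger(__name__)


class OmicsType(str, Enum):
    MRNA = "mrna"
    MIRNA = "mirna"
    METHYLATION = "methylation"


@dataclass
class OmicsMatrix:
    """A single omics data type: ``values[i, j]`` is sample i, feature j."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    omics_type: OmicsType

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if p != len(self.feature_ids):
            raise ValueError(f"{p} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique within a matrix")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SurvivalTable:
    """Per-sample survival time (days), event indicator, optional covariates."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.sample_ids) != self.time.shape[0] != self.event.shape[0]:
            raise ValueError("sample_ids, time and event must have equal length")
        if np.any(self.time < 0) or np.any(~np.isfinite(self.time)):
            raise ValueError("survival time must be finite and non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (dead)")

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        """Restrict and reorder to ``sample_ids`` (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        cov = self.covariates.iloc[rows].reset_index(drop=True) if self.covariates is not None else None
        return SurvivalTable(list(sample_ids), self.time[rows], self.event[rows], cov)


@dataclass
class MultiOmicsDataset:
    """Stacked per-patient vector over all omics types, aligned with survival.

    ``block_slices`` maps each omics type to its column range in ``matrix``;
    the blocks partition the columns exactly, in the order
    mRNA | miRNA | methylation.
    """

    matrix: np.ndarray
    block_slices: dict[OmicsType, slice]
    sample_ids: list[str]
    feature_ids: list[str]
    survival: SurvivalTable
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError("matrix shape inconsistent with id lists")
        if self.survival.sample_ids != self.sample_ids:
            raise ValueError("survival rows must align with matrix rows")
        covered = sorted((s.start, s.stop) for s in self.block_slices.values())
        edge = 0
        for start, stop in covered:
            if start != edge:
                raise ValueError("block_slices must partition the columns exactly")
            edge = stop
        if edge != p:
            raise ValueError("block widths must sum to the total feature count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def block(self, omics_type: OmicsType) -> np.ndarray:
        return self.matrix[:, self.block_slices[omics_type]]

    def block_feature_ids(self, omics_type: OmicsType) -> list[str]:
        sl = self.block_slices[omics_type]
        return self.feature_ids[sl.start : sl.stop]

    def with_matrix(self, matrix: np.ndarray, note: str | None = None) -> "MultiOmicsDataset":
        d = MultiOmicsDataset(matrix, dict(self.block_slices), list(self.sample_ids),
                              list(self.feature_ids), self.survival, list(self.log))
        if note:
            d.log.append(note)
        return d


# ---------------------------------------------------------------------------
# readers / writers

def read_omics_matrix(path, omics_type: OmicsType | str, sep: str = "\t") -> OmicsMatrix:
    """Read a samples x features table (header = feature ids, first column = sample ids).

    gzip is handled transparently by pandas based on the file extension.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    return OmicsMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index],
                       [str(f) for f in df.columns], OmicsType(omics_type))


def write_omics_matrix(m: OmicsMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids).to_csv(
        path, sep=sep, index_label="sample_id")


def read_survival_table(path, sep: str = "\t") -> SurvivalTable:
    """Read a clinical table with required columns sample_id, time, event."""
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in required]
    cov = df[extra].reset_index(drop=True) if extra else None
    return SurvivalTable([str(s) for s in df["sample_id"]],
                         df["time"].to_numpy(float), df["event"].to_numpy(int), cov)


def write_survival_table(t: SurvivalTable, path, sep: str = "\t") -> None:
    df = pd.DataFrame({"sample_id": t.sample_ids, "time": t.time, "event": t.event})
    if t.covariates is not None:
        df = pd.concat([df, t.covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# preprocessing

def _bad_mask(values: np.ndarray) -> np.ndarray:
    """Missing-or-zero mask: NaN or exactly 0.0."""
    return np.isnan(values) | (values == 0.0)


def filter_features(m: OmicsMatrix, max_bad_fraction: float = 0.20) -> OmicsMatrix:
    """Drop features that are missing or zero in more than ``max_bad_fraction`` of samples.

    The rule is strictly "more than": a feature bad in exactly 20% of samples
    is retained at the default threshold.  Column order is preserved.
    """
    if not 0.0 < max_bad_fraction < 1.0:
        raise ValueError("max_bad_fraction must lie in (0, 1)")
    bad = _bad_mask(m.values).mean(axis=0)
    keep = bad <= max_bad_fraction
    if not keep.any():
        raise ValueError(f"all {m.n_features} {m.omics_type.value} features failed the "
                         f"missing-or-zero filter (> {max_bad_fraction:.0%})")
    return OmicsMatrix(m.values[:, keep], list(m.sample_ids),
                       [f for f, k in zip(m.feature_ids, keep) if k], m.omics_type)


def filter_samples(m: OmicsMatrix, max_bad_fraction: float = 0.20) -> OmicsMatrix:
    """Drop samples with more than ``max_bad_fraction`` of features missing or zero.

    Applied after :func:`filter_features`; the order matters and is asserted in
    the pipeline.
    """
    if not 0.0 < max_bad_fraction < 1.0:
        raise ValueError("max_bad_fraction must lie in (0, 1)")
    bad = _bad_mask(m.values).mean(axis=1)
    keep = bad <= max_bad_fraction
    if not keep.any():
        raise ValueError(f"no {m.omics_type.value} samples survive the bad-fraction filter")
    removed = [s for s, k in zip(m.sample_ids, keep) if not k]
    if removed:
        logger.info("filter_samples(%s): removed %d samples: %s",
                    m.omics_type.value, len(removed), removed)
    return OmicsMatrix(m.values[keep], [s for s, k in zip(m.sample_ids, keep) if k],
                       list(m.feature_ids), m.omics_type)


def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Fill NaNs from the ``k`` nearest *features* (nan-Euclidean over samples).

    Neighbours are features, not samples, matching the behaviour of the
    gene-wise KNN imputation customary for omics matrices; each missing entry
    becomes the mean of the k nearest features' values in that sample.
    Non-missing entries are returned bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not np.isnan(m.values).any():
        return m
    if np.isnan(m.values).all(axis=0).any():
        raise ValueError("a feature is entirely missing; filter before imputing")
    if np.isnan(m.values).all(axis=1).any():
        raise ValueError("a sample is entirely missing; filter before imputing")
    # transpose so rows are features -> neighbours are features
    imputer = KNNImputer(n_neighbors=min(k, m.n_features - 1), weights="uniform")
    filled = imputer.fit_transform(m.values.T).T
    out = m.values.copy()
    nan_mask = np.isnan(out)
    out[nan_mask] = filled[nan_mask]
    return OmicsMatrix(out, list(m.sample_ids), list(m.feature_ids), m.omics_type)


_BLOCK_ORDER = (OmicsType.MRNA, OmicsType.MIRNA, OmicsType.METHYLATION)


def intersect_and_stack(mrna: OmicsMatrix, mirna: OmicsMatrix, methyl: OmicsMatrix,
                        surv: SurvivalTable) -> MultiOmicsDataset:
    """Keep samples present in all three omics types and the clinical table,
    then concatenate the blocks into one per-patient vector (mRNA | miRNA | methylation).

    Feature ids are qualified with their omics type so the stacked ids stay unique.
    """
    sources = {OmicsType.MRNA: mrna, OmicsType.MIRNA: mirna, OmicsType.METHYLATION: methyl}
    for t, m in sources.items():
        if m.omics_type != t:
            raise ValueError(f"matrix passed as {t.value} is typed {m.omics_type.value}")
        if m.n_samples == 0 or m.n_features == 0:
            raise ValueError(f"{t.value} matrix is empty")
    shared = set(surv.sample_ids)
    for m in sources.values():
        shared &= set(m.sample_ids)
    if not shared:
        counts = {t.value: m.n_samples for t, m in sources.items()}
        counts["survival"] = len(surv.sample_ids)
        raise ValueError(f"no samples shared across all inputs (per-source counts: {counts})")
    # deterministic order: survival-table order restricted to the intersection
    sample_ids = [s for s in surv.sample_ids if s in shared]

    blocks, feature_ids, block_slices, edge = [], [], {}, 0
    for t in _BLOCK_ORDER:
        m = sources[t]
        index = {s: i for i, s in enumerate(m.sample_ids)}
        rows = [index[s] for s in sample_ids]
        blocks.append(m.values[rows])
        feature_ids.extend(f"{t.value}:{f}" for f in m.feature_ids)
        block_slices[t] = slice(edge, edge + m.n_features)
        edge += m.n_features
    return MultiOmicsDataset(np.hstack(blocks), block_slices, sample_ids,
                             feature_ids, surv.subset(sample_ids))


def scale_unit_norm(d: MultiOmicsDataset) -> MultiOmicsDataset:
    """Scale each sample's stacked vector to unit Euclidean norm (zero rows kept)."""
    if np.isnan(d.matrix).any():
        raise ValueError("impute before scaling")
    zero_rows = np.where(~d.matrix.any(axis=1))[0]
    if zero_rows.size:
        logger.warning("scale_unit_norm: %d all-zero rows left as zeros", zero_rows.size)
    return d.with_matrix(normalize(d.matrix, norm="l2"), "scaled: unit-norm per sample")


def scale_minmax(d: MultiOmicsDataset) -> MultiOmicsDataset:
    """Affine-map each feature to [0, 1]; constant features map to 0."""
    if np.isnan(d.matrix).any():
        raise ValueError("impute before scaling")
    return d.with_matrix(MinMaxScaler().fit_transform(d.matrix), "scaled: min-max per feature")


def preprocess(mrna: OmicsMatrix, mirna: OmicsMatrix, methyl: OmicsMatrix,
               surv: SurvivalTable, *, feature_bad_fraction: float = 0.20,
               sample_bad_fraction: float = 0.20, knn_k: int = 10) -> MultiOmicsDataset:
    """Full preprocessing: per-omics feature filter, sample filter, KNN
    imputation, then sample intersection and stacking (scaling is applied
    separately per model variant)."""
    cleaned = []
    for m in (mrna, mirna, methyl):
        m = filter_features(m, feature_bad_fraction)
        m = filter_samples(m, sample_bad_fraction)
        m = knn_impute(m, knn_k)
        cleaned.append(m)
    return intersect_and_stack(*cleaned, surv)
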