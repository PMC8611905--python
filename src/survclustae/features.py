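"""Discovery of original omics features that differentiate clusters, and
cross-run / cross-loss consensus bookkeeping.

Per run: a two-step scaling of the preprocessed (pre-model-scaling) matrix,
a one-way ANOVA of every feature against the cluster labels, then the top 10%
of features per omics type filtered at the Bonferroni threshold P < 0.005
(0.05 corrected for the ten pipeline repetitions).  Across runs, features are
counted by how many of the 10 seeded runs selected them; a feature selected
in all runs is *robust*, and a robust feature of the focal loss not robust
under any comparison loss is *novel*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.preprocessing import RobustScaler, normalize

from .io import MultiOmicsDataset, OmicsType

_EPS = 1e-12


def twostep_scale(d: MultiOmicsDataset, median_norm_axis: str = "feature") -> MultiOmicsDataset:
    """Scaling used before the ANOVA, on the pre-model-scaling matrix.

    Step 1: median-norm scaling of every block — by default each feature is
    divided by its median (epsilon-guarded); ``median_norm_axis='sample'``
    switches to per-sample division.  Step 2: robust scaling (subtract the
    median, divide by the IQR) of the mRNA and methylation blocks, and
    unit-norm (row L2) scaling of the miRNA block.
    """
    if median_norm_axis not in ("feature", "sample"):
        raise ValueError("median_norm_axis must be 'feature' or 'sample'")
    X = d.matrix.copy()
    if median_norm_axis == "feature":
        med = np.median(X, axis=0, keepdims=True)
    else:
        med = np.median(X, axis=1, keepdims=True)
    guarded = np.where(np.abs(med) < _EPS, 1.0, med)
    X = X / guarded

    out = np.empty_like(X)
    for omics in d.block_slices:
        sl = d.block_slices[omics]
        block = X[:, sl]
        if omics is OmicsType.MIRNA:
            out[:, sl] = normalize(block, norm="l2")
        else:
            out[:, sl] = RobustScaler().fit_transform(block)
    return d.with_matrix(out, "scaled: two-step (median-norm + robust/unit-norm)")


@dataclass
class AnovaTable:
    """Per-feature one-way ANOVA results with within-omics P-value ranks."""

    table: pd.DataFrame  # columns: feature, omics_type, F, p_value, rank

    def block(self, omics_type: OmicsType) -> pd.DataFrame:
        return self.table[self.table["omics_type"] == omics_type.value]


def anova_per_feature(d: MultiOmicsDataset, labels: np.ndarray) -> AnovaTable:
    """One-way F test per feature across the cluster labels.

    Constant features (undefined F) are recorded with F = 0, p = 1 so the
    within-omics ranking stays total.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two samples")
    groups = [d.matrix[labels == g] for g in uniq]
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups, axis=0)
    F = np.where(np.isfinite(F), F, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)

    omics_col = np.empty(d.n_features, dtype=object)
    for omics, sl in d.block_slices.items():
        omics_col[sl] = omics.value
    table = pd.DataFrame({"feature": d.feature_ids, "omics_type": omics_col,
                          "F": F, "p_value": p})
    table["rank"] = table.groupby("omics_type")["p_value"].rank(method="first").astype(int)
    return AnovaTable(table)


def top_features(t: AnovaTable, top_fraction: float = 0.10, p_cut: float = 0.005
                 ) -> dict[str, set[str]]:
    """Per omics type: the floor(top_fraction * n) smallest-P features, kept
    only if P < p_cut (the Bonferroni threshold for ten runs)."""
    out: dict[str, set[str]] = {}
    for omics_value, block in t.table.groupby("omics_type"):
        pool = int(np.floor(top_fraction * len(block)))
        chosen = block[block["rank"] <= pool]
        out[omics_value] = set(chosen.loc[chosen["p_value"] < p_cut, "feature"])
    return out


def bonferroni_cut(n_runs: int = 10, alpha: float = 0.05) -> float:
    """The multiple-testing threshold for the configured number of pipeline
    repetitions (0.005 at the default ten)."""
    return alpha / n_runs


@dataclass
class ConsensusReport:
    """Cross-run feature-frequency summary per omics type."""

    n_runs: int
    counts: dict[str, dict[str, int]]  # omics -> feature -> run count

    def at_least(self, threshold: int) -> dict[str, set[str]]:
        return {omics: {f for f, c in feats.items() if c >= threshold}
                for omics, feats in self.counts.items()}

    @property
    def robust(self) -> dict[str, set[str]]:
        """Features selected in every run."""
        return self.at_least(self.n_runs)

    def summary(self, thresholds: tuple[int, ...] = (6, 8, 10)) -> pd.DataFrame:
        rows = [{"omics_type": omics,
                 **{f">={t}" if t < self.n_runs else f"=={t}": len(feats)
                    for t, feats in ((t, self.at_least(t)[omics]) for t in thresholds)}}
                for omics in self.counts]
        return pd.DataFrame(rows)


def consensus(per_run_sets: list[dict[str, set[str]]], n_runs: int = 10) -> ConsensusReport:
    """Count, per omics type, how many runs selected each feature."""
    if len(per_run_sets) != n_runs:
        raise ValueError(f"expected {n_runs} runs, got {len(per_run_sets)}")
    counts: dict[str, dict[str, int]] = {}
    for run in per_run_sets:
        for omics, feats in run.items():
            bucket = counts.setdefault(omics, {})
            for f in feats:
                bucket[f] = bucket.get(f, 0) + 1
    return ConsensusReport(n_runs=n_runs, counts=counts)


def novelty(focal: ConsensusReport, others: list[ConsensusReport]) -> dict[str, set[str]]:
    """Focal robust features absent from every comparison loss's robust set."""
    focal_robust = focal.robust
    out: dict[str, set[str]] = {}
    for omics, feats in focal_robust.items():
        union: set[str] = set()
        for rep in others:
            union |= rep.robust.get(omics, set())
        out[omics] = feats - union
    return out


def zscore_matrix(d: MultiOmicsDataset, features: list[str], labels: np.ndarray,
                  clip: float = 3.0) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-feature z-scores of the selected features, clipped to [-clip, clip],
    with samples ordered by cluster label — the matrix behind the heatmaps.
    Returns (features x samples frame, sample order)."""
    index = {f: i for i, f in enumerate(d.feature_ids)}
    missing = [f for f in features if f not in index]
    if missing:
        raise KeyError(f"unknown feature ids: {missing[:5]}")
    cols = [index[f] for f in features]
    X = d.matrix[:, cols]
    sd = X.std(axis=0, ddof=0)
    constant = sd < _EPS
    sd = np.where(constant, 1.0, sd)
    Z = np.clip((X - X.mean(axis=0)) / sd, -clip, clip)
    Z[:, constant] = 0.0
    order = np.argsort(np.asarray(labels), kind="stable")
    frame = pd.DataFrame(Z[order].T, index=features,
                         columns=[d.sample_ids[i] for i in order])
    return frame, order
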