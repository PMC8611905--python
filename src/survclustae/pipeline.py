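"""End-to-end orchestration: train each loss regime over seeded runs, label
prognostic subgroups, score them, discover differentiating omics features and
aggregate the cross-run / cross-loss comparison report.

Per the fixed pairing, BCE and MSE train the baseline architecture on the
unit-norm-scaled matrix and their bottlenecks are Cox-filtered before k-means;
the hybrid losses train the custom architecture on the min-max-scaled matrix.
L_RS clusters all 100 bottleneck features with k-means; L_RC and L_RSC take
their labels from the final training centroids.  The best run per loss is the
one with the smallest pairwise log-rank P (ties broken by silhouette).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterResult, labels_from_centroids, select_k
from .features import (AnovaTable, ConsensusReport, anova_per_feature, bonferroni_cut,
                       consensus, novelty, top_features, twostep_scale)
from .io import MultiOmicsDataset, scale_minmax, scale_unit_norm
from .losses import LossName, LossSpec
from .network import ArchitectureSpec, TrainingState, build, encode, train
from .survival import filter_bottleneck, min_pairwise_logrank_p

logger = logging.getLogger(__name__)

DEFAULT_LOSSES = (LossName.BCE, LossName.MSE, LossName.L_RC, LossName.L_RS, LossName.L_RSC)


@dataclass
class RunConfig:
    """Configuration shared by all runs of one comparison."""

    losses: tuple[LossName, ...] = DEFAULT_LOSSES
    seeds: tuple[int, ...] = tuple(range(10))
    k_range: tuple[int, int] = (2, 5)
    cox_alpha: float = 0.05
    top_fraction: float = 0.10
    epochs: dict[str, int] | None = None  # per-loss override
    median_norm_axis: str = "feature"
    out_dir: str | Path | None = None

    @property
    def p_cut(self) -> float:
        return bonferroni_cut(len(self.seeds))

    def epochs_for(self, loss: LossName) -> int | None:
        if self.epochs is None:
            return None
        return self.epochs.get(loss.value)


@dataclass
class RunResult:
    """Everything one seeded run produces."""

    loss: LossName
    seed: int
    bottleneck: np.ndarray
    cluster: ClusterResult
    logrank_p: float
    anova: AnovaTable
    top_sets: dict[str, set[str]]
    state: TrainingState
    n_cox_features: int | None = None  # baselines only

    @property
    def silhouette(self) -> float:
        return self.cluster.silhouette

    def summary(self) -> dict:
        return {
            "loss": self.loss.value,
            "seed": self.seed,
            "k": self.cluster.k,
            "cluster_sizes": self.cluster.sizes,
            "silhouette": round(self.cluster.silhouette, 10),
            "logrank_p": self.logrank_p,
            "n_cox_features": self.n_cox_features,
            "n_top_features": {o: len(s) for o, s in sorted(self.top_sets.items())},
            "epochs": self.state.epoch,
        }


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_one(dataset: MultiOmicsDataset, loss: LossName | str, seed: int,
            cfg: RunConfig | None = None) -> RunResult:
    """Execute one seeded run of one loss regime on a preprocessed dataset.

    ``dataset`` is the stacked, imputed, *unscaled* matrix; the run applies
    the variant-appropriate scaling itself.
    """
    cfg = cfg or RunConfig()
    loss = LossName(loss)
    spec = LossSpec.default(loss)
    arch = ArchitectureSpec.for_loss(loss, epochs=cfg.epochs_for(loss))

    with _stage("scale"):
        scaled = scale_unit_norm(dataset) if arch.variant.value == "baseline" \
            else scale_minmax(dataset)
    with _stage("train"):
        state = build(arch, dataset.n_features, seed)
        train(state, scaled, spec)
    with _stage("encode"):
        bottleneck = encode(state, scaled)

    n_cox = None
    with _stage("cluster"):
        if loss in (LossName.BCE, LossName.MSE):
            kept, _table = filter_bottleneck(bottleneck, dataset.survival, cfg.cox_alpha)
            n_cox = int(kept.size)
            cluster = select_k(bottleneck[:, kept], cfg.k_range, seed)
        elif loss is LossName.L_RS:
            cluster = select_k(bottleneck, cfg.k_range, seed)
        else:
            assert state.centroid_state is not None
            cluster = labels_from_centroids(bottleneck, state.centroid_state)

    with _stage("logrank"):
        if len(np.unique(cluster.labels)) > 1:
            logrank_p = min_pairwise_logrank_p(dataset.survival, cluster.labels)
        else:
            logrank_p = float("nan")

    with _stage("discover"):
        counts = np.bincount(cluster.labels)
        if (counts[counts > 0] >= 2).all() and len(np.unique(cluster.labels)) > 1:
            rescaled = twostep_scale(dataset, cfg.median_norm_axis)
            anova = anova_per_feature(rescaled, cluster.labels)
            top_sets = top_features(anova, cfg.top_fraction, cfg.p_cut)
        else:  # degenerate clustering: no per-feature contrast is defined
            anova = AnovaTable(pd.DataFrame(
                columns=["feature", "omics_type", "F", "p_value", "rank"]))
            top_sets = {o.value: set() for o in dataset.block_slices}

    result = RunResult(loss=loss, seed=seed, bottleneck=bottleneck, cluster=cluster,
                       logrank_p=logrank_p, anova=anova, top_sets=top_sets,
                       state=state, n_cox_features=n_cox)
    if cfg.out_dir is not None:
        _write_run(result, dataset, Path(cfg.out_dir) / loss.value / f"seed_{seed}")
    return result


def _write_run(r: RunResult, dataset: MultiOmicsDataset, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"sample_id": dataset.sample_ids, "cluster": r.cluster.labels}
                 ).to_csv(run_dir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(r.state.trace).to_csv(run_dir / "trace.csv", index=False)
    if len(r.anova.table):
        r.anova.table.to_csv(run_dir / "anova.tsv", sep="\t", index=False)
    (run_dir / "summary.json").write_text(json.dumps(r.summary(), indent=1, sort_keys=True))


@dataclass
class ComparisonReport:
    """Per-loss metric ranges, best runs and consensus/novelty counts."""

    per_loss: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"per_loss": self.per_loss, "failures": self.failures},
                          indent=1, sort_keys=True)


def run_all(dataset: MultiOmicsDataset, cfg: RunConfig | None = None
            ) -> tuple[ComparisonReport, dict[str, list[RunResult]]]:
    """All configured losses x seeds, plus the comparison report.

    Any individual run failure is recorded and the report stays partial.
    """
    cfg = cfg or RunConfig()
    if len(cfg.seeds) < 2:
        raise ValueError("run_all needs at least two seeds")
    results: dict[str, list[RunResult]] = {}
    cons_by_loss: dict[str, ConsensusReport] = {}
    report = ComparisonReport()
    for loss in cfg.losses:
        loss = LossName(loss)
        runs: list[RunResult] = []
        for seed in cfg.seeds:
            try:
                runs.append(run_one(dataset, loss, seed, cfg))
            except Exception as exc:  # enumerate failures, keep going
                report.failures.setdefault(loss.value, []).append(f"seed {seed}: {exc}")
        results[loss.value] = runs
        if not runs:
            continue
        cons = consensus([r.top_sets for r in runs], n_runs=len(cfg.seeds)) \
            if len(runs) == len(cfg.seeds) else None
        best = min(runs, key=lambda r: (r.logrank_p if np.isfinite(r.logrank_p) else np.inf,
                                        -r.silhouette))
        sils = [r.silhouette for r in runs]
        ps = [r.logrank_p for r in runs if np.isfinite(r.logrank_p)]
        n_runs = len(cfg.seeds)
        # frequency thresholds at 60%, 80% and 100% of runs (6/8/10 of ten)
        thresholds = sorted({int(np.ceil(0.6 * n_runs)), int(np.ceil(0.8 * n_runs)), n_runs})
        report.per_loss[loss.value] = {
            "silhouette_highest": max(sils),
            "silhouette_lowest": min(sils),
            "logrank_p_lowest": min(ps) if ps else None,
            "logrank_p_highest": max(ps) if ps else None,
            "best_seed": best.seed,
            "best_cluster_sizes": best.cluster.sizes,
            "consensus_thresholds": thresholds,
            "consensus_counts": {o: [len(cons.at_least(t)[o]) for t in thresholds]
                                 for o in cons.counts} if cons else None,
        }
        if cons is not None:
            cons_by_loss[loss.value] = cons

    # cross-loss novelty on the consensus reports
    for name, rep in cons_by_loss.items():
        others = [r for n, r in cons_by_loss.items() if n != name]
        nov = novelty(rep, others)
        report.per_loss[name]["novel_counts"] = {o: len(s) for o, s in sorted(nov.items())}

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison_report.json").write_text(report.to_json())
    return report, results
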