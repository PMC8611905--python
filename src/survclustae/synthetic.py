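"""Seeded multi-omics simulator with planted prognostic subgroups.

Samples belong to one of k latent subgroups.  Subgroup membership shifts the
mean of a disjoint set of informative features in every omics block and
multiplies the exponential event hazard, so both the clustering signal and the
survival signal trace back to the same ground truth.  Censoring is an
independent exponential clock.  Feature values sit on a positive scale
(baseline level 6, unit noise SD), emulating non-negative expression /
methylation summaries so that downstream unit-norm scaling lands in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import MultiOmicsDataset, OmicsMatrix, OmicsType, SurvivalTable, intersect_and_stack

_BASELINE_LEVEL = 6.0  # keeps values positive, expression-like
_BLOCK_ORDER = (OmicsType.MRNA, OmicsType.MIRNA, OmicsType.METHYLATION)


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated cohort.

    effect_size is the between-cluster mean shift in units of the noise SD;
    hazards are rates per day.
    """

    n_samples: int = 120
    block_widths: tuple[int, int, int] = (300, 30, 300)
    n_clusters: int = 2
    informative_per_block: tuple[int, int, int] = (20, 3, 20)
    effect_size: float = 3.0
    baseline_hazard: float = 1e-3
    hazard_ratio_per_cluster: tuple[float, ...] = (1.0, 5.0)
    censoring_rate: float = 2.5e-4
    missing_fraction: float = 0.0
    zero_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if len(self.hazard_ratio_per_cluster) != self.n_clusters:
            raise ValueError("need one hazard ratio per cluster")
        if self.baseline_hazard <= 0 or any(h <= 0 for h in self.hazard_ratio_per_cluster):
            raise ValueError("hazard rates must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        for frac in (self.missing_fraction, self.zero_fraction):
            if not 0.0 <= frac < 1.0:
                raise ValueError("fractions must lie in [0, 1)")
        for width, k in zip(self.block_widths, self.informative_per_block):
            if k > width:
                raise ValueError("informative_per_block cannot exceed the block width")


@dataclass
class SyntheticTruth:
    """Ground truth withheld from the emitted dataset (no leakage)."""

    cluster_labels: np.ndarray
    informative_feature_ids: dict[str, list[str]]
    true_event_times: np.ndarray

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"cluster_labels": self.cluster_labels.tolist(),
                       "informative_feature_ids": self.informative_feature_ids,
                       "true_event_times": self.true_event_times.tolist()}, fh, indent=1)


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.resize(np.arange(k), n)
    return rng.permutation(labels)


def generate(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Simulate one cohort; fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_clusters
    labels = _balanced_labels(n, k, rng)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    matrices: list[OmicsMatrix] = []
    informative: dict[str, list[str]] = {}
    for omics, width, n_info in zip(_BLOCK_ORDER, spec.block_widths, spec.informative_per_block):
        values = rng.normal(_BASELINE_LEVEL, 1.0, size=(n, width))
        info_cols = np.sort(rng.choice(width, size=n_info, replace=False))
        # cluster c shifts informative means by c * effect_size (noise SD = 1)
        values[:, info_cols] += spec.effect_size * labels[:, None]
        feature_ids = [f"{omics.value[:4]}_f{j:05d}" for j in range(width)]
        informative[omics.value] = [feature_ids[j] for j in info_cols]

        n_zero = int(round(spec.zero_fraction * values.size))
        if n_zero:
            flat = rng.choice(values.size, size=n_zero, replace=False)
            values.ravel()[flat] = 0.0
        n_miss = int(round(spec.missing_fraction * values.size))
        if n_miss:
            flat = rng.choice(values.size, size=n_miss, replace=False)
            values.ravel()[flat] = np.nan
        matrices.append(OmicsMatrix(values, list(sample_ids), feature_ids, omics))

    rates = spec.baseline_hazard * np.asarray(spec.hazard_ratio_per_cluster)[labels]
    event_times = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0:
        censor_times = rng.exponential(1.0 / spec.censoring_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    surv = SurvivalTable(list(sample_ids), observed, event)

    dataset = intersect_and_stack(*matrices, surv)
    truth = SyntheticTruth(labels, informative, event_times)
    return dataset, truth


EASY_FIXTURE_SEED = 7


def easy_fixture(seed: int = EASY_FIXTURE_SEED) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Small canonical cohort used across the test suite: 120 samples,
    blocks 300/30/300, two subgroups at effect size 3 with hazard ratios 1 and 5."""
    return generate(SyntheticSpec(seed=seed))


def write_dataset(dataset: MultiOmicsDataset, truth: SyntheticTruth, out_dir) -> None:
    """Emit the three omics TSVs, the clinical TSV and the truth JSON."""
    from pathlib import Path

    from .io import write_omics_matrix, write_survival_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for omics in _BLOCK_ORDER:
        sl = dataset.block_slices[omics]
        ids = [f.split(":", 1)[1] for f in dataset.feature_ids[sl.start:sl.stop]]
        write_omics_matrix(OmicsMatrix(dataset.block(omics), list(dataset.sample_ids), ids, omics),
                           out / f"{omics.value}.tsv")
    write_survival_table(dataset.survival, out / "clinical.tsv")
    truth.to_json(out / "truth.json")
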