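"""Training objectives: reconstruction, binary cross-entropy, k-means-style
clustering, Cox partial-likelihood survival loss, and their weighted hybrids.

Conventions that matter for the loss-weight balance:

* the reconstruction loss averages the *per-sample squared Euclidean norm*
  over samples — NOT the element mean.  It therefore differs from the common
  framework MSE by a factor of the feature count, and the alpha/beta/gamma
  weights below are calibrated against this convention;
* the survival loss function here is the *unnormalised* negative Cox partial
  log-likelihood, with Breslow handling of tied event times, so its magnitude
  grows with the number of events; the training loop averages it over the
  batch (the usual deep-learning reduction) so that the weighted combination
  with the other per-sample-mean terms does not depend on cohort size.

Default hybrid weights: L_RC / L_RS use alpha=0.25, beta=0.75;
L_RSC uses alpha=0.25, beta=0.50, gamma=0.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

BCE_EPS = 1e-7


class LossName(str, Enum):
    BCE = "bce"
    MSE = "mse"
    L_RC = "l_rc"
    L_RS = "l_rs"
    L_RSC = "l_rsc"

    @property
    def uses_clustering(self) -> bool:
        return self in (LossName.L_RC, LossName.L_RSC)

    @property
    def uses_survival(self) -> bool:
        return self in (LossName.L_RS, LossName.L_RSC)


_DEFAULT_WEIGHTS = {
    LossName.BCE: dict(alpha=1.0, beta=0.0, gamma=0.0),
    LossName.MSE: dict(alpha=1.0, beta=0.0, gamma=0.0),
    LossName.L_RC: dict(alpha=0.25, beta=0.0, gamma=0.75),
    LossName.L_RS: dict(alpha=0.25, beta=0.75, gamma=0.0),
    LossName.L_RSC: dict(alpha=0.25, beta=0.50, gamma=0.25),
}


@dataclass(frozen=True)
class LossSpec:
    """Which loss terms are active and their weights.

    alpha weighs reconstruction, beta the survival term and gamma the
    clustering term.  For L_RC the clustering weight is conventionally called
    beta in two-term notation; here it is always carried in ``gamma`` so the
    three-term hybrid needs no special casing.
    """

    name: LossName
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def default(cls, name: LossName | str) -> "LossSpec":
        name = LossName(name)
        return cls(name=name, **_DEFAULT_WEIGHTS[name])


@dataclass
class CentroidState:
    """Current cluster centroids in bottleneck space and sample assignments."""

    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) ints in [0, k)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.k < 2:
            raise ValueError("need at least two centroids")
        if self.assignments.min(initial=0) < 0 or self.assignments.max(initial=0) >= self.k:
            raise ValueError("assignments must index existing centroids")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def nearest_two_centroids(b: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the nearest (mu) and second-nearest (lambda) centroid per row.

    Ties break to the lower centroid index (argsort is stable on equal keys).
    """
    d2 = ((b[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, 0], order[:, 1]


@dataclass
class SurvivalOrder:
    """Samples sorted by descending observed time, with Breslow risk sets.

    ``risk_stop[i]`` is the exclusive end of the risk set of sample i in the
    sorted order: all samples with observed time >= t_i, i.e. the prefix up to
    and including i's tie group.
    """

    permutation: np.ndarray  # original index of each sorted position
    time: np.ndarray  # descending
    event: np.ndarray
    risk_stop: np.ndarray

    @classmethod
    def from_survival(cls, time: np.ndarray, event: np.ndarray) -> "SurvivalOrder":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        # stable sort on -time keeps original order within ties
        perm = np.argsort(-time, kind="stable")
        t = time[perm]
        n = t.shape[0]
        risk_stop = np.empty(n, dtype=int)
        j = 0
        for i in range(n):
            if j <= i:
                j = i + 1
            while j < n and t[j] == t[i]:
                j += 1
            risk_stop[i] = j
        return cls(perm, t, event[perm], risk_stop)

    @property
    def n(self) -> int:
        return self.time.shape[0]


# ---------------------------------------------------------------------------
# loss terms

def loss_reconstruction(x: np.ndarray, x_hat: np.ndarray) -> float:
    """(1/n) sum_i ||x_i - x_hat_i||^2 — mean over samples of the per-sample
    squared reconstruction error."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    diff = x - x_hat
    return float(np.einsum("ij,ij->", diff, diff) / x.shape[0])


def loss_bce(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Element-mean binary cross-entropy; x must lie in [0, 1], x_hat is
    clipped to [BCE_EPS, 1 - BCE_EPS]."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("BCE targets must lie in [0, 1]")
    p = np.clip(x_hat, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(x * np.log(p) + (1.0 - x) * np.log1p(-p)))


def loss_clustering(b: np.ndarray, cs: CentroidState) -> float:
    """(1/n){ sum_i ||b_i - mu_i||^2 - sum_i ||b_i - lambda_i||^2 } with mu_i
    the nearest and lambda_i the second-nearest centroid; may be negative and
    decreases as clusters tighten and separate."""
    b = np.asarray(b, float)
    if cs.assignments.shape[0] != b.shape[0]:
        raise ValueError("assignments must cover every bottleneck row")
    mu_idx, lam_idx = nearest_two_centroids(b, cs.centroids)
    near = ((b - cs.centroids[mu_idx]) ** 2).sum()
    second = ((b - cs.centroids[lam_idx]) ** 2).sum()
    return float((near - second) / b.shape[0])


def loss_survival(scores: np.ndarray, order: SurvivalOrder) -> float:
    """Negative Cox partial log-likelihood (Breslow ties, unnormalised):

        - sum_i delta_i { s_i - log sum_{j in R(t_i)} exp(s_j) }

    ``scores`` must already be aligned with ``order``'s sorted permutation.
    Computed with a max-shifted running log-sum-exp over the descending-time
    ordering, so large |scores| do not overflow.
    """
    s = np.asarray(scores, float).ravel()
    if s.shape[0] != order.n:
        raise ValueError("scores must align with the survival ordering")
    if order.n == 0:
        raise ValueError("need at least one sample")
    m = s.max()
    cum = np.cumsum(np.exp(s - m))
    log_risk = m + np.log(cum[order.risk_stop - 1])
    delta = order.event.astype(float)
    return float(-(delta * (s - log_risk)).sum())


def loss_survival_gradient(scores: np.ndarray, order: SurvivalOrder) -> np.ndarray:
    """d L_S / d s_j in the sorted order (used by the training loop).

    grad_j = -delta_j + exp(s_j) * sum_{i : j in R(t_i)} delta_i / S_i
    where S_i = sum_{k in R(t_i)} exp(s_k); j is in R(t_i) iff
    risk_stop[i] > j, i.e. i's tie-group prefix covers j.
    """
    s = np.asarray(scores, float).ravel()
    m = s.max()
    e = np.exp(s - m)
    cum = np.cumsum(e)
    S = cum[order.risk_stop - 1]  # scaled by exp(-m), cancels below
    delta = order.event.astype(float)
    # weight_j = sum over events i whose risk set covers position j of 1/S_i;
    # event i covers positions [0, risk_stop[i]) -> difference-array prefix sum
    n = order.n
    contrib = delta / S
    diff = np.zeros(n + 1)
    diff[0] = contrib.sum()
    np.subtract.at(diff, order.risk_stop, contrib)
    weight = np.cumsum(diff[:-1])
    return -delta + e * weight


def combine(spec: LossSpec, lr: float | None = None, ls: float | None = None,
            lc: float | None = None) -> float:
    """Weighted sum of the loss terms active for ``spec.name``.

    For BCE/MSE ``lr`` is the sole (reconstruction) term, returned unweighted
    by convention alpha=1.
    """
    name = spec.name
    if lr is None:
        raise ValueError("reconstruction term is required by every loss")
    total = spec.alpha * lr
    if name.uses_survival:
        if ls is None:
            raise ValueError(f"{name.value} requires the survival term")
        total += spec.beta * ls
    if name.uses_clustering:
        if lc is None:
            raise ValueError(f"{name.value} requires the clustering term")
        total += spec.gamma * lc
    return float(total)
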