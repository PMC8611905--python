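"""Autoencoder architectures and the centroid/survival-aware training loop.

Two feed-forward architectures share a 100-unit bottleneck:

* ``baseline`` — widths 500/100/500, tanh throughout, dropout 0.5 on the wide
  hidden layers, L1 kernel penalty 1e-3, L2 activity penalty 1e-4 on the
  output, SGD with batch size 1 for 10 epochs;
* ``custom`` — widths 1000/100/1000, sigmoid throughout, L1 kernel penalty
  1e-3, Adam with a single full-batch gradient step per epoch for 40 epochs,
  plus an optional linear survival branch (bottleneck -> 1 score, no bias,
  no activation) whose output feeds the Cox partial-likelihood loss.

The training loop implements the bespoke procedure: when the clustering term
is active, a one-epoch reconstruction-only warm-up seeds two centroids at the
farthest-apart bottleneck vectors, and after every epoch centroids are reset
to their group means and samples reassigned to the nearest centroid; when the
survival term is active, samples are presented in descending order of
observed survival time and never shuffled.  Centroids are treated as
constants within an epoch.  Everything is plain numpy with hand-written
backpropagation; runs are bit-reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .io import MultiOmicsDataset
from .losses import (BCE_EPS, CentroidState, LossName, LossSpec, SurvivalOrder,
                     loss_bce, loss_clustering, loss_reconstruction, loss_survival,
                     loss_survival_gradient, nearest_two_centroids)

BOTTLENECK_DIM = 100
FULL_BATCH = 0  # sentinel: one gradient step per epoch over all samples


class Activation(str, Enum):
    TANH = "tanh"
    SIGMOID = "sigmoid"


class Optimizer(str, Enum):
    SGD = "sgd"
    ADAM = "adam"


class Variant(str, Enum):
    BASELINE = "baseline"
    CUSTOM = "custom"


@dataclass(frozen=True)
class ArchitectureSpec:
    variant: Variant
    hidden_dims: tuple[int, int, int]
    activation: Activation
    dropout: float
    l1_kernel: float
    l2_activity: float
    optimizer: Optimizer
    batch_size: int  # FULL_BATCH (0) or a positive count
    epochs: int
    has_survival_branch: bool
    learning_rate: float

    @classmethod
    def baseline(cls, epochs: int = 10, learning_rate: float = 0.01) -> "ArchitectureSpec":
        return cls(Variant.BASELINE, (500, 100, 500), Activation.TANH, dropout=0.5,
                   l1_kernel=1e-3, l2_activity=1e-4, optimizer=Optimizer.SGD,
                   batch_size=1, epochs=epochs, has_survival_branch=False,
                   learning_rate=learning_rate)

    @classmethod
    def custom(cls, epochs: int = 40, learning_rate: float = 1e-3,
               has_survival_branch: bool = False) -> "ArchitectureSpec":
        return cls(Variant.CUSTOM, (1000, 100, 1000), Activation.SIGMOID, dropout=0.0,
                   l1_kernel=1e-3, l2_activity=0.0, optimizer=Optimizer.ADAM,
                   batch_size=FULL_BATCH, epochs=epochs, has_survival_branch=has_survival_branch,
                   learning_rate=learning_rate)

    @classmethod
    def for_loss(cls, loss: LossName | str, epochs: int | None = None) -> "ArchitectureSpec":
        """The fixed loss -> architecture pairing: BCE/MSE train the baseline
        variant, the hybrid losses train the custom variant."""
        loss = LossName(loss)
        if loss in (LossName.BCE, LossName.MSE):
            return cls.baseline(epochs=epochs or 10)
        return cls.custom(epochs=epochs or 40, has_survival_branch=loss.uses_survival)


@dataclass
class TrainingState:
    """Parameters and bookkeeping for one training run."""

    arch: ArchitectureSpec
    weights: list[np.ndarray]  # kernel per dense layer
    biases: list[np.ndarray]
    survival_w: np.ndarray | None  # (bottleneck,) linear branch, no bias
    seed: int
    centroid_state: CentroidState | None = None
    presentation_order: np.ndarray | None = None  # fixed; never reshuffled
    epoch: int = 0
    trace: list[dict] = field(default_factory=list)
    _adam: dict = field(default_factory=dict, repr=False)

    @property
    def bottleneck_index(self) -> int:
        # activations: [x, h1, bottleneck, h3, x_hat]
        return (len(self.weights) // 2)


def _act(z: np.ndarray, kind: Activation) -> np.ndarray:
    if kind is Activation.TANH:
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))


def _act_deriv(a: np.ndarray, kind: Activation) -> np.ndarray:
    if kind is Activation.TANH:
        return 1.0 - a * a
    return a * (1.0 - a)


def build(arch: ArchitectureSpec, n_features: int, seed: int) -> TrainingState:
    """Glorot-uniform initialisation of all layers, reproducible from ``seed``."""
    if n_features < BOTTLENECK_DIM:
        raise ValueError(f"need at least {BOTTLENECK_DIM} input features")
    if arch.hidden_dims[1] != BOTTLENECK_DIM:
        raise ValueError("bottleneck width must be 100")
    rng = np.random.default_rng(seed)
    widths = [n_features, *arch.hidden_dims, n_features]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    surv_w = None
    if arch.has_survival_branch:
        # start at the null Cox model (all scores 0) so the risk direction
        # grows along the score gradient instead of a random projection
        surv_w = np.zeros(BOTTLENECK_DIM)
    return TrainingState(arch=arch, weights=weights, biases=biases,
                         survival_w=surv_w, seed=seed)


def _forward(state: TrainingState, X: np.ndarray, *, training: bool,
             rng: np.random.Generator | None = None):
    """Return (activations, dropout_masks); dropout only while training and
    only on the wide hidden layers (never the bottleneck or output)."""
    arch = state.arch
    acts = [X]
    masks: list[np.ndarray | None] = []
    a = X
    n_layers = len(state.weights)
    b_idx = state.bottleneck_index
    for l, (W, b) in enumerate(zip(state.weights, state.biases)):
        a = _act(a @ W + b, arch.activation)
        mask = None
        is_hidden = l < n_layers - 1
        if training and arch.dropout > 0.0 and is_hidden and (l + 1) != b_idx:
            keep = 1.0 - arch.dropout
            mask = (rng.random(a.shape) < keep) / keep
            a = a * mask
        acts.append(a)
        masks.append(mask)
    return acts, masks


def encode(state: TrainingState, data: MultiOmicsDataset | np.ndarray) -> np.ndarray:
    """Bottleneck matrix (n x 100) in the input's own row order; inference
    mode, so dropout is off and repeated calls are identical."""
    X = data.matrix if isinstance(data, MultiOmicsDataset) else np.asarray(data, float)
    acts, _ = _forward(state, X, training=False)
    return acts[state.bottleneck_index]


def reconstruct(state: TrainingState, X: np.ndarray) -> np.ndarray:
    acts, _ = _forward(state, X, training=False)
    return acts[-1]


def survival_scores(state: TrainingState, bottleneck: np.ndarray) -> np.ndarray:
    if state.survival_w is None:
        raise ValueError("this architecture has no survival branch")
    return bottleneck @ state.survival_w


# ---------------------------------------------------------------------------
# gradient machinery

def _l1_term(state: TrainingState) -> float:
    total = sum(np.abs(W).sum() for W in state.weights)
    if state.survival_w is not None:
        total += np.abs(state.survival_w).sum()
    return state.arch.l1_kernel * float(total)


def _backward(state: TrainingState, acts, masks, d_out: np.ndarray,
              d_bottleneck_extra: np.ndarray | None):
    """Backpropagate d_out (gradient w.r.t. the output activation) and an
    optional extra gradient injected at the bottleneck activation; returns
    (dW list, db list)."""
    arch = state.arch
    dW = [None] * len(state.weights)
    db = [None] * len(state.weights)
    b_idx = state.bottleneck_index
    da = d_out
    for l in range(len(state.weights) - 1, -1, -1):
        a = acts[l + 1]
        if (l + 1) == b_idx and d_bottleneck_extra is not None:
            da = da + d_bottleneck_extra
        if masks[l] is not None:
            da = da * masks[l]
            a = acts[l + 1]  # post-dropout stored; recover pre-dropout derivative
            # acts stores post-dropout activation; derivative needs pre-dropout a.
            # With inverted dropout a_post = a_pre*mask, and mask elements are 0
            # or 1/keep, so a_pre = a_post*keep where mask>0 — but dz at dropped
            # units is zero anyway, so using a_post only perturbs kept units by
            # the 1/keep factor; undo it explicitly:
            a = acts[l + 1] * (masks[l] > 0) * (1.0 - arch.dropout)
        dz = da * _act_deriv(a, arch.activation)
        a_prev = acts[l]
        dW[l] = a_prev.T @ dz + arch.l1_kernel * np.sign(state.weights[l])
        db[l] = dz.sum(axis=0)
        da = dz @ state.weights[l].T
    return dW, db


def _apply_update(state: TrainingState, grads: dict[str, np.ndarray]) -> None:
    arch = state.arch
    params = {f"W{l}": state.weights[l] for l in range(len(state.weights))}
    params.update({f"b{l}": state.biases[l] for l in range(len(state.biases))})
    if state.survival_w is not None:
        params["sw"] = state.survival_w
    if arch.optimizer is Optimizer.SGD:
        for key, g in grads.items():
            params[key] -= arch.learning_rate * g
        return
    # Adam (beta1=0.9, beta2=0.999, eps=1e-8)
    st = state._adam
    st["t"] = st.get("t", 0) + 1
    t = st["t"]
    b1, b2, eps = 0.9, 0.999, 1e-8
    for key, g in grads.items():
        m = st.setdefault(f"m_{key}", np.zeros_like(g))
        v = st.setdefault(f"v_{key}", np.zeros_like(g))
        m += (1 - b1) * (g - m)
        v += (1 - b2) * (g * g - v)
        m_hat = m / (1 - b1 ** t)
        v_hat = v / (1 - b2 ** t)
        params[key] -= arch.learning_rate * m_hat / (np.sqrt(v_hat) + eps)


def _gradient_step(state: TrainingState, X: np.ndarray, spec: LossSpec,
                   order: SurvivalOrder | None, cs: CentroidState | None,
                   rng: np.random.Generator) -> dict[str, float]:
    """One gradient step on the rows of X (already in presentation order);
    returns the loss terms at the pre-update parameters."""
    arch = state.arch
    n = X.shape[0]
    acts, masks = _forward(state, X, training=True, rng=rng)
    x_hat = acts[-1]
    terms: dict[str, float] = {}

    if spec.name is LossName.BCE:
        lr_val = loss_bce(X, x_hat)
        p = np.clip(x_hat, BCE_EPS, 1.0 - BCE_EPS)
        d_out = np.where((x_hat > BCE_EPS) & (x_hat < 1.0 - BCE_EPS),
                         (p - X) / (p * (1.0 - p)), 0.0) / X.size
        d_out = spec.alpha * d_out
    else:
        lr_val = loss_reconstruction(X, x_hat)
        d_out = spec.alpha * (2.0 / n) * (x_hat - X)
    terms["recon"] = lr_val

    if arch.l2_activity > 0.0:
        terms["l2_activity"] = arch.l2_activity * float((x_hat ** 2).sum()) / n
        d_out = d_out + arch.l2_activity * (2.0 / n) * x_hat

    bottleneck = acts[state.bottleneck_index]
    d_bneck = np.zeros_like(bottleneck)
    grads: dict[str, np.ndarray] = {}

    if spec.name.uses_survival:
        assert order is not None and state.survival_w is not None
        scores = bottleneck @ state.survival_w
        # batch-mean convention: like the reconstruction and clustering terms,
        # the partial-likelihood term is averaged over the batch during
        # training so the alpha/beta balance does not scale with cohort size
        terms["survival"] = loss_survival(scores, order) / n
        ds = loss_survival_gradient(scores, order) / n
        grads["sw"] = spec.beta * (bottleneck.T @ ds) \
            + arch.l1_kernel * np.sign(state.survival_w)
        d_bneck += spec.beta * np.outer(ds, state.survival_w)

    if spec.name.uses_clustering:
        assert cs is not None
        terms["clustering"] = loss_clustering(bottleneck, cs)
        mu_idx, lam_idx = nearest_two_centroids(bottleneck, cs.centroids)
        d_bneck += spec.gamma * (2.0 / n) * (cs.centroids[lam_idx] - cs.centroids[mu_idx])

    dW, db = _backward(state, acts, masks, d_out,
                       d_bneck if (d_bneck != 0).any() else None)
    for l in range(len(dW)):
        grads[f"W{l}"] = dW[l]
        grads[f"b{l}"] = db[l]
    _apply_update(state, grads)
    return terms


# ---------------------------------------------------------------------------
# centroid management

def seed_centroids(bottleneck: np.ndarray) -> CentroidState:
    """Farthest-apart pair of bottleneck vectors become the two seed
    centroids; every sample joins the nearer one.  Ties (multiple pairs at the
    maximal distance) resolve to the lexicographically smallest index pair."""
    n = bottleneck.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to seed centroids")
    sq = (bottleneck ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (bottleneck @ bottleneck.T)
    np.fill_diagonal(d2, -np.inf)
    best = np.unravel_index(np.argmax(d2), d2.shape)  # row-major => lexicographic min
    i, j = sorted(best)
    centroids = bottleneck[[i, j]].copy()
    mu_idx, _ = nearest_two_centroids(bottleneck, centroids)
    return CentroidState(centroids, mu_idx)


def update_centroids(bottleneck: np.ndarray, cs: CentroidState) -> CentroidState:
    """End-of-epoch refresh: each centroid becomes the mean bottleneck vector
    of its current group, then samples are reassigned to the nearest centroid.
    An emptied group is re-seeded with the sample farthest from its nearest
    surviving centroid so k stays constant."""
    k = cs.k
    centroids = cs.centroids.copy()
    for c in range(k):
        members = cs.assignments == c
        if members.any():
            centroids[c] = bottleneck[members].mean(axis=0)
    mu_idx, _ = nearest_two_centroids(bottleneck, centroids)
    for c in range(k):
        if not (mu_idx == c).any():
            others = [o for o in range(k) if o != c and (mu_idx == o).any()]
            d2 = ((bottleneck[:, None, :] - centroids[None, others, :]) ** 2).sum(axis=2)
            far = int(np.argmax(d2.min(axis=1)))
            centroids[c] = bottleneck[far]
            mu_idx, _ = nearest_two_centroids(bottleneck, centroids)
    return CentroidState(centroids, mu_idx)


def warmup_and_seed_centroids(state: TrainingState, X: np.ndarray,
                              rng: np.random.Generator) -> CentroidState:
    """One epoch of reconstruction-only training, then seed centroids from
    the inferred bottleneck.  The warm-up parameters are kept: combined-loss
    training continues from this state."""
    warm_spec = LossSpec(LossName.MSE, alpha=1.0, beta=0.0, gamma=0.0)
    _run_epoch(state, X, warm_spec, None, None, rng)
    bottleneck = encode(state, X)
    cs = seed_centroids(bottleneck)
    state.centroid_state = cs
    return cs


def _run_epoch(state: TrainingState, X: np.ndarray, spec: LossSpec,
               order: SurvivalOrder | None, cs: CentroidState | None,
               rng: np.random.Generator) -> dict[str, float]:
    arch = state.arch
    if arch.batch_size == FULL_BATCH:
        return _gradient_step(state, X, spec, order, cs, rng)
    if order is not None or cs is not None:
        raise ValueError("mini-batch training supports reconstruction losses only")
    sums: dict[str, float] = {}
    n = X.shape[0]
    for start in range(0, n, arch.batch_size):
        terms = _gradient_step(state, X[start:start + arch.batch_size], spec, None, None, rng)
        for key, val in terms.items():
            sums[key] = sums.get(key, 0.0) + val
    n_batches = -(-n // arch.batch_size)
    return {key: val / n_batches for key, val in sums.items()}


def train(state: TrainingState, data: MultiOmicsDataset, spec: LossSpec) -> TrainingState:
    """Run the configured number of epochs with the bespoke loop.

    The input matrix must already carry the variant's scaling (unit-norm for
    the baseline, min-max for the custom architecture).  Appends one trace row
    per epoch with the loss terms (and the bottleneck silhouette when the
    clustering term is active).
    """
    from .cluster import silhouette  # local import to avoid a cycle

    X = data.matrix
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((state.seed, 0xD0)))

    order: SurvivalOrder | None = None
    if spec.name.uses_survival:
        order = SurvivalOrder.from_survival(data.survival.time, data.survival.event)
        perm = order.permutation
    else:
        perm = np.arange(n)
    state.presentation_order = perm
    Xp = X[perm]

    cs: CentroidState | None = None
    if spec.name.uses_clustering:
        cs = state.centroid_state
        if cs is None:
            cs = warmup_and_seed_centroids(state, Xp, rng)
        if not any("silhouette" in row for row in state.trace):
            # epoch-0 baseline: quality of the farthest-pair seeded assignments
            b0 = encode(state, Xp)
            sil0 = silhouette(b0, cs.assignments) \
                if len(np.unique(cs.assignments)) > 1 else 0.0
            state.trace.append({"epoch": state.epoch, "silhouette": sil0})

    for _ in range(state.arch.epochs):
        terms = _run_epoch(state, Xp, spec, order, cs, rng)
        row = {"epoch": state.epoch, **terms, "l1_kernel": _l1_term(state)}
        active = {"recon": spec.alpha, "survival": spec.beta, "clustering": spec.gamma}
        row["total"] = sum(w * terms[t] for t, w in active.items() if t in terms) \
            + row["l1_kernel"] + terms.get("l2_activity", 0.0)
        if cs is not None:
            bottleneck = encode(state, Xp)
            cs = update_centroids(bottleneck, cs)
            state.centroid_state = cs
            if len(np.unique(cs.assignments)) > 1:
                row["silhouette"] = silhouette(bottleneck, cs.assignments)
            else:
                row["silhouette"] = 0.0
        state.trace.append(row)
        state.epoch += 1
    return state


# ---------------------------------------------------------------------------
# checkpointing

def save_state(state: TrainingState, path) -> None:
    """Portable checkpoint: arrays in an .npz next to a JSON metadata file."""
    path = Path(path)
    arrays = {f"W{l}": W for l, W in enumerate(state.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(state.biases)})
    if state.survival_w is not None:
        arrays["sw"] = state.survival_w
    if state.centroid_state is not None:
        arrays["centroids"] = state.centroid_state.centroids
        arrays["assignments"] = state.centroid_state.assignments
    if state.presentation_order is not None:
        arrays["presentation_order"] = state.presentation_order
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"arch": {k: (v.value if isinstance(v, Enum) else v)
                     for k, v in vars(state.arch).items()},
            "seed": state.seed, "epoch": state.epoch, "trace": state.trace}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_state(path) -> TrainingState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    a = meta["arch"]
    arch = ArchitectureSpec(Variant(a["variant"]), tuple(a["hidden_dims"]),
                            Activation(a["activation"]), a["dropout"], a["l1_kernel"],
                            a["l2_activity"], Optimizer(a["optimizer"]), a["batch_size"],
                            a["epochs"], a["has_survival_branch"], a["learning_rate"])
    with np.load(path.with_suffix(".npz")) as npz:
        n_layers = len([k for k in npz.files if k.startswith("W")])
        weights = [npz[f"W{l}"] for l in range(n_layers)]
        biases = [npz[f"b{l}"] for l in range(n_layers)]
        sw = npz["sw"] if "sw" in npz.files else None
        cs = None
        if "centroids" in npz.files:
            cs = CentroidState(npz["centroids"], npz["assignments"])
        order = npz["presentation_order"] if "presentation_order" in npz.files else None
    state = TrainingState(arch=arch, weights=weights, biases=biases, survival_w=sw,
                          seed=meta["seed"], centroid_state=cs,
                          presentation_order=order, epoch=meta["epoch"],
                          trace=meta["trace"])
    return state
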