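"""Class-weighted end-to-end training, cross-validation and ensemble scoring.

Training minimizes per-sample class-weighted cross-entropy with Adam
(weight decay on weight matrices, not on biases or normalization parameters),
mini-batches of 16, at most 100 epochs, and early stopping: if the validation
loss fails to improve by at least 1e-4 for 20 consecutive epochs, training
stops and the best-validation-loss weights are restored.

Splits follow the study protocol: 5-fold stratified cross-validation with 20%
of the molecules held out as the test set per fold and 10% of the remaining
80% as a validation set, all stratified by label.  One master seed fans out
deterministically to the split, weight-initialization and batch-shuffle
streams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import LabeledDataset, MoleculeSignal, SpectralOperators
from .layers import ModelState, backward_batch, forward_batch, parameters
from .metrics import MetricsReport, summary_metrics

__all__ = [
    "TrainingConfig",
    "SplitPlan",
    "FoldResult",
    "class_weights",
    "weighted_cross_entropy",
    "stratified_splits",
    "train_model",
    "grid_search",
    "anticancer_likeness",
    "DEFAULT_GRID",
]

_EPS = 1e-12

# hyperparameter space of the original study (ChebNet adds its filter size)
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [5e-4, 5e-3],
    "l2": [1e-5, 1e-4, 5e-4],
    "n_conv_layers": [1, 2, 3],
    "dropout_layers": [1, 2],
    "batch_norm": [True, False],
    "feature_normalization": [True, False],
    "cheb_n": [2, 4, 6],
}


@dataclass
class TrainingConfig:
    learning_rate: float = 5e-3
    l2: float = 1e-4
    max_epochs: int = 100
    early_stop_window: int = 20
    early_stop_min_delta: float = 1e-4
    batch_size: int = 16
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "l2", "max_epochs", "early_stop_window",
                     "early_stop_min_delta", "batch_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Fold:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class SplitPlan:
    folds: list[Fold]
    seed: int


@dataclass
class FoldResult:
    model: ModelState
    metrics: MetricsReport
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0
    test_scores: np.ndarray | None = None


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class loss weights inversely proportional to class frequency.

    w_c = n_total / (2 n_c), so a balanced dataset gets unit weights.
    Returns ``[w_neg, w_pos]``.
    """
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    n = n_pos + n_neg
    return np.array([n / (2.0 * n_neg), n / (2.0 * n_pos)])


def weighted_cross_entropy(probs: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Batch-averaged −w_y log p_y with an epsilon clamp against log 0."""
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = np.clip(probs[np.arange(len(y)), y], _EPS, None)
    return float(np.mean(-np.asarray(w)[y] * np.log(p_true)))


def stratified_splits(labels: np.ndarray, k: int = 5, val_frac: float = 0.1,
                      seed: int = 0) -> SplitPlan:
    """Deterministic stratified k-fold plan with per-fold validation subsets.

    Per class, indices are shuffled by the seed and dealt round-robin into the
    k test folds; within each fold's remainder the first ceil(val_frac * n)
    indices per class (in post-shuffle order) form the validation set.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    per_class: dict[int, np.ndarray] = {}
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer than k={k} members")
        per_class[c] = rng.permutation(idx)
    test_sets: list[list[int]] = [[] for _ in range(k)]
    for c in (0, 1):
        for pos, i in enumerate(per_class[c]):
            test_sets[pos % k].append(int(i))
    folds = []
    for f in range(k):
        test = np.array(sorted(test_sets[f]), dtype=np.int64)
        val_parts, train_parts = [], []
        for c in (0, 1):
            rest = [int(i) for i in per_class[c] if i not in set(test_sets[f])]
            n_val = int(np.ceil(val_frac * len(rest)))
            val_parts.extend(rest[:n_val])
            train_parts.extend(rest[n_val:])
        folds.append(Fold(
            train=np.array(sorted(train_parts), dtype=np.int64),
            val=np.array(sorted(val_parts), dtype=np.int64),
            test=test,
        ))
    return SplitPlan(folds=folds, seed=seed)


class _Adam:
    """Adam with decoupled-from-bias L2 weight decay added to the gradient."""

    def __init__(self, model: ModelState, lr: float, l2: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(arr) for name, arr, _ in parameters(model)}
        self.v = {name: np.zeros_like(arr) for name, arr, _ in parameters(model)}

    def step(self, model: ModelState, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for name, arr, decay in parameters(model):
            g = grads.get(name)
            if g is None:
                continue
            if decay and self.l2 > 0:
                g = g + self.l2 * arr
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            arr -= self.lr * (self.m[name] / b1c) / (np.sqrt(self.v[name] / b2c) + self.eps)


def _eval_loss(model: ModelState, x: np.ndarray, y: np.ndarray, w: np.ndarray,
               ops: SpectralOperators) -> tuple[float, np.ndarray]:
    probs, _ = forward_batch(model, x, ops, train_mode=False)
    return weighted_cross_entropy(probs, y, w), probs[:, 1]


def train_model(
    data: LabeledDataset,
    ops: SpectralOperators,
    arch: ModelState,
    cfg: TrainingConfig,
    fold: Fold,
) -> FoldResult:
    """Train one fold end-to-end; returns the restored-best model and metrics.

    ``arch`` supplies the architecture and the initial weights (it is copied,
    never mutated).  Class weights are computed on the training labels and
    used for both training and validation loss, keeping one objective.
    """
    x_all = data.feature_matrix()
    y_all = data.labels
    model = arch.copy()
    if cfg.class_weighting:
        w = class_weights(y_all[fold.train])
    else:
        w = np.array([1.0, 1.0])
    ss = np.random.SeedSequence(entropy=cfg.seed)
    shuffle_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt = _Adam(model, cfg.learning_rate, cfg.l2)
    best_val = np.inf
    best_weights: dict[str, np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] = []
    best_epoch = 0
    bad_epochs = 0
    train_losses: list[float] = []
    val_losses: list[float] = []
    stop_epoch = cfg.max_epochs
    for epoch in range(1, cfg.max_epochs + 1):
        order = shuffle_rng.permutation(fold.train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            probs, cache = forward_batch(model, xb, ops, train_mode=True, rng=dropout_rng)
            loss = weighted_cross_entropy(probs, yb, w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}")
            onehot = np.eye(2)[yb]
            dlogits = (np.asarray(w)[yb][:, None] * (probs - onehot)) / len(yb)
            grads, _ = backward_batch(model, ops, cache, dlogits)
            opt.step(model, grads)
            epoch_loss += loss
            n_batches += 1
        train_losses.append(epoch_loss / max(1, n_batches))
        val_loss, _ = _eval_loss(model, x_all[fold.val], y_all[fold.val], w, ops)
        val_losses.append(val_loss)
        if val_loss < best_val - cfg.early_stop_min_delta:
            best_val = val_loss
            best_epoch = epoch
            best_weights = {name: arr.copy() for name, arr, _ in parameters(model)}
            best_bn = [
                (lw.batch_norm.running_mean.copy(), lw.batch_norm.running_var.copy())
                for lw in model.layers if lw.batch_norm is not None
            ]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_window:
                stop_epoch = epoch
                break
    else:
        stop_epoch = cfg.max_epochs
    if best_weights is not None:
        for name, arr, _ in parameters(model):
            arr[...] = best_weights[name]
        bn_layers = [lw for lw in model.layers if lw.batch_norm is not None]
        for lw, (rm, rv) in zip(bn_layers, best_bn):
            lw.batch_norm.running_mean[...] = rm
            lw.batch_norm.running_var[...] = rv
    test_probs, _ = forward_batch(model, x_all[fold.test], ops, train_mode=False)
    report = summary_metrics(y_all[fold.test], test_probs[:, 1])
    return FoldResult(
        model=model,
        metrics=report,
        train_loss=train_losses,
        val_loss=val_losses,
        stop_epoch=stop_epoch,
        best_epoch=best_epoch,
        test_scores=test_probs[:, 1],
    )


def _grid_combinations(grid: dict[str, list], kind: str) -> list[dict]:
    keys = [k for k in grid if kind == "cheb" or k != "cheb_n"]
    combos = []
    for values in itertools.product(*(grid[k] for k in keys)):
        combos.append(dict(zip(keys, values)))
    return combos


def grid_search(
    data: LabeledDataset,
    ops: SpectralOperators,
    fold: Fold,
    kind: str = "cheb",
    grid: dict[str, list] | None = None,
    seed: int = 0,
    model_kwargs: dict | None = None,
    training_kwargs: dict | None = None,
):
    """Exhaustive grid search on one fold's validation split.

    Selection: minimum validation loss; ties broken by higher validation AUPR,
    then by grid order.  Returns ``(best_combo, best_result, table)`` where
    ``table`` records every combination's validation loss and AUPR.
    """
    from .layers import init_model  # local import to avoid cycle at module load

    grid = grid if grid is not None else DEFAULT_GRID
    combos = _grid_combinations(grid, kind)
    if not combos:
        raise ValueError("empty grid")
    model_kwargs = dict(model_kwargs or {})
    training_kwargs = dict(training_kwargs or {})
    ss = np.random.SeedSequence(entropy=seed)
    init_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(combos))]
    rows = []
    best = None
    y_all = data.labels
    x_all = data.feature_matrix()
    for ci, combo in enumerate(combos):
        arch = init_model(
            n_nodes=ops.n_nodes,
            kind=kind,
            n_conv_layers=combo.get("n_conv_layers", 2),
            cheb_n=combo.get("cheb_n", 4),
            batch_norm=combo.get("batch_norm", False),
            dropout_layers=combo.get("dropout_layers", 1),
            feature_normalization=combo.get("feature_normalization", False),
            seed=init_seeds[ci],
            **model_kwargs,
        )
        cfg = TrainingConfig(
            learning_rate=combo.get("learning_rate", 5e-3),
            l2=combo.get("l2", 1e-4),
            seed=init_seeds[ci],
            **training_kwargs,
        )
        result = train_model(data, ops, arch, cfg, fold)
        w = class_weights(y_all[fold.train])
        val_loss, val_scores = _eval_loss(result.model, x_all[fold.val],
                                          y_all[fold.val], w, ops)
        try:
            val_aupr = summary_metrics(y_all[fold.val], val_scores).aupr
        except ValueError:
            val_aupr = float("nan")
        rows.append({**combo, "val_loss": val_loss, "val_aupr": val_aupr})
        key = (val_loss, -(val_aupr if np.isfinite(val_aupr) else -np.inf), ci)
        if best is None or key < best[0]:
            best = (key, combo, result)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


def anticancer_likeness(
    models: list[ModelState],
    foods: list[MoleculeSignal],
    ops: SpectralOperators,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Ensemble anticancer-likeness of unlabeled molecules.

    The score is the mean over the (typically 5 cross-validation) models of
    the predicted anticancer probability; molecules scoring at or above
    ``threshold`` are flagged.  All models must share the interactome node
    order.
    """
    if not models:
        raise ValueError("need at least one model")
    orders = {tuple(m.gene_ids) for m in models if m.gene_ids is not None}
    if len(orders) > 1:
        raise ValueError("models disagree on interactome node order")
    if any(m.config.get("n_nodes") != ops.n_nodes for m in models):
        raise ValueError("model/graph node-count mismatch")
    x = np.stack([f.x for f in foods]).astype(np.float64)
    scores = np.zeros(len(foods))
    for m in models:
        probs, _ = forward_batch(m, x, ops, train_mode=False)
        scores += probs[:, 1]
    scores /= len(models)
    df = pd.DataFrame({
        "molecule_id": [f.molecule_id for f in foods],
        "score": scores,
        "flagged": scores >= threshold,
    })
    return df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
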