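"""Desk-scale end-to-end benchmark on planted synthetic data.

One call runs the whole study loop at one seed: generate a dataset, train the
ChebNet classifier (K=2, N=4, d=8) with a small validation-selected
hyperparameter grid, score the no-propagation ablations (raw signal + linear
SVM, raw signal + MLP) and the RWR + SVM baseline on the same held-out fold,
and compute the attribution recall of the trained model against an untrained
(random-weight) one.  Used by the test suite and the results-reproduction
script; all randomness is derived from the single ``seed``.
"""

from __future__ import annotations

import numpy as np

from .attribution import (
    attribution_recall,
    average_positive_attributions,
    preranked_enrichment,
)
from .baseline import (
    DEFAULT_RESTART_GRID,
    _squash,
    fit_raw_mlp,
    fit_svm,
    rwr_matrix,
    train_baseline,
)
from .interactome import LabeledDataset, build_spectral_operators
from .layers import init_model
from .metrics import summary_metrics
from .synthetic import SyntheticConfig, generate_all
from .training import TrainingConfig, grid_search, stratified_splits, train_model

__all__ = ["evaluate_synthetic", "SMALL_GRID"]

# runtime-sized slice of the full hyperparameter space; selection is still by
# validation loss, exactly as in the full grid
SMALL_GRID: dict[str, list] = {
    "learning_rate": [5e-4, 5e-3],
    "dropout_layers": [1, 2],
}


def evaluate_synthetic(
    seed: int,
    cfg: SyntheticConfig | None = None,
    grid: dict[str, list] | None = None,
    include_rwr: bool = True,
    n_restarts: int = 3,
    steps: int = 64,
    n_perm: int = 500,
    fdr_threshold: float = 0.25,
) -> dict[str, float]:
    """Run the full pipeline at one seed; returns headline numbers in percent
    (recall values as fractions in [0, 1])."""
    cfg = cfg if cfg is not None else SyntheticConfig(seed=seed)
    g, pa, data, _foods, _mech = generate_all(cfg)
    # drop the rare zero-target molecules: they carry no signal and RWR needs
    # a seed distribution
    keep = [i for i, s in enumerate(data.signals) if s.n_targets > 0]
    if len(keep) < len(data.signals):
        data = LabeledDataset(signals=[data.signals[i] for i in keep],
                              labels=data.labels[keep])
    ops = build_spectral_operators(g)
    plan = stratified_splits(data.labels, seed=seed)
    feats = data.feature_matrix()

    # hyperparameters selected once on the first fold's validation split
    # (global mode), then every fold is trained with the chosen configuration
    # and metrics are averaged across the five held-out test sets.  With a
    # single-channel input (d0=1) Glorot draws are high-variance, so each fold
    # trains from `n_restarts` seeded inits and keeps the one with the lowest
    # validation loss (the training objective; the test set plays no role).
    combo, _result0, _table = grid_search(
        data, ops, plan.folds[0], kind="cheb",
        grid=grid if grid is not None else SMALL_GRID,
        seed=seed + 1,
        model_kwargs={"gene_ids": g.gene_ids},
    )
    models = []
    reports = []
    for fi, fold in enumerate(plan.folds):
        best = None
        for ri in range(n_restarts):
            init_seed = seed + 100 + 10 * fi + ri
            arch = init_model(
                n_nodes=g.n_genes, kind="cheb",
                n_conv_layers=combo.get("n_conv_layers", 2),
                cheb_n=combo.get("cheb_n", 4),
                batch_norm=combo.get("batch_norm", False),
                dropout_layers=combo.get("dropout_layers", 1),
                feature_normalization=combo.get("feature_normalization", False),
                seed=init_seed, gene_ids=g.gene_ids,
            )
            tc = TrainingConfig(learning_rate=combo.get("learning_rate", 5e-3),
                                l2=combo.get("l2", 1e-4), seed=init_seed)
            res = train_model(data, ops, arch, tc, fold)
            if best is None or min(res.val_loss) < min(best.val_loss):
                best = res
        models.append(best.model)
        reports.append(best.metrics)
    out = {
        "chebnet_aupr": float(np.mean([r.aupr for r in reports])),
        "chebnet_f1": float(np.mean([r.f1_positive for r in reports])),
        "chebnet_balanced_accuracy": float(
            np.mean([r.balanced_accuracy for r in reports])),
    }

    svm_auprs, mlp_auprs, rwr_auprs, restarts = [], [], [], []
    if include_rwr:
        profiles = {r: rwr_matrix(g, list(data.signals), r)
                    for r in DEFAULT_RESTART_GRID}
    for fold in plan.folds:
        y_test = data.labels[fold.test]
        clf, _ = fit_svm(feats, data.labels, fold)
        svm_scores = _squash(clf.decision_function(feats[fold.test]))
        svm_auprs.append(summary_metrics(y_test, svm_scores).aupr)
        _mlp, mlp_scores = fit_raw_mlp(feats, data.labels, fold, seed=seed + 2)
        mlp_auprs.append(summary_metrics(y_test, mlp_scores).aupr)
        if include_rwr:
            _c, best_r, rwr_scores = train_baseline(profiles, data.labels,
                                                    DEFAULT_RESTART_GRID, fold)
            rwr_auprs.append(summary_metrics(y_test, rwr_scores).aupr)
            restarts.append(best_r)
    out["raw_svm_aupr"] = float(np.mean(svm_auprs))
    out["raw_mlp_aupr"] = float(np.mean(mlp_auprs))
    if include_rwr:
        out["rwr_svm_aupr"] = float(np.mean(rwr_auprs))
        out["rwr_best_restart"] = float(np.median(restarts))

    ranked = average_positive_attributions(
        models, data, ops, plan, g.gene_ids, steps=steps)
    er = preranked_enrichment(ranked, pa, weight_exp=0.0, n_perm=n_perm,
                              seed=seed + 3, gene_ids=g.gene_ids)
    out["attribution_recall"] = attribution_recall(er, pa, fdr_threshold)

    untrained = [init_model(n_nodes=g.n_genes, kind="cheb", n_conv_layers=2,
                            cheb_n=4, seed=seed + 200 + fi, gene_ids=g.gene_ids)
                 for fi in range(len(plan.folds))]
    try:
        ranked_u = average_positive_attributions(
            untrained, data, ops, plan, g.gene_ids, steps=steps)
        er_u = preranked_enrichment(ranked_u, pa, weight_exp=0.0, n_perm=n_perm,
                                    seed=seed + 3, gene_ids=g.gene_ids)
        out["untrained_attribution_recall"] = attribution_recall(er_u, pa,
                                                                 fdr_threshold)
    except ValueError:
        # a random model may never predict the anticancer class
        out["untrained_attribution_recall"] = 0.0
    return out
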