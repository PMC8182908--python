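"""Random-walk-with-restart baseline and no-propagation ablations.

The comparison method learns unsupervised diffusion profiles: starting from a
molecule's target genes, a walker moves over the interactome and returns to
the seed set with probability r each step.  The stationary distribution of

    p <- (1 - r) W p + r e,      W = column-normalized A,  e = x / Σx

is the molecule's systemic diffusion profile, then fed to a class-weighted
linear max-margin classifier.  The restart probability is chosen on a
validation split by AUPR over the grid [0.001, 0.01, 0.1, 0.2, ..., 0.9].
Ablations without propagation (raw signal + SVM, raw signal + MLP) are also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .interactome import Interactome, MoleculeSignal
from .metrics import summary_metrics
from .training import Fold

__all__ = [
    "DiffusionProfile",
    "rwr",
    "rwr_matrix",
    "train_baseline",
    "fit_svm",
    "fit_raw_mlp",
    "DEFAULT_RESTART_GRID",
    "DEFAULT_C_GRID",
]

DEFAULT_RESTART_GRID = [0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
DEFAULT_C_GRID = [0.01, 0.1, 1.0, 10.0]


@dataclass
class DiffusionProfile:
    molecule_id: str
    p: np.ndarray
    restart_prob: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.min() < 0 or abs(self.p.sum() - 1.0) > 1e-8:
            raise ValueError("profile must be a probability vector")


def _walk_matrix(g: Interactome, normalization: str = "column",
                 self_loops: bool = False) -> sp.csr_matrix:
    a = g.adjacency.astype(np.float64)
    if self_loops:
        a = a + sp.identity(a.shape[0], format="csr")
    if normalization == "column":
        colsum = np.asarray(a.sum(axis=0)).ravel()
        if (colsum == 0).any():
            raise ValueError("isolated node: column normalization undefined")
        return (a @ sp.diags(1.0 / colsum)).tocsr()
    if normalization == "row":
        rowsum = np.asarray(a.sum(axis=1)).ravel()
        if (rowsum == 0).any():
            raise ValueError("isolated node: row normalization undefined")
        return (sp.diags(1.0 / rowsum) @ a).tocsr()
    raise ValueError(f"unknown normalization {normalization!r}")


def rwr(
    g: Interactome,
    x: MoleculeSignal | np.ndarray,
    restart: float,
    tol: float = 1e-8,
    max_iter: int = 10000,
    normalization: str = "column",
    self_loops: bool = False,
) -> DiffusionProfile:
    """Fixed point of p <- (1-r) W p + r e for one molecule.

    ``e`` is the uniform distribution over the molecule's targets.  Raises on
    zero-target molecules and on non-convergence within ``max_iter``.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart must lie in (0, 1]")
    mol_id = x.molecule_id if isinstance(x, MoleculeSignal) else "<array>"
    xv = (x.x if isinstance(x, MoleculeSignal) else np.asarray(x)).astype(np.float64)
    total = xv.sum()
    if total < 1:
        raise ValueError(f"{mol_id}: zero-target molecule has no seed distribution")
    e = xv / total
    if restart == 1.0:
        return DiffusionProfile(mol_id, e, restart)
    w = _walk_matrix(g, normalization, self_loops)
    p = e.copy()
    for _ in range(max_iter):
        p_new = (1.0 - restart) * (w @ p) + restart * e
        if np.abs(p_new - p).sum() < tol:
            return DiffusionProfile(mol_id, p_new, restart)
        p = p_new
    residual = float(np.abs((1.0 - restart) * (w @ p) + restart * e - p).sum())
    raise RuntimeError(f"{mol_id}: RWR did not converge in {max_iter} iterations "
                       f"(residual {residual:.3e})")


def rwr_matrix(
    g: Interactome,
    signals: list[MoleculeSignal],
    restart: float,
    tol: float = 1e-8,
    max_iter: int = 10000,
    normalization: str = "column",
    self_loops: bool = False,
) -> np.ndarray:
    """Stack of diffusion profiles, one row per molecule in input order."""
    if not signals:
        return np.zeros((0, g.n_genes))
    if not 0 < restart <= 1:
        raise ValueError("restart must lie in (0, 1]")
    totals = np.array([s.x.sum() for s in signals], dtype=np.float64)
    if (totals < 1).any():
        bad = signals[int(np.flatnonzero(totals < 1)[0])].molecule_id
        raise ValueError(f"{bad}: zero-target molecule has no seed distribution")
    e = np.stack([s.x for s in signals]).astype(np.float64).T / totals  # (V, n)
    if restart == 1.0:
        return e.T
    w = _walk_matrix(g, normalization, self_loops)
    p = e.copy()
    for _ in range(max_iter):
        p_new = (1.0 - restart) * (w @ p) + restart * e
        if np.abs(p_new - p).sum(axis=0).max() < tol:
            return np.asarray(p_new).T
        p = p_new
    raise RuntimeError(f"RWR batch did not converge in {max_iter} iterations")


def fit_svm(
    features: np.ndarray,
    labels: np.ndarray,
    fold: Fold,
    c_grid: list[float] | None = None,
):
    """Class-weighted linear max-margin classifier, C chosen on validation AUPR.

    Returns ``(clf, val_aupr)``; decision-function scores are squashed through
    a logistic for [0,1] ranking scores.
    """
    c_grid = c_grid if c_grid is not None else DEFAULT_C_GRID
    y_train = labels[fold.train]
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training fold")
    best = None
    for c in c_grid:
        clf = SVC(kernel="linear", C=c, class_weight="balanced")
        clf.fit(features[fold.train], y_train)
        val_scores = _squash(clf.decision_function(features[fold.val]))
        try:
            aupr = summary_metrics(labels[fold.val], val_scores).aupr
        except ValueError:
            aupr = float("nan")
        if best is None or (np.isfinite(aupr) and aupr > best[1]):
            best = (clf, aupr)
    return best


def _squash(scores: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=np.float64)))


def train_baseline(
    profiles: dict[float, np.ndarray],
    labels: np.ndarray,
    restart_grid: list[float],
    fold: Fold,
    c_grid: list[float] | None = None,
):
    """RWR + max-margin classifier with restart probability chosen on validation.

    ``profiles`` maps each candidate restart to its precomputed profile matrix
    (n_molecules x |V|).  Returns ``(clf, best_restart, test_scores)``.
    """
    best = None
    for r in restart_grid:
        if r not in profiles:
            raise KeyError(f"no precomputed profiles for restart={r}")
        clf, aupr = fit_svm(profiles[r], labels, fold, c_grid)
        if best is None or (np.isfinite(aupr) and aupr > best[2]):
            best = (clf, r, aupr)
    clf, r, _ = best
    test_scores = _squash(clf.decision_function(profiles[r][fold.test]))
    return clf, r, test_scores


def fit_raw_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    fold: Fold,
    hidden: int = 32,
    seed: int = 0,
):
    """No-propagation neural ablation: raw target signal into a small MLP."""
    y_train = labels[fold.train]
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training fold")
    clf = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=500,
                        random_state=seed, early_stopping=False)
    clf.fit(features[fold.train], y_train)
    return clf, clf.predict_proba(features[fold.test])[:, 1]
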