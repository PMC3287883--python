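"""Replicate-split cross-validation for gene-number selection and evaluation.

Phenotype replicates are split into disjoint train/test/validation sets.
The full pipeline (Z statistics, rho, shrinkage, gene ranking) is fitted on
the training replicates only; the misclassification error on the test
replicates picks the number of genes K* (smallest K on ties); the chosen
rule is then scored on the validation replicates, and means with standard
errors are reported over repeated random splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .classifiers import ShrinkConfig, fit_model

DEFAULT_K_GRID = tuple(range(1, 51))


@dataclass
class SplitSpec:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.test, self.validation)]
        self.train, self.test, self.validation = parts
        allidx = np.concatenate(parts)
        if len(np.unique(allidx)) != len(allidx):
            raise ValueError("split index sets must be disjoint")


def split_replicates(R_total: int, sizes=(50, 50, 100), seed=0) -> SplitSpec:
    """Random disjoint train/test/validation replicate index sets.

    ``sizes`` are counts (fractions of R_total also accepted).
    """
    sizes = list(sizes)
    if len(sizes) != 3:
        raise ValueError("sizes must be (train, test, validation)")
    if all(0 < s < 1 for s in sizes):
        sizes = [int(round(s * R_total)) for s in sizes]
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("each split needs at least one replicate")
    if sum(sizes) > R_total:
        raise ValueError(f"split sizes {sizes} exceed {R_total} replicates")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(R_total)
    a, b, c = sizes
    return SplitSpec(perm[:a], perm[a:a + b], perm[a + b:a + b + c])


def misclassification_error(pred_labels, true_labels) -> float:
    """Fraction of disagreeing labels."""
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape:
        raise ValueError("label vectors must have the same length")
    return float(np.mean(p != t))


def roc_auc(scores, true_labels):
    """AUC by the Mann-Whitney pairwise formulation (ties count 1/2).

    Returns ``(auc, points)`` where points is an array of (fpr, tpr) pairs,
    one per distinct threshold, from (0,0) to (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels)
    n1 = int((y == 1).sum())
    n2 = int((y == 0).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n2)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.diff(ss) != 0, True]
    tps = np.cumsum(ys == 1)[distinct]
    fps = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n2]
    return float(auc), np.column_stack([fpr, tpr])


@dataclass
class CVResult:
    kind: str
    K_grid: list
    splits: list                      # SplitSpec per repetition
    error_curves: list                # per split: array over K_grid (test error)
    k_star: list                      # per split
    selected_genes: list              # per split: genes at K*
    val_error: list                   # per split mean over validation replicates
    val_auc: list
    val_error_mean: float = 0.0
    val_error_se: float = 0.0
    val_auc_mean: float = 0.0
    val_auc_se: float = 0.0

    def finalize(self) -> "CVResult":
        ns = len(self.val_error)
        self.val_error_mean = float(np.mean(self.val_error))
        self.val_auc_mean = float(np.mean(self.val_auc))
        if ns > 1:
            self.val_error_se = float(np.std(self.val_error, ddof=1) / np.sqrt(ns))
            self.val_auc_se = float(np.std(self.val_auc, ddof=1) / np.sqrt(ns))
        return self

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind,
            "K_grid": [int(k) for k in self.K_grid],
            "splits": [{"train": s.train.tolist(), "test": s.test.tolist(),
                        "validation": s.validation.tolist()} for s in self.splits],
            "error_curves": [np.asarray(c).tolist() for c in self.error_curves],
            "k_star": [int(k) for k in self.k_star],
            "selected_genes": [[str(g) for g in gs] for gs in self.selected_genes],
            "val_error": list(map(float, self.val_error)),
            "val_auc": list(map(float, self.val_auc)),
            "val_error_mean": self.val_error_mean,
            "val_error_se": self.val_error_se,
            "val_auc_mean": self.val_auc_mean,
            "val_auc_se": self.val_auc_se,
        }, indent=2)


def _mean_metrics_over_replicates(decision, labels_matrix, tau):
    """Mean error and AUC of one decision vector against replicate columns."""
    errs, aucs = [], []
    pred = (decision > tau).astype(np.int8)
    for r in range(labels_matrix.shape[1]):
        yr = labels_matrix[:, r]
        errs.append(misclassification_error(pred, yr))
        aucs.append(roc_auc(decision, yr)[0])
    return float(np.mean(errs)), float(np.mean(aucs))


def cross_validate(genotypes, annotation, phenotypes, covariates=None,
                   kind: str = "eb", K_grid=DEFAULT_K_GRID, n_splits: int = 5,
                   sizes=None, seed: int = 0, shrink: ShrinkConfig | None = None,
                   use_covariates: bool = True, rho: float | None = None) -> CVResult:
    """Full CV loop: fit on train, pick K on test error, report on validation."""
    K_grid = sorted(int(k) for k in K_grid)
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    Y = phenotypes.Y
    R = Y.shape[1]
    if sizes is None:
        # paper-style thirds when fewer than the canonical 200 replicates
        base = R // 4
        sizes = (base, base, R - 2 * base) if R >= 4 else (1, 1, R - 2)
    if R < 3:
        raise ValueError("cross-validation needs at least 3 replicates")

    rng = np.random.default_rng(seed)
    result = CVResult(kind, K_grid, [], [], [], [], [], [])
    for s in range(n_splits):
        spec = split_replicates(R, sizes, seed=rng.integers(2 ** 31))
        model = fit_model(genotypes, annotation, Y[:, spec.train],
                          covariates=covariates, kind=kind, shrink=shrink,
                          rho=rho, use_covariates=use_covariates)
        curve = []
        for K in K_grid:
            err, _ = _mean_metrics_over_replicates(
                model.decision_values(K), Y[:, spec.test], model.tau)
            curve.append(err)
        curve = np.asarray(curve)
        k_star = K_grid[int(np.argmin(curve))]  # argmin takes the smallest K on ties
        verr, vauc = _mean_metrics_over_replicates(
            model.decision_values(k_star), Y[:, spec.validation], model.tau)
        result.splits.append(spec)
        result.error_curves.append(curve)
        result.k_star.append(k_star)
        result.selected_genes.append(model.selected_genes(k_star))
        result.val_error.append(verr)
        result.val_auc.append(vauc)
    return result.finalize()
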