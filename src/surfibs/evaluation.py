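"""Per-protein evaluation: threshold-free ROC AUC, thresholded MCC, and
superfamily-grouped cross-validation splits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import matthews_corrcoef, roc_auc_score


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mcc(pred, labels) -> float:
    """Matthews correlation coefficient; zero-denominator cases return 0."""
    pred = np.asarray(pred).astype(int)
    labels = np.asarray(labels).astype(int)
    if pred.shape != labels.shape:
        raise ValueError("pred and labels must have the same length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(labels, pred))


def binarize(scores, threshold: float) -> np.ndarray:
    """score >= threshold -> 1."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


@dataclass
class EvalReport:
    per_protein: dict  # id -> {roc_auc, mcc, n_pos, n_neg, level}
    summary: dict  # median/mean roc_auc, median mcc

    def to_rows(self) -> list[dict]:
        return [{"protein": k, **v} for k, v in self.per_protein.items()]


def per_protein_report(
    predictions: dict, labels: dict, level: str = "surface", threshold: float = 0.5
) -> EvalReport:
    """One metric row per protein plus summary medians.

    ``predictions`` maps protein id -> score vector; ``labels`` maps protein
    id -> binary vector over the same ids (for residue level, restrict both
    to surface-exposed residues before calling).  Proteins missing labels
    are skipped with a warning; single-class proteins are skipped likewise.
    """
    ids = [k for k in predictions if k in labels]
    if not ids:
        raise ValueError("no protein id shared between predictions and labels")
    for k in predictions:
        if k not in labels:
            warnings.warn(f"protein {k} has no labels; skipped")
    per = {}
    for k in ids:
        s = np.asarray(predictions[k], dtype=float)
        y = np.asarray(labels[k]).astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"protein {k} has single-class labels; skipped")
            continue
        per[k] = {
            "roc_auc": roc_auc(s, y),
            "mcc": mcc(binarize(s, threshold), y),
            "n_pos": int(y.sum()),
            "n_neg": int((1 - y).sum()),
            "level": level,
        }
    if not per:
        raise ValueError("no protein with both classes present")
    aucs = [v["roc_auc"] for v in per.values()]
    mccs = [v["mcc"] for v in per.values()]
    summary = {
        "median_roc_auc": float(np.median(aucs)),
        "mean_roc_auc": float(np.mean(aucs)),
        "median_mcc": float(np.median(mccs)),
        "n_proteins": len(per),
    }
    return EvalReport(per_protein=per, summary=summary)


def grouped_kfold(proteins: list[tuple[str, str]], k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign whole groups (superfamilies) to folds, balancing fold sizes.

    Groups are placed greedily, largest first (ties shuffled by seed), each
    into the currently smallest fold, so no group ever spans folds.
    Returns a map protein id -> fold index.
    """
    groups: dict[str, list[str]] = {}
    for pid, g in proteins:
        groups.setdefault(g, []).append(pid)
    if k > len(groups):
        raise ValueError(f"k={k} exceeds number of groups ({len(groups)})")
    rng = np.random.default_rng(seed)
    names = list(groups)
    rng.shuffle(names)
    names.sort(key=lambda g: -len(groups[g]))  # stable: ties keep shuffled order
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for g in names:
        fold = int(np.argmin(fold_sizes))
        for pid in groups[g]:
            assignment[pid] = fold
        fold_sizes[fold] += len(groups[g])
    return assignment
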