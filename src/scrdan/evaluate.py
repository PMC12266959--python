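"""Annotation and batch-correction metrics.

Annotation quality is the unweighted mean of per-cell-type recall
(accuracy_c = correct_c / true_c averaged over the K types present in the
truth), which is robust to class imbalance. Batch-correction quality is the
silhouette score of the cell types on the joint source+target embedding:
a(i) is the mean within-cluster distance, b(i) the smallest mean distance to
another cluster, s(i) = (b - a) / max(a, b), and the score averages s(i)
over all cells. Both metrics are computed from first principles here; an
established library implementation serves as a cross-check in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def mean_class_accuracy(
    predicted, truth
) -> tuple[dict[str, float], float]:
    """Per-class recall and its unweighted mean over classes in the truth."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"{len(predicted)} predictions for {len(truth)} true labels"
        )
    if not truth:
        raise ValueError("truth is empty")
    per_class: dict[str, float] = {}
    for cls in sorted(set(truth)):
        idx = [i for i, t in enumerate(truth) if t == cls]
        correct = sum(1 for i in idx if predicted[i] == cls)
        per_class[cls] = correct / len(idx)
    return per_class, float(np.mean(list(per_class.values())))


def confusion_table(predicted, truth) -> pd.DataFrame:
    """Counts with true classes as rows, predicted classes as columns
    (union of both label sets so spurious predictions stay visible)."""
    predicted, truth = list(predicted), list(truth)
    classes = sorted(set(truth) | set(predicted))
    table = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, predicted):
        table.loc[t, p] += 1
    table.index.name = "true"
    table.columns.name = "predicted"
    return table


def silhouette(embeddings: np.ndarray, cluster_labels, metric: str = "euclidean") -> float:
    """Mean silhouette width over all cells; singleton clusters score 0."""
    X = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(cluster_labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("one label per embedding row required")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(X, X, metric)
    n = X.shape[0]
    members = {c: np.flatnonzero(labels == c) for c in classes}
    s = np.zeros(n)
    for c in classes:
        idx = members[c]
        if idx.size == 1:
            s[idx[0]] = 0.0  # a(i) undefined for singletons
            continue
        a = D[np.ix_(idx, idx)].sum(axis=1) / (idx.size - 1)
        b = np.full(idx.size, np.inf)
        for other in classes:
            if other == c:
                continue
            b = np.minimum(b, D[np.ix_(idx, members[other])].mean(axis=1))
        s[idx] = (b - a) / np.maximum(a, b)
    return float(s.mean())


@dataclass
class EvalReport:
    per_class_accuracy: dict[str, float] | None
    mean_accuracy: float | None
    silhouette_celltype: float
    silhouette_batch: float
    confusion: pd.DataFrame | None
    n_source_cells: int
    n_target_cells: int

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": self.per_class_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "silhouette_celltype": self.silhouette_celltype,
            "silhouette_batch": self.silhouette_batch,
            "confusion": None
            if self.confusion is None
            else self.confusion.to_dict(),
            "n_source_cells": self.n_source_cells,
            "n_target_cells": self.n_target_cells,
        }

    def save(self, path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        if self.confusion is not None:
            self.confusion.to_csv(path.with_suffix(".confusion.tsv"), sep="\t")


def evaluate_embeddings(
    source_embeddings: np.ndarray,
    target_embeddings: np.ndarray,
    source_types,
    target_types,
) -> tuple[float, float]:
    """Cell-type and batch silhouettes on the joint embedding.

    High cell-type silhouette means types separate while batches mix (good
    correction); the batch silhouette is a diagnostic — near or below zero
    means the two batches are indistinguishable in the latent space.
    """
    Z = np.vstack([source_embeddings, target_embeddings])
    types = list(source_types) + list(target_types)
    batches = ["source"] * len(source_embeddings) + ["target"] * len(
        target_embeddings
    )
    return silhouette(Z, types), silhouette(Z, batches)
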