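"""Ranking input statistics by informativeness for each output variable.

Two schemes over a trained network and a test set:

* permutation importance: permute one statistic's values across the test
  datasets and record the resulting accuracy decrease -- the increase in
  mean relative size error for each of N1/N2/N3, and the increase in
  misclassification rate for selection;
* perturbation importance: shift one statistic by +/-delta (clamped to
  the [0,1] feature scale) and record the mean absolute change in each
  output -- in the normalized size prediction for N1/N2/N3, and in the
  class-probability vector (mean absolute probability change) for
  selection.

Both are deterministic given seed/delta.  The perturbation scheme is
this package's own protocol, not a reproduction of any particular
published variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Model, denormalize_targets, feed_forward

OUTPUTS = ("N1", "N2", "N3", "selection")


@dataclass
class ImportanceTable:
    scores: pd.DataFrame          # rows: statistics; columns: OUTPUTS
    top_k: dict[str, list[str]]   # per output, the k most important names
    method: str

    def membership_matrix(self) -> pd.DataFrame:
        """Top-k membership of each statistic across the four outputs
        (the data behind a 4-way Venn diagram)."""
        names = sorted({n for v in self.top_k.values() for n in v})
        return pd.DataFrame(
            {out: [n in self.top_k[out] for n in names] for out in OUTPUTS},
            index=names)


def _names(model: Model, n_feat: int) -> list[str]:
    if model.feature_names and len(model.feature_names) == n_feat:
        return list(model.feature_names)
    return [f"stat_{i}" for i in range(n_feat)]


def _size_errors(model: Model, X: np.ndarray, lam_true: np.ndarray) -> np.ndarray:
    raw = feed_forward(X, model.weights).linear
    lam_hat = denormalize_targets(raw, model.config.prior_bounds)
    return np.mean(np.abs(lam_hat - lam_true) / np.abs(lam_true), axis=0)


def _misclassification(model: Model, X: np.ndarray, y_class: np.ndarray) -> float:
    probs = feed_forward(X, model.weights).probs
    return float(np.mean(probs.argmax(axis=1) != y_class))


def _top_k(scores: pd.DataFrame, k: int) -> dict[str, list[str]]:
    return {out: scores[out].nlargest(k).index.tolist() for out in OUTPUTS}


def permutation_importance(model: Model, test_features: np.ndarray,
                           test_lambdas: np.ndarray, test_classes: np.ndarray,
                           k: int = 25, seed: int = 0) -> ImportanceTable:
    """Accuracy decrease when each statistic is permuted across datasets."""
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    lam_true = np.atleast_2d(np.asarray(test_lambdas, dtype=float))
    y_class = np.asarray(test_classes)
    base_err = _size_errors(model, X, lam_true)
    base_mis = _misclassification(model, X, y_class)
    rng = np.random.default_rng(seed)
    rows = np.empty((X.shape[1], 4))
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
        rows[j, :3] = _size_errors(model, Xp, lam_true) - base_err
        rows[j, 3] = _misclassification(model, Xp, y_class) - base_mis
    scores = pd.DataFrame(rows, index=_names(model, X.shape[1]),
                          columns=OUTPUTS)
    return ImportanceTable(scores, _top_k(scores, k), "permutation")


def perturbation_importance(model: Model, test_features: np.ndarray,
                            k: int = 25, delta: float = 0.05) -> ImportanceTable:
    """Mean absolute output change under +/-delta input perturbations."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    base = feed_forward(X, model.weights)
    rows = np.zeros((X.shape[1], 4))
    for j in range(X.shape[1]):
        acc = np.zeros(4)
        for sign in (+1.0, -1.0):
            Xp = X.copy()
            Xp[:, j] = np.clip(Xp[:, j] + sign * delta, 0.0, 1.0)
            tr = feed_forward(Xp, model.weights)
            acc[:3] += np.mean(np.abs(tr.linear - base.linear), axis=0)
            acc[3] += np.mean(np.abs(tr.probs - base.probs))
        rows[j] = acc / 2.0
    scores = pd.DataFrame(rows, index=_names(model, X.shape[1]),
                          columns=OUTPUTS)
    return ImportanceTable(scores, _top_k(scores, k), "perturbation")
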