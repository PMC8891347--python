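"""Assignment-performance evaluation: confusion matrices, accuracy /
efficiency / power across posterior thresholds, and hybrid-detection error
rates.

Definitions (per class c, at posterior threshold t):

* an individual is *assigned* iff its maximum posterior >= t;
* accuracy  = correct assignments to c / all assignments to c;
* efficiency = correct assignments to c / number of true-c individuals;
* power = accuracy x efficiency;
* Type I error = pure individuals max-assigned to any hybrid class / pure;
* Type II error = hybrid individuals max-assigned to any pure class / hybrids.

Accuracy is undefined (``nan``) for a class receiving no assignments at a
threshold; such cells are reported missing, never zero.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .crosses import CLASSES

__all__ = [
    "DEFAULT_THRESHOLDS",
    "confusion_matrix",
    "power_curves",
    "error_rates",
    "plot_power_curves",
]

#: Threshold grid for power curves (0.50 to 0.95 in steps of 0.05).
DEFAULT_THRESHOLDS: np.ndarray = np.round(np.arange(0.50, 0.951, 0.05), 2)

_PURE = {"pure0", "pure1"}


def _check_labels(labels) -> list[str]:
    labels = list(labels)
    bad = set(labels) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside the six classes: {sorted(bad)}")
    return labels


def confusion_matrix(
    true_labels, assigned_classes, max_posteriors=None, threshold: float = 0.0
) -> pd.DataFrame:
    """Row-normalised confusion matrix (rows = true class, columns =
    assigned class).

    Without a threshold every individual is assigned to its max-posterior
    class. With ``threshold > 0`` (requires ``max_posteriors``), individuals
    below the threshold fall into an extra ``unassigned`` column; rows still
    sum to 1.
    """
    true_labels = _check_labels(true_labels)
    assigned = _check_labels(assigned_classes)
    if len(true_labels) != len(assigned):
        raise ValueError("label vectors must have equal length")
    cols = list(CLASSES)
    if threshold > 0:
        if max_posteriors is None:
            raise ValueError("threshold > 0 requires max_posteriors")
        mp = np.asarray(max_posteriors, dtype=float)
        assigned = [a if m >= threshold else "unassigned" for a, m in zip(assigned, mp)]
        cols = cols + ["unassigned"]

    mat = pd.crosstab(pd.Series(true_labels, name="true"), pd.Series(assigned, name="assigned"))
    mat = mat.reindex(index=list(CLASSES), columns=cols, fill_value=0)
    mat = mat.loc[mat.sum(axis=1) > 0]
    return mat.div(mat.sum(axis=1), axis=0)


def power_curves(
    posteriors: pd.DataFrame | np.ndarray,
    true_labels,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-class accuracy, efficiency and power over a threshold grid.

    ``posteriors`` is either the assignment result DataFrame (with
    ``assigned_class`` and ``max_posterior`` columns) or a raw (n, 6)
    posterior array in canonical class order.

    Returns a tidy DataFrame with columns ``threshold, class, n_true,
    n_assigned, accuracy, efficiency, power``.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(thresholds < 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie in [0, 1)")
    true_labels = np.asarray(_check_labels(true_labels))

    if isinstance(posteriors, pd.DataFrame):
        assigned = posteriors["assigned_class"].to_numpy()
        maxpost = posteriors["max_posterior"].to_numpy()
    else:
        post = np.asarray(posteriors, dtype=float)
        assigned = np.asarray(CLASSES)[post.argmax(axis=1)]
        maxpost = post.max(axis=1)
    if assigned.shape[0] != true_labels.shape[0]:
        raise ValueError("posteriors and true labels disagree in length")

    rows = []
    for t in thresholds:
        is_assigned = maxpost >= t
        for c in CLASSES:
            true_c = true_labels == c
            assigned_c = is_assigned & (assigned == c)
            n_true = int(true_c.sum())
            n_assigned = int(assigned_c.sum())
            correct = int((assigned_c & true_c).sum())
            accuracy = correct / n_assigned if n_assigned else np.nan
            efficiency = correct / n_true if n_true else np.nan
            rows.append(
                {
                    "threshold": t,
                    "class": c,
                    "n_true": n_true,
                    "n_assigned": n_assigned,
                    "accuracy": accuracy,
                    "efficiency": efficiency,
                    "power": accuracy * efficiency,
                }
            )
    return pd.DataFrame(rows)


def error_rates(assigned_classes, true_labels) -> tuple[float, float]:
    """Hybrid-detection error rates from max-posterior assignments.

    Returns ``(type_I, type_II)``: the fraction of true-pure individuals
    assigned to any hybrid class, and the fraction of true-hybrid
    individuals assigned to any pure class.
    """
    true_labels = np.asarray(_check_labels(true_labels))
    assigned = np.asarray(_check_labels(assigned_classes))
    is_pure_true = np.isin(true_labels, list(_PURE))
    is_pure_assigned = np.isin(assigned, list(_PURE))
    n_pure = int(is_pure_true.sum())
    n_hyb = int((~is_pure_true).sum())
    if n_pure == 0 or n_hyb == 0:
        raise ValueError("need at least one pure and one hybrid individual")
    type1 = float((is_pure_true & ~is_pure_assigned).sum() / n_pure)
    type2 = float((~is_pure_true & is_pure_assigned).sum() / n_hyb)
    return type1, type2


def plot_power_curves(curves: pd.DataFrame, path, metric: str = "power") -> None:
    """Write a per-class metric-vs-threshold plot (one line per class)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c, sub in curves.groupby("class"):
        ax.plot(sub["threshold"], sub[metric], marker="o", label=c)
    ax.set_xlabel("critical posterior probability threshold")
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
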