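"""Diagnostic plots and summaries for the MDS-space classification.

``accuracy_vs_subset_size`` reproduces the coordinate-selection
diagnostic: leave-one-out accuracy/precision of the classifier built on
the first k dominant MDS coordinates versus the best subset of k
coordinates, for k = 1..max_k.  ``plot_embedding`` scatters subjects in
the first two MDS dimensions colored by group.
"""

from __future__ import annotations

import numpy as np

from . import distclassify
from .distclassify import Embedding, _counts_from_predictions, _labels_to01


def accuracy_vs_subset_size(
    embedding: Embedding,
    y,
    n_dims: int = 15,
    max_k: int = 6,
    discriminant: str = "linear",
) -> dict:
    """LOO accuracy/precision of first-k vs best-k coordinate sets."""
    import itertools

    coords = np.atleast_2d(embedding.coords)
    n_dims = min(n_dims, coords.shape[1])
    y01 = _labels_to01(y)
    first_acc, best_acc, first_prec, best_prec = [], [], [], []
    for k in range(1, max_k + 1):
        pred = distclassify.loo_predictions(coords[:, :k], y01, discriminant)
        c = _counts_from_predictions(pred, y01)
        first_acc.append((c.TP + c.TN) / c.N)
        first_prec.append(c.TP / (c.TP + c.FP) if c.TP + c.FP else np.nan)
        bk = (-1.0, -1.0)
        for subset in itertools.combinations(range(n_dims), k):
            pred = distclassify.loo_predictions(coords[:, subset], y01,
                                                discriminant)
            c = _counts_from_predictions(pred, y01)
            acc = (c.TP + c.TN) / c.N
            prec = c.TP / (c.TP + c.FP) if c.TP + c.FP else -1.0
            bk = max(bk, (acc, prec))
        best_acc.append(bk[0])
        best_prec.append(bk[1])
    return {"k": list(range(1, max_k + 1)),
            "first_accuracy": first_acc, "best_accuracy": best_acc,
            "first_precision": first_prec, "best_precision": best_prec}


def plot_embedding(embedding: Embedding, labels: dict[str, str], ax=None):
    """Scatter of subjects in the first two MDS coordinates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = embedding.coords
    for group, color in (("control", "tab:blue"), ("patient", "tab:red")):
        sel = [i for i, s in enumerate(embedding.subject_ids)
               if labels[s] == group]
        ax.scatter(coords[sel, 0], coords[sel, 1] if coords.shape[1] > 1
                   else np.zeros(len(sel)), c=color, label=group, s=30)
    ax.set_xlabel("MDS dim 1")
    ax.set_ylabel("MDS dim 2")
    ax.legend()
    return ax


def plot_accuracy_vs_subset_size(curves: dict, ax=None):
    """Companion plot for :func:`accuracy_vs_subset_size`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curves["k"], curves["first_accuracy"], "kx-", label="first k coords")
    ax.plot(curves["k"], curves["best_accuracy"], "go-", mfc="none",
            label="best k coords")
    ax.set_xlabel("number of coordinates k")
    ax.set_ylabel("LOO accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return ax
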