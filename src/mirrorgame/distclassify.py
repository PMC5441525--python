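"""Dissimilarity-based classification of distribution features.

The classifier never sees raw feature vectors.  Each subject is a
distribution (histogram, bivariate histogram or frequency profile);
subjects are compared by earth mover's distance (EMD), the resulting
dissimilarity matrix is embedded with classical (Torgerson) MDS, and
linear / pseudo-quadratic Gaussian discriminants are evaluated with
leave-one-out cross-validation on every coordinate subset of size up to
6 drawn from the first 15 MDS dimensions.  The winning subset per
feature is selected by accuracy, then precision; residual ties are fused
by majority vote.  Feature-level classifiers are combined across
features with the same majority rule (patient only if strictly more than
half of the votes say patient).

The MDS embedding is computed once on the full cohort; leave-one-out
applies to the discriminant only.  This mirrors the original procedure
and carries a mild information leak through the embedding, which is a
known property of the method, not corrected here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import mannwhitneyu

from .features_dyad import PhaseLagProfile
from .features_solo import GWS, Hist1D, Hist2D

__all__ = [
    "DistanceMatrix", "Embedding", "ClassifierSpec", "ConfusionCounts",
    "ClassificationResult", "emd", "emd_hist1d", "emd_profile", "emd_hist2d",
    "pairwise_distance_matrix", "classical_mds", "loo_discriminant_eval",
    "subset_search_select", "classification_metrics", "majority_vote",
    "questionnaire_classify", "count_subsets", "loo_predictions",
]

PATIENT, CONTROL = "patient", "control"


# --------------------------------------------------------------------------- #
# types
# --------------------------------------------------------------------------- #

@dataclass
class DistanceMatrix:
    subject_ids: list[str]
    D: np.ndarray
    feature_name: str = ""

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.subject_ids),) * 2:
            raise ValueError("D must be square over subject_ids")
        if not np.allclose(D, D.T, atol=1e-9):
            raise ValueError("D must be symmetric")
        if np.any(np.diag(D) > 1e-9) or np.any(D < -1e-12):
            raise ValueError("D must be non-negative with zero diagonal")
        self.D = D


@dataclass
class Embedding:
    coords: np.ndarray             # (n_subjects, n_dims), eigenvalue order
    eigenvalues: np.ndarray
    subject_ids: list[str]
    n_dropped_negative: int = 0


@dataclass(frozen=True)
class ClassifierSpec:
    feature_name: str
    coord_subset: tuple[int, ...]
    discriminant: str              # "linear" | "pseudo_quadratic"


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ClassificationResult:
    predictions: dict[str, str]
    counts: ConfusionCounts
    metrics: dict[str, float]
    spec: object = None            # ClassifierSpec, list of them, or a string


# --------------------------------------------------------------------------- #
# earth mover's distance
# --------------------------------------------------------------------------- #

def emd_1d(mass_p: np.ndarray, mass_q: np.ndarray, coords: np.ndarray) -> float:
    """Exact 1-D EMD: L1 distance between CDFs weighted by bin spacing.

    ``coords`` are the (sorted) bin-center positions; the cost of moving
    mass between adjacent bins is their center distance.
    """
    mass_p = np.asarray(mass_p, float)
    mass_q = np.asarray(mass_q, float)
    coords = np.asarray(coords, float)
    if mass_p.shape != mass_q.shape or mass_p.shape != coords.shape:
        raise ValueError("mismatched supports")
    for m in (mass_p, mass_q):
        if abs(m.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must have unit mass")
    cdf_diff = np.cumsum(mass_p - mass_q)[:-1]
    return float(np.sum(np.abs(cdf_diff) * np.diff(coords)))


def emd_hist1d(p: Hist1D, q: Hist1D) -> float:
    if not np.allclose(p.edges, q.edges):
        raise ValueError("histograms must share bin edges")
    return emd_1d(p.mass, q.mass, p.centers)


def _profile_mass(prof) -> np.ndarray:
    if isinstance(prof, GWS):
        v = prof.power.astype(float)
    elif isinstance(prof, PhaseLagProfile):
        v = np.nan_to_num(prof.abs_lag, nan=0.0)
    else:
        raise TypeError(f"not a profile feature: {type(prof)}")
    s = v.sum()
    if s <= 0:
        raise ValueError("profile has no mass")
    return v / s


def emd_profile(p, q) -> float:
    """EMD between unit-mass-normalized frequency profiles.

    Frequencies lie on a dyadic (log-spaced) scale grid, so the natural
    ground metric is the scale index: adjacent scale steps are unit
    distance apart.
    """
    if not np.allclose(p.freqs, q.freqs):
        raise ValueError("profiles must share the frequency grid")
    coords = np.arange(len(p.freqs), dtype=float)
    return emd_1d(_profile_mass(p), _profile_mass(q), coords)


def emd_transport_lp(
    pos_p: np.ndarray, w_p: np.ndarray,
    pos_q: np.ndarray, w_q: np.ndarray,
) -> float:
    """Exact transportation LP between weighted point sets (HiGHS).

    Euclidean ground metric between support points; weights must each
    sum to 1.
    """
    w_p = np.asarray(w_p, float)
    w_q = np.asarray(w_q, float)
    if abs(w_p.sum() - 1) > 1e-6 or abs(w_q.sum() - 1) > 1e-6:
        raise ValueError("weights must sum to 1")
    npts, mpts = len(w_p), len(w_q)
    C = np.linalg.norm(pos_p[:, None, :] - pos_q[None, :, :], axis=-1)
    idx = np.arange(npts * mpts).reshape(npts, mpts)
    rows = np.concatenate([np.repeat(np.arange(npts), mpts),
                           npts + np.tile(np.arange(mpts), npts)])
    cols = np.concatenate([idx.ravel(), idx.ravel(order="C")])
    data = np.ones(2 * npts * mpts)
    A = sparse.csr_matrix((data, (rows, cols)), shape=(npts + mpts, npts * mpts))
    res = linprog(C.ravel(), A_eq=A, b_eq=np.concatenate([w_p, w_q]),
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


def emd_hist2d(p: Hist2D, q: Hist2D) -> float:
    """Exact 2-D EMD over the non-zero bins of two shared-grid histograms.

    Bin centers are standardized per axis by the cohort axis_scales
    before applying the Euclidean ground metric.
    """
    if not (np.allclose(p.edges_x, q.edges_x) and np.allclose(p.edges_y, q.edges_y)):
        raise ValueError("histograms must share the grid")
    sx, sy = p.axis_scales

    def support(h: Hist2D):
        ii, jj = np.nonzero(h.mass)
        pos = np.column_stack([h.centers_x[ii] / sx, h.centers_y[jj] / sy])
        return pos, h.mass[ii, jj]

    pos_p, w_p = support(p)
    pos_q, w_q = support(q)
    return emd_transport_lp(pos_p, w_p, pos_q, w_q)


def emd(p, q) -> float:
    """Dispatch EMD by feature type (shared support required)."""
    if isinstance(p, Hist1D) and isinstance(q, Hist1D):
        return emd_hist1d(p, q)
    if isinstance(p, Hist2D) and isinstance(q, Hist2D):
        return emd_hist2d(p, q)
    if isinstance(p, (GWS, PhaseLagProfile)) and type(p) is type(q):
        return emd_profile(p, q)
    raise TypeError(f"cannot compare features of type {type(p)} and {type(q)}")


def pairwise_distance_matrix(
    features: dict[str, object], feature_name: str = ""
) -> DistanceMatrix:
    """Symmetric EMD matrix over all subjects for one feature channel."""
    ids = sorted(features)
    missing = [s for s in ids if features[s] is None]
    if missing:
        raise ValueError(f"missing feature for subjects: {missing}")
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = emd(features[ids[i]], features[ids[j]])
    return DistanceMatrix(subject_ids=ids, D=D, feature_name=feature_name)


# --------------------------------------------------------------------------- #
# classical MDS
# --------------------------------------------------------------------------- #

def classical_mds(dm: DistanceMatrix, n_dims: int = 15) -> Embedding:
    """Torgerson MDS: eigen-decomposition of the double-centered squared
    distance matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues, in descending eigenvalue order; dimensions
    with non-positive eigenvalues are dropped and counted.  Axis signs
    are canonicalized so the largest-magnitude loading is positive.
    """
    D = dm.D
    n = len(D)
    if n_dims > n - 1:
        n_dims = n - 1
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * max(eigval.max(), 1.0))
    pos = eigval > tol
    n_dropped = int(np.sum(~pos[:n_dims]))
    keep = min(n_dims, int(pos.sum()))
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for k in range(coords.shape[1]):        # sign canonicalization
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    return Embedding(coords=coords, eigenvalues=eigval,
                     subject_ids=list(dm.subject_ids),
                     n_dropped_negative=n_dropped)


# --------------------------------------------------------------------------- #
# discriminants with leave-one-out cross-validation
# --------------------------------------------------------------------------- #

def _batched_pinv_logpdet(covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moore-Penrose pseudo-inverse and pseudo-log-determinant of a stack
    of symmetric matrices (eigenvalues below a relative tolerance are
    treated as zero)."""
    w, V = np.linalg.eigh(covs)
    wmax = np.maximum(w.max(axis=-1, keepdims=True), 1e-300)
    mask = w > np.maximum(1e-10 * wmax, 1e-14)
    w_inv = np.where(mask, 1.0 / np.where(mask, w, 1.0), 0.0)
    pinv = np.einsum("...ik,...k,...jk->...ij", V, w_inv, V)
    logpdet = np.sum(np.where(mask, np.log(np.where(mask, w, 1.0)), 0.0), axis=-1)
    return pinv, logpdet


def loo_predictions(X: np.ndarray, y01: np.ndarray, discriminant: str) -> np.ndarray:
    """Leave-one-out class predictions of a Gaussian discriminant.

    ``y01`` holds 0 (control) / 1 (patient).  "linear" pools the class
    scatters into one covariance per fold; "pseudo_quadratic" fits one
    covariance per class with pseudo-inverse and pseudo-log-determinant,
    so singular scatters are tolerated.  Priors are the training-fold
    class frequencies.  All folds are evaluated in one batched
    computation via leave-one-out downdates of the class sums and
    scatter matrices.  Returns a boolean array (True = patient).
    """
    X = np.atleast_2d(np.asarray(X, float))
    n, d = X.shape
    y01 = np.asarray(y01, int)
    if set(np.unique(y01)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if n != len(y01):
        raise ValueError("X and y length mismatch")
    n1 = int(y01.sum())
    n0 = n - n1
    if min(n0, n1) < 2:
        raise ValueError("each class needs >= 2 members for leave-one-out")

    S = np.stack([X[y01 == 0].sum(axis=0), X[y01 == 1].sum(axis=0)])     # (2, d)
    M = np.stack([X[y01 == 0].T @ X[y01 == 0], X[y01 == 1].T @ X[y01 == 1]])
    counts = np.array([n0, n1], float)

    own = np.eye(2)[y01]                                # (n, 2) membership
    n_eff = counts[None, :] - own                       # (n, 2)
    S_eff = S[None, :, :] - own[:, :, None] * X[:, None, :]
    mu = S_eff / n_eff[:, :, None]
    xxT = np.einsum("ni,nj->nij", X, X)
    M_eff = M[None] - own[:, :, None, None] * xxT[:, None]
    scatter = M_eff - n_eff[:, :, None, None] * np.einsum(
        "nci,ncj->ncij", mu, mu)

    priors = n_eff / (n - 1)
    diff = X[:, None, :] - mu                           # (n, 2, d)
    if discriminant == "linear":
        pooled = scatter.sum(axis=1) / np.maximum(n - 1 - 2, 1)   # (n, d, d)
        pinv, logpdet = _batched_pinv_logpdet(pooled)
        maha = np.einsum("nci,nij,ncj->nc", diff, pinv, diff)
        score = np.log(priors) - 0.5 * maha - 0.5 * logpdet[:, None]
    elif discriminant == "pseudo_quadratic":
        covs = scatter / np.maximum(n_eff - 1, 1)[:, :, None, None]
        pinv, logpdet = _batched_pinv_logpdet(covs)
        maha = np.einsum("nci,ncij,ncj->nc", diff, pinv, diff)
        score = np.log(priors) - 0.5 * maha - 0.5 * logpdet
    else:
        raise ValueError(f"unknown discriminant {discriminant!r}")
    return score[:, 1] > score[:, 0]


def _counts_from_predictions(pred_patient: np.ndarray, y01: np.ndarray
                             ) -> ConfusionCounts:
    y = y01.astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(pred_patient & y)),
        FP=int(np.sum(pred_patient & ~y)),
        TN=int(np.sum(~pred_patient & ~y)),
        FN=int(np.sum(~pred_patient & y)),
    )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and precision from counts.

    Patient is the positive class.  Precision is NaN when no subject is
    predicted patient.
    """
    if counts.N == 0:
        raise ValueError("empty confusion counts")
    if counts.TP + counts.FN == 0 or counts.TN + counts.FP == 0:
        raise ValueError("both true classes must be present")
    return {
        "accuracy": (counts.TP + counts.TN) / counts.N,
        "sensitivity": counts.TP / (counts.TP + counts.FN),
        "specificity": counts.TN / (counts.TN + counts.FP),
        "precision": (counts.TP / (counts.TP + counts.FP)
                      if counts.TP + counts.FP > 0 else float("nan")),
    }


def _result(pred_patient: np.ndarray, y01: np.ndarray, ids: list[str],
            spec) -> ClassificationResult:
    counts = _counts_from_predictions(pred_patient, y01)
    return ClassificationResult(
        predictions={s: (PATIENT if p else CONTROL)
                     for s, p in zip(ids, pred_patient)},
        counts=counts,
        metrics=classification_metrics(counts),
        spec=spec,
    )


def loo_discriminant_eval(
    X: np.ndarray, y: list[str] | np.ndarray, discriminant: str = "linear",
    subject_ids: list[str] | None = None, spec=None,
) -> ClassificationResult:
    """Leave-one-out evaluation of one discriminant on one coordinate set."""
    y01 = _labels_to01(y)
    ids = subject_ids if subject_ids is not None else [str(i) for i in range(len(y01))]
    pred = loo_predictions(np.atleast_2d(X), y01, discriminant)
    return _result(pred, y01, ids, spec)


def _labels_to01(y) -> np.ndarray:
    y = list(y)
    bad = set(y) - {CONTROL, PATIENT}
    if bad:
        raise ValueError(f"unknown labels {bad}")
    return np.array([1 if v == PATIENT else 0 for v in y], int)


# --------------------------------------------------------------------------- #
# exhaustive coordinate-subset search (Steps 4-7)
# --------------------------------------------------------------------------- #

def iter_subsets(n_dims: int, max_size: int = 6):
    """Coordinate subsets in size-then-lexicographic order."""
    for k in range(1, max_size + 1):
        yield from itertools.combinations(range(n_dims), k)


def count_subsets(n_dims: int = 15, max_size: int = 6) -> int:
    return sum(math.comb(n_dims, k) for k in range(1, max_size + 1))


def _majority_fuse(pred_matrix: np.ndarray) -> np.ndarray:
    """Row-wise majority over classifier predictions (columns); a subject
    is patient only if strictly more than half the votes say patient."""
    votes = pred_matrix.sum(axis=1)
    return votes * 2 > pred_matrix.shape[1]


def _search_one_discriminant(coords: np.ndarray, y01: np.ndarray,
                             discriminant: str, max_size: int):
    best_key = (-1.0, -1.0)
    best_specs: list[tuple[int, ...]] = []
    best_preds: list[np.ndarray] = []
    for subset in iter_subsets(coords.shape[1], max_size):
        pred = loo_predictions(coords[:, subset], y01, discriminant)
        counts = _counts_from_predictions(pred, y01)
        acc = (counts.TP + counts.TN) / counts.N
        prec = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else -1.0
        key = (acc, prec)
        if key > best_key:
            best_key, best_specs, best_preds = key, [subset], [pred]
        elif key == best_key:
            best_specs.append(subset)
            best_preds.append(pred)
    fused = _majority_fuse(np.column_stack(best_preds))
    return best_key, best_specs, fused


def subset_search_select(
    embedding: Embedding,
    y: list[str] | np.ndarray,
    n_dims: int = 15,
    max_subset_size: int = 6,
    discriminants: tuple[str, ...] = ("linear", "pseudo_quadratic"),
    feature_name: str = "",
) -> dict:
    """Exhaustive subset search over MDS coordinates with the selection
    and tie-breaking rules of the classification procedure.

    For each discriminant, every coordinate subset of size 1..6 of the
    first ``n_dims`` dimensions is scored by leave-one-out accuracy;
    ties are broken by precision and residual ties fused by majority
    vote over the tied classifiers.  The better discriminant (accuracy,
    then precision; linear on a full tie) provides the channel's result.
    """
    coords = np.atleast_2d(embedding.coords)
    avail = coords.shape[1]
    use_dims = min(n_dims, avail)
    coords = coords[:, :use_dims]
    y01 = _labels_to01(y)
    per_disc = {}
    for disc in discriminants:
        per_disc[disc] = _search_one_discriminant(
            coords, y01, disc, max_subset_size)
    # choose the discriminant by its best-subset accuracy, then precision;
    # deterministic preference order on a full tie (linear first)
    winner = max(per_disc, key=lambda dname: (per_disc[dname][0],
                                              -discriminants.index(dname)))
    key, specs, fused = per_disc[winner]
    best_specs = [ClassifierSpec(feature_name=feature_name, coord_subset=s,
                                 discriminant=winner) for s in specs]
    result = _result(fused, y01, embedding.subject_ids, best_specs)
    return {"best": best_specs, "result": result,
            "n_dims_used": use_dims, "discriminant": winner}


# --------------------------------------------------------------------------- #
# majority rule over feature channels
# --------------------------------------------------------------------------- #

def majority_vote(
    per_feature_predictions: dict[str, dict[str, str]],
    labels: dict[str, str],
) -> ClassificationResult:
    """Fuse feature-level predictions with the strict majority rule.

    A subject is classified patient only when strictly more than half of
    the feature-level classifiers vote patient (a tie counts as
    control: 2 of 2 yes, 1 of 2 no, 2 of 3 yes, 2 of 4 no, 3 of 5 yes).
    """
    if not per_feature_predictions:
        raise ValueError("need >= 1 feature channel")
    ids = sorted(labels)
    for fname, preds in per_feature_predictions.items():
        if sorted(preds) != ids:
            raise ValueError(f"feature {fname!r} does not cover all subjects")
    mat = np.column_stack([
        [per_feature_predictions[f][s] == PATIENT for s in ids]
        for f in sorted(per_feature_predictions)
    ])
    fused = _majority_fuse(mat)
    y01 = _labels_to01([labels[s] for s in ids])
    return _result(fused, y01, ids,
                   spec=f"majority({', '.join(sorted(per_feature_predictions))})")


# --------------------------------------------------------------------------- #
# questionnaire variant
# --------------------------------------------------------------------------- #

def questionnaire_classify(
    table: np.ndarray,
    y: list[str] | np.ndarray,
    item_names: list[str] | None = None,
    prescreen_p: float = 0.3,
    prescreen_k: int = 15,
    max_subset_size: int = 6,
) -> dict:
    """Classify subjects from ordinal questionnaire items.

    Item columns are used directly as coordinates.  When more than
    ``prescreen_k`` items are present, a two-sided rank-sum test per
    item prescreens them: the ``prescreen_k`` items with the lowest
    p-values among those with p < ``prescreen_p`` are kept (fewer if
    fewer qualify).  Constant columns are excluded.  The subset search,
    both discriminants, leave-one-out evaluation and tie rules then run
    exactly as for MDS coordinates.
    """
    table = np.atleast_2d(np.asarray(table, float))
    n, n_items = table.shape
    y01 = _labels_to01(y)
    if len(y01) != n:
        raise ValueError("table and labels length mismatch")
    names = item_names if item_names is not None else [f"item{k:02d}"
                                                       for k in range(n_items)]
    variable = [k for k in range(n_items) if np.ptp(table[:, k]) > 0]
    excluded_constant = [names[k] for k in range(n_items) if k not in variable]

    if len(variable) > prescreen_k:
        pvals = {}
        for k in variable:
            a = table[y01 == 0, k]
            b = table[y01 == 1, k]
            pvals[k] = float(mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic").pvalue)
        qualifying = [k for k in variable if pvals[k] < prescreen_p]
        kept = sorted(qualifying, key=lambda k: (pvals[k], k))[:prescreen_k]
        kept = sorted(kept)
    else:
        kept = variable
    if not kept:
        raise ValueError("no items survive the prescreen")

    emb = Embedding(coords=table[:, kept], eigenvalues=np.zeros(len(kept)),
                    subject_ids=[f"s{i:03d}" for i in range(n)])
    out = subset_search_select(emb, y, n_dims=len(kept),
                               max_subset_size=max_subset_size,
                               feature_name="questionnaire")
    out["kept_items"] = [names[k] for k in kept]
    out["excluded_constant_items"] = excluded_constant
    # map subset indices back to item names
    out["best"] = [
        ClassifierSpec(feature_name="questionnaire",
                       coord_subset=tuple(kept[i] for i in s.coord_subset),
                       discriminant=s.discriminant)
        for s in out["best"]
    ]
    return out
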