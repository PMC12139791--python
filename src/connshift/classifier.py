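"""Paired leave-one-subject-out condition classification.

A linear soft-margin SVM is trained to separate the two drug conditions from
upper-triangle Fisher-z edge vectors. Cross-validation leaves one *subject*
out per fold — both of that subject's condition scans are held out together
(or the single scan, if only one survived QC) — so no subject's data leaks
between train and test. Significance comes from a permutation null that
flips each subject's MA/PL label pair with probability 1/2, preserving the
paired structure, and reruns the full cross-validation.

Fold fits go through scikit-learn's SVC. The permutation loop uses a
precomputed linear Gram matrix, which is mathematically identical to the
linear kernel on features but avoids re-touching the (often much wider)
feature matrix in every fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from connshift.io import ConnMatrix, EdgeMask, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0


@dataclass(frozen=True)
class Design:
    """Scan-by-edge feature matrix with labels and subject grouping."""

    X: np.ndarray             # (n_scans, n_edges) Fisher-z edge vectors
    y: np.ndarray             # (n_scans,) condition labels "MA"/"PL"
    subjects: np.ndarray      # (n_scans,) subject ids
    edge_i: np.ndarray        # kept upper-triangle row indices
    edge_j: np.ndarray        # kept upper-triangle col indices
    n_nodes: int
    n_dropped_edges: int = 0

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    @property
    def subject_ids(self) -> list[str]:
        return sorted(set(self.subjects.tolist()))

    def devectorize(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Mirror an edge vector back into a symmetric node×node matrix.

        Dropped edges and the diagonal get ``fill``.
        """
        m = np.full((self.n_nodes, self.n_nodes), fill, dtype=float)
        m[self.edge_i, self.edge_j] = values
        m[self.edge_j, self.edge_i] = values
        return m


def build_design(conns: Sequence[ConnMatrix | tuple[str, str, ConnMatrix]]) -> Design:
    """Vectorize connectomes into a scan×edge design.

    Each entry is either a ConnMatrix carrying ``meta`` (subject_id and
    condition) or an explicit ``(subject_id, condition, conn)`` tuple.
    Edges that are NaN in *any* scan are dropped globally so every scan sees
    the same feature space.
    """
    rows, labels, subjects = [], [], []
    n_nodes = None
    for entry in conns:
        if isinstance(entry, ConnMatrix):
            if entry.meta is None:
                raise ValidationError("ConnMatrix without meta; pass (subject, condition, conn)")
            subj, cond, conn = entry.meta.subject_id, entry.meta.condition, entry
        else:
            subj, cond, conn = entry
        if n_nodes is None:
            n_nodes = conn.n_nodes
        elif conn.n_nodes != n_nodes:
            raise ValidationError("all connectomes must share the node count")
        iu = np.triu_indices(n_nodes, k=1)
        rows.append(conn.values[iu])
        labels.append(cond)
        subjects.append(subj)
    if n_nodes is None:
        raise ValidationError("no connectomes supplied")
    X = np.asarray(rows)
    iu = np.triu_indices(n_nodes, k=1)
    keep = ~np.isnan(X).any(axis=0)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("zero usable edges after NaN drop")
    if n_dropped:
        logger.info("build_design: dropped %d edge(s) NaN in at least one scan", n_dropped)
    return Design(X=X[:, keep], y=np.asarray(labels), subjects=np.asarray(subjects),
                  edge_i=iu[0][keep], edge_j=iu[1][keep],
                  n_nodes=n_nodes, n_dropped_edges=n_dropped)


@dataclass(frozen=True)
class ClassifierReport:
    """Paired-LOSO cross-validation output."""

    per_fold_predictions: dict   # subject -> list of (true, predicted)
    accuracy: float              # pooled over all held-out scans
    fold_weights: np.ndarray     # (n_folds, n_edges) primal weight vectors
    mean_weights: np.ndarray     # node×node fold-averaged symmetric weight map
    svc_C: float


def _folds(subjects: np.ndarray) -> list[tuple[str, np.ndarray, np.ndarray]]:
    out = []
    for subj in sorted(set(subjects.tolist())):
        test = subjects == subj
        out.append((subj, ~test, test))
    return out


def _check_design(y: np.ndarray, subjects: np.ndarray) -> None:
    if len(set(subjects.tolist())) < 3:
        raise ValidationError("paired LOSO needs at least 3 subjects")
    if set(y.tolist()) - {"MA", "PL"}:
        raise ValidationError("labels must be MA/PL")


def loso_paired_cv(design: Design, svc_C: float = DEFAULT_C) -> ClassifierReport:
    """Leave-one-subject-out linear SVM over paired condition scans.

    One fold per subject; the fold's model is a linear-kernel soft-margin SVM
    (regularization ``svc_C``, no feature standardization — Fisher-z edges
    share a scale). Accuracy pools over every held-out scan. Per-fold primal
    weight vectors are kept and averaged (as-is, no sign alignment) into a
    symmetric node×node weight map.
    """
    _check_design(design.y, design.subjects)
    preds: dict = {}
    weights = []
    n_correct = 0
    n_total = 0
    for subj, train, test in _folds(design.subjects):
        y_train = design.y[train]
        if len(set(y_train.tolist())) < 2:
            raise ValidationError(f"fold {subj}: training set is single-class")
        clf = SVC(kernel="linear", C=svc_C)
        clf.fit(design.X[train], y_train)
        y_hat = clf.predict(design.X[test])
        preds[subj] = list(zip(design.y[test].tolist(), y_hat.tolist()))
        n_correct += int((y_hat == design.y[test]).sum())
        n_total += int(test.sum())
        # sklearn orients the primal w toward classes_[-1]; flip so that a
        # positive weight always marks an edge stronger under MA
        w = clf.coef_.ravel().copy()
        if clf.classes_[-1] != "MA":
            w = -w
        weights.append(w)
    fold_weights = np.asarray(weights)
    mean_w = fold_weights.mean(axis=0)
    return ClassifierReport(per_fold_predictions=preds,
                            accuracy=n_correct / n_total,
                            fold_weights=fold_weights,
                            mean_weights=design.devectorize(mean_w),
                            svc_C=svc_C)


def _cv_accuracy_gram(G: np.ndarray, y: np.ndarray, subjects: np.ndarray,
                      svc_C: float) -> float:
    """LOSO accuracy using a precomputed linear Gram matrix (no weights)."""
    n_correct = 0
    n_total = 0
    for subj, train, test in _folds(subjects):
        y_train = y[train]
        if len(set(y_train.tolist())) < 2:
            raise ValidationError(f"fold {subj}: training set is single-class")
        clf = SVC(kernel="precomputed", C=svc_C)
        clf.fit(G[np.ix_(train, train)], y_train)
        y_hat = clf.predict(G[np.ix_(test, train)])
        n_correct += int((y_hat == y[test]).sum())
        n_total += int(test.sum())
    return n_correct / n_total


def loso_accuracy(design: Design, svc_C: float = DEFAULT_C) -> float:
    """Pooled LOSO accuracy via the Gram-matrix fast path (identical decisions
    to :func:`loso_paired_cv`, but no weight extraction)."""
    _check_design(design.y, design.subjects)
    G = design.X @ design.X.T
    return _cv_accuracy_gram(G, design.y, design.subjects, svc_C)


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    perm_p: float               # (1 + #{null >= observed}) / (1 + n_perm)


def _flip_pairs(y: np.ndarray, subjects: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flipped = y.copy()
    swap = {"MA": "PL", "PL": "MA"}
    for subj in sorted(set(subjects.tolist())):
        if rng.random() < 0.5:
            idx = subjects == subj
            flipped[idx] = [swap[l] for l in y[idx]]
    return flipped


def permutation_test(design: Design, n_perm: int, seed: int,
                     svc_C: float = DEFAULT_C,
                     scheme: str = "pair_flip") -> PermutationResult:
    """Permutation null for the paired-LOSO accuracy.

    ``pair_flip`` (default) flips each subject's MA/PL labels together with
    probability 1/2, which respects exchangeability under the paired design;
    ``full_shuffle`` permutes all scan labels globally. Each permutation
    reruns the full cross-validation. The p-value uses the add-one estimator
    (1 + #{null ≥ observed}) / (1 + n_perm), never exactly zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if scheme not in ("pair_flip", "full_shuffle"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")
    _check_design(design.y, design.subjects)
    rng = np.random.default_rng(seed)
    G = design.X @ design.X.T
    observed = _cv_accuracy_gram(G, design.y, design.subjects, svc_C)
    null = np.empty(n_perm)
    for k in range(n_perm):
        if scheme == "pair_flip":
            y_perm = _flip_pairs(design.y, design.subjects, rng)
        else:
            y_perm = rng.permutation(design.y)
        null[k] = _cv_accuracy_gram(G, y_perm, design.subjects, svc_C)
    perm_p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed_accuracy=observed,
                             null_accuracies=null, perm_p=perm_p)


@dataclass(frozen=True)
class EdgeSelection:
    """Top-weight edge sets from the fold-averaged SVM weight map."""

    positive_mask: EdgeMask
    negative_mask: EdgeMask
    pos_threshold: float
    neg_threshold: float
    rule: str


def select_edges(mean_weights: np.ndarray, rule: str = "absolute",
                 pos_threshold: float | None = None,
                 neg_threshold: float | None = None,
                 q: float | None = None) -> EdgeSelection:
    """Extract the most condition-discriminative edges from a weight map.

    ``absolute``: edges with mean weight > pos_threshold form the positive
    (condition A > B) mask, < neg_threshold the negative mask.
    ``percentile``: the floor(q% · n_finite) largest weights per side; ties
    broken by edge order; realized cutoffs are reported as the thresholds.
    NaN (dropped) edges are never selected. Empty selections warn.
    """
    w = np.asarray(mean_weights, dtype=float)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    finite = np.isfinite(vals)
    pos = np.zeros(vals.shape, dtype=bool)
    neg = np.zeros(vals.shape, dtype=bool)
    if rule == "absolute":
        if pos_threshold is None or neg_threshold is None:
            raise ValidationError("absolute rule needs pos_threshold and neg_threshold")
        pos = finite & (vals > pos_threshold)
        neg = finite & (vals < neg_threshold)
        pos_thr, neg_thr = float(pos_threshold), float(neg_threshold)
    elif rule == "percentile":
        if q is None:
            raise ValidationError("percentile rule needs q")
        n_take = int(np.floor(q / 100.0 * finite.sum()))
        order = np.argsort(vals[finite], kind="stable")
        fin_idx = np.where(finite)[0]
        if n_take > 0:
            pos[fin_idx[order[-n_take:]]] = True
            neg[fin_idx[order[:n_take]]] = True
        overlap = pos & neg
        if overlap.any():  # q > 50%: a single edge cannot sit in both sets
            pos &= ~overlap
            neg &= ~overlap
        pos_thr = float(vals[pos].min()) if pos.any() else np.nan
        neg_thr = float(vals[neg].max()) if neg.any() else np.nan
    else:
        raise ValidationError(f"unknown selection rule {rule!r}")
    if not pos.any() or not neg.any():
        warnings.warn("edge selection produced an empty mask", stacklevel=2)

    def _to_mask(sel: np.ndarray, label: str) -> EdgeMask:
        m = np.zeros((n, n), dtype=np.int8)
        m[iu[0][sel], iu[1][sel]] = 1
        return EdgeMask(m + m.T, label=label)

    return EdgeSelection(positive_mask=_to_mask(pos, "svc_positive"),
                         negative_mask=_to_mask(neg, "svc_negative"),
                         pos_threshold=pos_thr, neg_threshold=neg_thr, rule=rule)
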