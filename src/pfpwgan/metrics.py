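"""Evaluation measures: protein-centric Fmax, term-centric F1/AUPR/AUC/MCC,
the true-path-rule conflict score, and the term co-occurrence heatmap.

Conventions
-----------
* The threshold grid has 100 evenly spaced values spanning [0, 1]; a term is
  predicted at threshold ``t`` iff its score is ``>= t`` (so ``t = 0`` is the
  all-positive prediction).
* A 0/0 precision or recall is defined as 0 and the protein still counts in
  the protein averages.  The CAFA refinement (averaging precision only over
  proteins with at least one prediction) is available via ``cafa_precision``.
* Term-centric measures are undefined (NaN) for terms without positives
  (and, for AUC, without negatives); macro averages exclude those terms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .annotations import AnnotationMatrix
from .go_dag import OntologyDag

__all__ = [
    "threshold_grid",
    "protein_prf",
    "fmax",
    "term_f1",
    "term_aupr",
    "term_auc_mcc",
    "tpr_score",
    "cooccurrence_heatmap",
    "heatmap_mse",
    "f1_by_height",
    "f1_by_sample_count",
    "EvalReport",
    "evaluate",
]


def threshold_grid(n: int = 100) -> np.ndarray:
    """100 evenly spaced thresholds from 0 to 1 inclusive."""
    return np.linspace(0.0, 1.0, n)


def _binary(a) -> np.ndarray:
    a = a.values if isinstance(a, AnnotationMatrix) else np.asarray(a)
    return a.astype(bool)


def protein_prf(truth_row, scores_row, t: float):
    """Precision/recall and confusion counts of one protein at threshold t."""
    truth = np.asarray(truth_row, dtype=bool)
    pred = np.asarray(scores_row) >= t
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return prec, rec, tp, fp, fn


def fmax(truth, scores, grid: np.ndarray | None = None, cafa_precision: bool = False):
    """Protein-centric Fmax: max over thresholds of the harmonic mean of the
    protein-averaged precision and recall.  Returns ``(fmax, threshold)``."""
    truth = _binary(truth)
    scores = np.asarray(scores, dtype=float)
    if truth.shape != scores.shape:
        raise ValueError("truth and score matrices must have equal shape")
    if truth.shape[0] == 0:
        raise ValueError("Fmax requires at least one protein")
    grid = threshold_grid() if grid is None else np.asarray(grid)
    n_true = truth.sum(axis=1)
    best_f, best_t = 0.0, float(grid[0])
    for t in grid:
        pred = scores >= t
        tp = (pred & truth).sum(axis=1)
        n_pred = pred.sum(axis=1)
        prec = np.divide(tp, n_pred, out=np.zeros(len(tp)), where=n_pred > 0)
        rec = np.divide(tp, n_true, out=np.zeros(len(tp)), where=n_true > 0)
        if cafa_precision:
            predicting = n_pred > 0
            ave_pr = prec[predicting].mean() if predicting.any() else 0.0
        else:
            ave_pr = prec.mean()
        ave_re = rec.mean()
        f = 2 * ave_pr * ave_re / (ave_pr + ave_re) if ave_pr + ave_re > 0 else 0.0
        if f > best_f:
            best_f, best_t = float(f), float(t)
    return best_f, best_t


def term_f1(truth_col, scores_col, grid: np.ndarray | None = None) -> float:
    """Term-centric F1: max over thresholds, counts over samples.

    NaN for terms with no positive samples.
    """
    truth = np.asarray(truth_col, dtype=bool)
    scores = np.asarray(scores_col, dtype=float)
    pos = int(truth.sum())
    if pos == 0:
        return float("nan")
    grid = threshold_grid() if grid is None else np.asarray(grid)
    best = 0.0
    for t in grid:
        pred = scores >= t
        tp = int((pred & truth).sum())
        fp = int((pred & ~truth).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / pos
        f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        best = max(best, f)
    return best


def term_aupr(truth_col, scores_col) -> float:
    """Area under the precision-recall curve by trapezoidal integration.

    The curve is evaluated at every unique score cut point (prediction =
    score >= cut); it is anchored at recall 0 with the precision of the
    highest cut.  NaN when the term has no positives.
    """
    truth = np.asarray(truth_col, dtype=bool)
    scores = np.asarray(scores_col, dtype=float)
    P = int(truth.sum())
    if P == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    cum_tp = np.cumsum(truth[order])
    # last index of each run of equal scores = the >= cut containing the run
    boundary = np.flatnonzero(np.diff(s) != 0)
    cut = np.append(boundary, len(s) - 1)
    tp = cum_tp[cut]
    n_pred = cut + 1
    prec = tp / n_pred
    rec = tp / P
    r = np.concatenate(([0.0], rec))
    p = np.concatenate(([prec[0]], prec))
    return float(np.trapezoid(p, r))


def term_auc_mcc(truth_col, scores_col, mcc_threshold: float = 0.5):
    """ROC AUC (rank statistic, ties at 1/2) and MCC at a fixed threshold.

    AUC is NaN for degenerate columns (no positive or no negative sample);
    MCC is 0 whenever a confusion-matrix marginal is zero.
    """
    truth = np.asarray(truth_col, dtype=int)
    scores = np.asarray(scores_col, dtype=float)
    if truth.min() == truth.max():
        auc = float("nan")
    else:
        auc = float(roc_auc_score(truth, scores))
    pred = (scores >= mcc_threshold).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(truth, pred))
    return auc, mcc


def micro_f1(truth, scores, threshold: float) -> float:
    """F1 over the pooled protein x term confusion counts at one threshold."""
    t = _binary(truth)
    pred = np.asarray(scores) >= threshold
    tp = int((pred & t).sum())
    fp = int((pred & ~t).sum())
    fn = int((~pred & t).sum())
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def tpr_score(dag: OntologyDag, predicted: AnnotationMatrix) -> float:
    """Expected number of true-path conflicts per protein.

    For every annotated term, counts its ancestors (restricted to the
    evaluated term set) missing from the protein's annotation, summed over
    terms and averaged over proteins.
    """
    terms = predicted.terms
    ti = {t: j for j, t in enumerate(terms)}
    c = len(terms)
    anc = np.zeros((c, c), dtype=np.int64)
    for j, t in enumerate(terms):
        for a in dag.ancestors(t):
            k = ti.get(a)
            if k is not None:
                anc[j, k] = 1
    v = predicted.values.astype(np.int64)
    anc_sizes = anc.sum(axis=1)
    # conflicts per protein: sum_j v_j * |anc(j)| - sum_j v_j * |anc(j) ∩ annot|
    present = v @ anc.T  # (n, c): for each term j, how many of anc(j) are annotated
    conflicts = (v * (anc_sizes[None, :] - present)).sum(axis=1)
    return float(conflicts.mean())


def cooccurrence_heatmap(assignments) -> np.ndarray:
    """c x c binary matrix: 1 iff some protein carries both terms."""
    v = _binary(assignments).astype(np.int64)
    return ((v.T @ v) > 0).astype(np.int8)


def heatmap_mse(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared entrywise difference (= disagreement fraction when binary)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("heatmap shapes differ")
    return float(np.mean((predicted.astype(float) - truth.astype(float)) ** 2))


def f1_by_height(dag: OntologyDag, terms, f1_values) -> dict:
    """Mean term-centric F1 grouped by term height (NaN terms excluded)."""
    groups: dict[int, list] = {}
    for t, f in zip(terms, np.asarray(f1_values, dtype=float)):
        if np.isnan(f):
            continue
        groups.setdefault(dag.term_height(t), []).append(f)
    return {h: float(np.mean(v)) for h, v in sorted(groups.items())}


def f1_by_sample_count(truth, f1_values) -> list:
    """(number of positive samples, F1) pairs per defined term."""
    v = _binary(truth)
    out = []
    for j, f in enumerate(np.asarray(f1_values, dtype=float)):
        if np.isnan(f):
            continue
        out.append((int(v[:, j].sum()), float(f)))
    return out


@dataclass
class EvalReport:
    """Bundle of every evaluation measure for one model on one dataset."""

    fmax: float
    fmax_threshold: float
    terms: list
    term_f1: np.ndarray
    term_aupr: np.ndarray
    term_auc: np.ndarray
    term_mcc: np.ndarray
    macro_f1: float
    macro_aupr: float
    macro_auc: float
    macro_mcc: float
    tpr_score: float
    heatmap: np.ndarray
    per_height_f1: dict = field(default_factory=dict)
    per_sample_count_f1: list = field(default_factory=list)
    heatmap_mse_vs_truth: float | None = None

    def summary(self) -> dict:
        out = {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "macro_f1": self.macro_f1,
            "macro_aupr": self.macro_aupr,
            "macro_auc": self.macro_auc,
            "macro_mcc": self.macro_mcc,
            "tpr_score": self.tpr_score,
        }
        if self.heatmap_mse_vs_truth is not None:
            out["heatmap_mse_vs_truth"] = self.heatmap_mse_vs_truth
        return out

    def to_json(self, path) -> None:
        payload = dict(self.summary())
        payload["per_height_f1"] = {str(k): v for k, v in self.per_height_f1.items()}
        payload["per_sample_count_f1"] = self.per_sample_count_f1
        payload["terms"] = list(self.terms)
        payload["term_f1"] = [None if np.isnan(v) else float(v) for v in self.term_f1]
        payload["term_aupr"] = [None if np.isnan(v) else float(v) for v in self.term_aupr]
        payload["term_auc"] = [None if np.isnan(v) else float(v) for v in self.term_auc]
        payload["term_mcc"] = [float(v) for v in self.term_mcc]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _nanmean(a: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    good = ~np.isnan(a)
    return float(a[good].mean()) if good.any() else float("nan")


def evaluate(truth: AnnotationMatrix, scores: np.ndarray, dag: OntologyDag,
             mcc_threshold: float = 0.5, cafa_precision: bool = False,
             truth_heatmap: np.ndarray | None = None) -> EvalReport:
    """Full evaluation of a score matrix against a propagated truth matrix.

    Predictions are binarized at the Fmax-maximizing threshold for the
    conflict score and the co-occurrence heatmap.
    """
    scores = np.asarray(scores, dtype=float)
    grid = threshold_grid()
    fm, ft = fmax(truth, scores, grid, cafa_precision=cafa_precision)
    c = len(truth.terms)
    t_f1 = np.array([term_f1(truth.values[:, j], scores[:, j], grid) for j in range(c)])
    t_aupr = np.array([term_aupr(truth.values[:, j], scores[:, j]) for j in range(c)])
    auc_mcc = [term_auc_mcc(truth.values[:, j], scores[:, j], mcc_threshold) for j in range(c)]
    t_auc = np.array([a for a, _ in auc_mcc])
    t_mcc = np.array([m for _, m in auc_mcc])
    binarized = AnnotationMatrix(list(truth.proteins), list(truth.terms),
                                 (scores >= ft).astype(np.int8))
    heat = cooccurrence_heatmap(binarized)
    report = EvalReport(
        fmax=fm,
        fmax_threshold=ft,
        terms=list(truth.terms),
        term_f1=t_f1,
        term_aupr=t_aupr,
        term_auc=t_auc,
        term_mcc=t_mcc,
        macro_f1=_nanmean(t_f1),
        macro_aupr=_nanmean(t_aupr),
        macro_auc=_nanmean(t_auc),
        macro_mcc=float(np.mean(t_mcc)),
        tpr_score=tpr_score(dag, binarized),
        heatmap=heat,
        per_height_f1=f1_by_height(dag, truth.terms, t_f1),
        per_sample_count_f1=f1_by_sample_count(truth, t_f1),
        heatmap_mse_vs_truth=(heatmap_mse(heat, truth_heatmap)
                              if truth_heatmap is not None else None),
    )
    return report
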