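"""Naive reference implementations used as independent oracles.

Everything here is written as plain loops over definitions — no vectorizing,
no reuse of package internals — so agreement with the package is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np


def naive_protein_prf(truth_row, scores_row, t):
    tp = fp = fn = 0
    for y, s in zip(truth_row, scores_row):
        pred = s >= t
        if pred and y:
            tp += 1
        elif pred and not y:
            fp += 1
        elif not pred and y:
            fn += 1
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return prec, rec


def naive_fmax(truth, scores, grid):
    best = 0.0
    for t in grid:
        precs, recs = [], []
        for i in range(len(truth)):
            p, r = naive_protein_prf(truth[i], scores[i], t)
            precs.append(p)
            recs.append(r)
        ap = sum(precs) / len(precs)
        ar = sum(recs) / len(recs)
        f = 2 * ap * ar / (ap + ar) if ap + ar > 0 else 0.0
        best = max(best, f)
    return best


def naive_term_f1(truth_col, scores_col, grid):
    pos = sum(int(v) for v in truth_col)
    if pos == 0:
        return float("nan")
    best = 0.0
    for t in grid:
        tp = fp = 0
        for y, s in zip(truth_col, scores_col):
            if s >= t:
                if y:
                    tp += 1
                else:
                    fp += 1
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / pos
        f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        best = max(best, f)
    return best


def naive_term_aupr(truth_col, scores_col):
    pos = sum(int(v) for v in truth_col)
    if pos == 0:
        return float("nan")
    cuts = sorted(set(scores_col), reverse=True)
    points = []
    for c in cuts:
        tp = fp = 0
        for y, s in zip(truth_col, scores_col):
            if s >= c:
                if y:
                    tp += 1
                else:
                    fp += 1
        points.append((tp / pos, tp / (tp + fp)))
    points = [(0.0, points[0][1])] + points
    area = 0.0
    for (r1, p1), (r2, p2) in zip(points, points[1:]):
        area += (r2 - r1) * (p1 + p2) / 2.0
    return area


def naive_ancestors(parents: dict, term):
    result = set()
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents[t]:
            if p not in result:
                result.add(p)
                frontier.append(p)
    return result


def naive_height(parents: dict, term):
    """Longest path to a root by exhaustive path enumeration."""
    if not parents[term]:
        return 0
    return 1 + max(naive_height(parents, p) for p in parents[term])


def naive_tpr(parents: dict, terms, values):
    total = 0
    for row in values:
        annot = {terms[j] for j in range(len(terms)) if row[j]}
        for t in annot:
            anc = naive_ancestors(parents, t) & set(terms)
            total += len(anc - annot)
    return total / len(values)


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random acyclic parent map: node i draws 1-2 parents among nodes < i."""
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = 1 if i == 1 else int(rng.integers(1, 3))
        ps = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = {terms[int(p)] for p in ps}
    return terms, parents
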