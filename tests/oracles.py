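"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, exhaustive threshold enumeration,
pair-counting formulas) and written without reference to the package's
implementation paths, so they can serve as oracles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ari_bruteforce(a, b) -> float:
    """Adjusted Rand index by direct pair counting."""
    a = list(a)
    b = list(b)
    n = len(a)
    assert len(b) == n
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    index = ss
    expected = (ss + sd) * (ss + ds) / total
    maximum = 0.5 * ((ss + sd) + (ss + ds))
    if maximum == expected:
        return 1.0
    return (index - expected) / (maximum - expected)


def auprc_bruteforce(labels, scores) -> float:
    """Area under the precision-recall curve by exhaustive threshold
    enumeration with the step-wise (average-precision) rule."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    assert 0 < n_pos < len(labels)
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        predicted = scores >= t
        tp = int(((labels == 1) & predicted).sum())
        fp = int(((labels == 0) & predicted).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def cluster_impute_bruteforce(cell_states: dict, assignment: dict,
                              site, cell, exclude_self: bool = False):
    """Cluster-mean level by an explicit loop over member cells' states.

    cell_states: {cell: {site: state}}; returns None when no member covers
    the site (after optional exclusion of the target cell's own entry).
    """
    cluster = assignment[cell]
    num = den = 0
    for other, states in cell_states.items():
        if assignment[other] != cluster:
            continue
        if exclude_self and other == cell:
            continue
        if site in states:
            num += states[site]
            den += 1
    if den == 0:
        return None
    return num / den


def quality_score_bruteforce(probs_by_pos: dict, target_pos: int,
                             n_side: int = 5):
    """Mean |p(target) - p(neighbor)| over the n_side nearest positions on
    each side (borrowing across the target when one side runs short).

    probs_by_pos: {position: probability} for one cell on one chromosome.
    """
    positions = sorted(probs_by_pos)
    i = positions.index(target_pos)
    up = positions[:i]
    down = positions[i + 1:]
    want = 2 * n_side
    take_up = min(n_side + max(0, n_side - len(down)), len(up))
    take_down = min(n_side + max(0, n_side - len(up)), len(down))
    neighbors = up[len(up) - take_up:] + down[:take_down]
    neighbors = neighbors[:want]
    if not neighbors:
        return None
    target = probs_by_pos[target_pos]
    return float(np.mean([abs(target - probs_by_pos[p]) for p in neighbors]))
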