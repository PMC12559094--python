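"""Independent oracles used by the test suite.

These deliberately re-derive quantities by a different route from the
package: exhaustive enumeration for the sign test, pairwise counting for the
AUC, an all-point (exact-area) precision-recall integral for AP, a
shapely-based greedy matcher for detection assignment, and networkx maximum
bipartite matching for feasibility of the stage-1 caliper matching.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from shapely.geometry import box as shapely_box


def enumeration_sign_p(n_pos: int, n_neg: int) -> float:
    """Two-sided sign-test p by brute force over all 2^m equiprobable sign vectors."""
    m = n_pos + n_neg
    k = max(n_pos, n_neg)
    hits = 0
    for signs in product((0, 1), repeat=m):
        s = sum(signs)
        if max(s, m - s) >= k:
            hits += 1
    return hits / 2**m


def pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs won, ties counted half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def allpoint_ap(tp_flags: np.ndarray, n_truth: int) -> float:
    """Exact area under the interpolated precision-recall curve (all-point AP)."""
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if len(tp_flags) == 0 or n_truth == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    precision = tp_cum / np.arange(1, len(tp_flags) + 1)
    recall = tp_cum / n_truth
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(env, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def shapely_iou(b1, b2) -> float:
    g1 = shapely_box(b1.x_min, b1.y_min, b1.x_max, b1.y_max)
    g2 = shapely_box(b2.x_min, b2.y_min, b2.x_max, b2.y_max)
    inter = g1.intersection(g2).area
    union = g1.union(g2).area
    return inter / union if union > 0 else 0.0


def greedy_match_oracle(dets, truths: dict, iou_threshold: float):
    """Independent greedy confidence-ordered matcher (shapely geometry).

    Returns (tp_count, fp_count, fn_count) pooled over images.
    """
    order = sorted(
        dets,
        key=lambda d: (-d.confidence, d.image_id, d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max),
    )
    used: dict[str, set[int]] = {img: set() for img in truths}
    tp = 0
    for d in order:
        boxes = truths.get(d.image_id, [])
        candidates = [
            (shapely_iou(d.box, t), j)
            for j, t in enumerate(boxes)
            if j not in used.get(d.image_id, set())
        ]
        if not candidates:
            continue
        best_iou, best_j = max(candidates)
        if best_iou >= iou_threshold:
            used[d.image_id].add(best_j)
            tp += 1
    n_truth = sum(len(b) for b in truths.values())
    return tp, len(order) - tp, n_truth - tp


def perfect_matching_exists(anchors, candidates, caliper: float) -> bool:
    """Can every anchor be paired to a distinct candidate (same projection,
    age within caliper)?  Maximum bipartite matching via networkx."""
    import networkx as nx

    g = nx.Graph()
    a_nodes = [("a", a.image_id) for a in anchors]
    g.add_nodes_from(a_nodes, bipartite=0)
    g.add_nodes_from((("c", c.image_id) for c in candidates), bipartite=1)
    for a in anchors:
        for c in candidates:
            if a.projection == c.projection and abs(a.patient_age - c.patient_age) <= caliper:
                g.add_edge(("a", a.image_id), ("c", c.image_id))
    if not anchors:
        return True
    matching = nx.algorithms.bipartite.maximum_matching(g, top_nodes=a_nodes)
    return sum(1 for n in matching if n[0] == "a") == len(anchors)
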