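"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a plain scalar loop from the definition of the
quantity, deliberately sharing no code with the package, so that
agreement is evidence and not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special, stats


def brute_path_length(points) -> float:
    total = 0.0
    for (x1, y1), (x2, y2) in zip(points[:-1], points[1:]):
        total += math.hypot(x2 - x1, y2 - y1)
    return total


def brute_direction_changes(points, angle_threshold=90.0, min_step=2.0) -> int:
    """Jitter-merge steps forward, then count turning angles >= threshold
    using the atan2 formulation."""
    vecs = []
    ax = ay = 0.0
    for (x1, y1), (x2, y2) in zip(points[:-1], points[1:]):
        ax += x2 - x1
        ay += y2 - y1
        if math.hypot(ax, ay) >= min_step:
            vecs.append((ax, ay))
            ax = ay = 0.0
    count = 0
    for (ux, uy), (vx, vy) in zip(vecs[:-1], vecs[1:]):
        cross = ux * vy - uy * vx
        dot = ux * vx + uy * vy
        angle = abs(math.degrees(math.atan2(cross, dot)))
        if angle >= angle_threshold - 1e-9:
            count += 1
    return count


def brute_event_runs(z, threshold=2.0, min_gap=1):
    """Sample-by-sample scanner for supra-threshold runs with gap merging."""
    events = []
    in_event = False
    start = None
    last_end = None
    for i, zi in enumerate(z):
        if zi >= threshold:
            if not in_event:
                if events and last_end is not None and i - last_end - 1 < min_gap:
                    start = events.pop()[0]  # merge with previous run
                else:
                    start = i
                in_event = True
        else:
            if in_event:
                events.append((start, i - 1))
                last_end = i - 1
                in_event = False
    if in_event:
        events.append((start, len(z) - 1))
    return events


def brute_point_in_polygon(r: float, c: float, vertices) -> bool:
    """Scalar even-odd (ray casting) test for one point."""
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if r1 == r2:
            continue
        if (r1 > r) != (r2 > r):
            c_at = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_at:
                inside = not inside
    return inside


def brute_max_counts(records) -> dict:
    """Max projections per cell from (cell_id, frame, n) triples."""
    out: dict = {}
    for cell_id, _frame, n in records:
        out[cell_id] = max(out.get(cell_id, 0), n)
    return out


def brute_welch(a, b):
    """Textbook Welch two-sample t with Welch-Satterthwaite df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def brute_anova(groups):
    """Textbook one-way ANOVA F and p from sums of squares."""
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    return f, p


def brute_zscore(values):
    """Two-pass mean/SD (ddof=1) z-scoring as a scalar loop."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return [(v - mean) / sd for v in values]


def brute_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency table, comb-by-comb."""
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    n = len(labels_a)
    table = {
        (ai, bi): sum(
            1 for x, y in zip(labels_a, labels_b) if x == ai and y == bi
        )
        for ai in a_vals
        for bi in b_vals
    }
    comb2 = lambda m: special.comb(m, 2, exact=True)
    sum_ij = sum(comb2(v) for v in table.values())
    sum_a = sum(comb2(sum(table[(ai, bi)] for bi in b_vals)) for ai in a_vals)
    sum_b = sum(comb2(sum(table[(ai, bi)] for ai in a_vals)) for bi in b_vals)
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def brute_kmeans_partition(X, k):
    """Globally optimal k-partition by exhaustive assignment enumeration
    (tiny n only).  Returns the label vector minimizing WCSS."""
    X = np.asarray(X, float)
    n = len(X)
    best_labels, best_wcss = None, math.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        wcss = 0.0
        for ci in range(k):
            pts = X[[i for i in range(n) if labels[i] == ci]]
            wcss += ((pts - pts.mean(axis=0)) ** 2).sum()
        if wcss < best_wcss - 1e-12:
            best_wcss = wcss
            best_labels = labels
    return list(best_labels), best_wcss
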