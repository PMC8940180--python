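"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: explicit loops
for means and covariances, np.linalg.eig (not eigh), exhaustive window
scans, and direct counting.
"""

from __future__ import annotations

import numpy as np


def brute_bgpca(X: np.ndarray, labels):
    """Between-group PCA by explicit summation and a generic eigensolver.

    Returns (axes, scores, variance_explained) with the same orientation
    convention as the implementation (largest-|loading| positive).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    levels = sorted(set(labels))
    g = len(levels)
    means = np.zeros((g, p))
    for a, lv in enumerate(levels):
        rows = [i for i in range(n) if labels[i] == lv]
        for j in range(p):
            s = 0.0
            for i in rows:
                s += X[i, j]
            means[a, j] = s / len(rows)
    grand = np.zeros(p)
    for j in range(p):
        for a in range(g):
            grand[j] += means[a, j] / g
    cov = np.zeros((p, p))
    for a in range(g):
        d = means[a] - grand
        cov += np.outer(d, d) / g
    vals, vecs = np.linalg.eig(cov)
    vals, vecs = np.real(vals), np.real(vecs)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(g - 1, p)
    keep = min(keep, int(np.sum(vals > 1e-12 * max(vals[0], 0))) if vals[0] > 0 else 0)
    axes = vecs[:, :keep]
    for j in range(axes.shape[1]):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    scores = (X - grand) @ axes
    total = 0.0
    for j in range(p):
        col = X[:, j]
        m = col.mean()
        total += ((col - m) ** 2).sum() / (n - 1)
    ve = np.array(
        [((scores[:, j] - scores[:, j].mean()) ** 2).sum() / (n - 1) / total
         for j in range(axes.shape[1])]
    )
    return axes, scores, ve


def brute_hpd(values, mass: float):
    """Exhaustive scan over every window of ceil(mass*n) sorted values."""
    x = sorted(float(v) for v in values)
    n = len(x)
    w = int(np.ceil(mass * n))
    if w >= n:
        return x[0], x[-1]
    best = None
    for i in range(n - w + 1):
        width = x[i + w - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, x[i], x[i + w - 1])
    return best[1], best[2]


def brute_newick_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of a Newick tree by direct recursive
    descent over the string (no tree library)."""
    import re

    s = newick.strip().rstrip(";")
    s = re.sub(r":[0-9.eE+-]+", "", s)  # drop branch lengths
    pos = 0

    def parse():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse()]
            while s[pos] == ",":
                pos += 1
                children.append(parse())
            assert s[pos] == ")"
            pos += 1
            # skip internal label
            m = re.match(r"[^,()\s;]+", s[pos:])
            if m:
                pos += m.end()
            return ("clade", children)
        m = re.match(r"[^,()\s;]+", s[pos:])
        pos += m.end()
        return ("tip", m.group())

    root = parse()
    all_tips: set[str] = set()
    clades: list[set[str]] = []

    def collect(node):
        if node[0] == "tip":
            all_tips.add(node[1])
            return {node[1]}
        tips = set()
        for c in node[1]:
            tips |= collect(c)
        clades.append(tips)
        return tips

    collect(root)
    anchor = min(all_tips)
    out = set()
    for c in clades:
        side = frozenset(c if anchor not in c else all_tips - c)
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out
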