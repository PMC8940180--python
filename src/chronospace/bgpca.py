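"""Between-group PCA on node-age matrices and factor impact measures.

Between-group PCA (bgPCA) summarizes how a categorical factor (clock
model, substitution model, node-age prior, loci sampling scheme) shifts
posterior node ages.  A PCA is performed on the covariance matrix of the
factor-level mean age vectors, and all samples are projected onto the
resulting axes; the proportion of total age variance captured by those
axes estimates the factor's impact on divergence times.

Level means are unweighted (each level counts equally) and the data are
centered on the grand mean of level means, so unbalanced designs do not
tilt the axes.  Because bgPCA can separate groups by chance, a label
permutation baseline is provided to calibrate observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import ChronospaceMatrix, clade_label, clade_sort_key

__all__ = [
    "BgPCAResult",
    "bgpca",
    "factor_impact",
    "node_shifts",
    "consensus_age_ranges",
    "permutation_baseline",
    "PermutationBaseline",
]

#: eigenvalues below this times the leading eigenvalue are treated as rank 0
RANK_TOLERANCE = 1e-12


@dataclass
class BgPCAResult:
    """Output of one between-group PCA.

    Attributes
    ----------
    factor, levels : the grouping factor and its ordered levels.
    axes : (n_nodes, n_axes) orthonormal loading vectors.
    scores : (n_samples, n_axes) projections of the centered samples, Myr.
    variance_explained : per-axis share of the total age variance.
    group_centroids : level means projected into score space (Myr).
    centroid_distances : pairwise Euclidean distances between centroids.
    """

    factor: str
    levels: list[str]
    axes: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray
    group_centroids: pd.DataFrame
    centroid_distances: pd.DataFrame
    grand_mean: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())

    def loadings_frame(self, node_keys) -> pd.DataFrame:
        labels = [clade_label(k) for k in node_keys]
        cols = [f"bgPC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.axes, index=labels, columns=cols)


def _level_indices(metadata: pd.DataFrame, factor: str) -> dict[str, np.ndarray]:
    if factor not in metadata.columns:
        raise KeyError(
            f"unknown factor {factor!r}; available: "
            + ", ".join(sorted(metadata.columns))
        )
    labels = metadata[factor].astype(str).to_numpy()
    levels = sorted(set(labels))
    return {lv: np.flatnonzero(labels == lv) for lv in levels}


def _group_axes(X: np.ndarray, groups: dict[str, np.ndarray]):
    """Level means, grand mean and orthonormal between-group axes."""
    M = np.vstack([X[idx].mean(axis=0) for idx in groups.values()])
    grand = M.mean(axis=0)
    D = M - grand
    cov = D.T @ D / len(groups)  # denominator g; scale cancels in ratios
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:
        keep = 0
    else:
        keep = int(np.sum(vals > RANK_TOLERANCE * vals[0]))
    keep = min(keep, len(groups) - 1, X.shape[1])
    axes = vecs[:, :keep]
    # deterministic orientation: largest-magnitude loading positive
    for j in range(keep):
        i = int(np.argmax(np.abs(axes[:, j])))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    return M, grand, axes


def total_variance(X: np.ndarray) -> float:
    """Sum of per-node sample variances (denominator n-1)."""
    return float(np.var(X, axis=0, ddof=1).sum())


def bgpca(matrix: ChronospaceMatrix, factor: str) -> BgPCAResult:
    """Between-group PCA of the age matrix for one factor.

    Level mean age vectors are computed, the data are centered on the
    grand mean of level means, and the covariance of the level means is
    eigen-decomposed.  Samples are projected onto eigenvectors with
    non-negligible eigenvalue; the variance explained by an axis is the
    sample variance of scores on it divided by the total variance of the
    age matrix (sum of per-node variances, denominator n-1 throughout).

    Raises
    ------
    ValueError
        If any level has fewer than two samples, or the age matrix is
        constant (zero total variance).
    """
    X = matrix.ages
    groups = _level_indices(matrix.metadata, factor)
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    for lv, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"level {lv!r} of {factor!r} has < 2 samples")
    tot = total_variance(X)
    if tot <= 0:
        raise ValueError("age matrix is constant; no variance to explain")

    M, grand, axes = _group_axes(X, groups)
    scores = (X - grand) @ axes
    if axes.shape[1]:
        ve = np.var(scores, axis=0, ddof=1) / tot
    else:
        ve = np.zeros(0)
    centroids = pd.DataFrame(
        (M - grand) @ axes,
        index=list(groups),
        columns=[f"bgPC{i + 1}" for i in range(axes.shape[1])],
    )
    C = centroids.to_numpy()
    dists = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(axis=2))
    centroid_distances = pd.DataFrame(dists, index=list(groups), columns=list(groups))
    return BgPCAResult(
        factor=factor,
        levels=list(groups),
        axes=axes,
        scores=scores,
        variance_explained=ve,
        group_centroids=centroids,
        centroid_distances=centroid_distances,
        grand_mean=grand,
    )


def factor_impact(
    matrix: ChronospaceMatrix, factors: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, BgPCAResult]]:
    """One bgPCA per factor; rank factors by total variance explained.

    Returns a table (factor, n_levels, n_axes, variance_explained_pct,
    max_centroid_distance) sorted by impact, plus the per-factor results.
    """
    if factors is None:
        factors = matrix.factors()
    if not factors:
        raise ValueError("no factors to analyze")
    results: dict[str, BgPCAResult] = {}
    rows = []
    for f in factors:
        res = bgpca(matrix, f)
        results[f] = res
        off = res.centroid_distances.to_numpy()
        rows.append(
            {
                "factor": f,
                "n_levels": len(res.levels),
                "n_axes": res.n_axes,
                "variance_explained": res.total_variance_explained,
                "variance_explained_pct": 100 * res.total_variance_explained,
                "max_centroid_distance": float(off.max()) if off.size else 0.0,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("variance_explained", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return table, results


def node_shifts(
    matrix: ChronospaceMatrix, factor: str, threshold: float = 20.0
) -> pd.DataFrame:
    """Per-node sensitivity to a factor: the largest absolute difference
    between factor-level mean ages, flagged when it exceeds ``threshold``
    Myr.  Sorted by shift, descending; ties broken by canonical clade
    order.
    """
    groups = _level_indices(matrix.metadata, factor)
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    for lv, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"level {lv!r} of {factor!r} has < 2 samples")
    M = np.vstack([matrix.ages[idx].mean(axis=0) for idx in groups.values()])
    shift = M.max(axis=0) - M.min(axis=0)  # max pairwise |mean difference|
    order = sorted(
        range(len(matrix.node_keys)),
        key=lambda i: (-shift[i], clade_sort_key(matrix.node_keys[i])),
    )
    return pd.DataFrame(
        {
            "node": [clade_label(matrix.node_keys[i]) for i in order],
            "clade_size": [len(matrix.node_keys[i]) for i in order],
            "max_shift": shift[order],
            "flagged": shift[order] > threshold,
        }
    )


def consensus_age_ranges(per_run_medians: pd.DataFrame, top: int | None = None) -> pd.DataFrame:
    """Extremes of run-level median node ages across independent runs.

    ``per_run_medians`` has one row per run and one column per node
    (median posterior age).  Returns per-node (min, max, width), sorted
    by width descending; ``top`` limits the report to the widest ranges.
    """
    if per_run_medians.isna().any().any():
        raise ValueError("runs do not share node keys (missing medians)")
    out = pd.DataFrame(
        {
            "node": per_run_medians.columns,
            "min_age": per_run_medians.min(axis=0).to_numpy(),
            "max_age": per_run_medians.max(axis=0).to_numpy(),
        }
    )
    out["width"] = out["max_age"] - out["min_age"]
    out = out.sort_values(
        ["width", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out.head(top) if top is not None else out


@dataclass
class PermutationBaseline:
    """Null distribution of total variance explained under label shuffles."""

    observed: float
    null_values: np.ndarray
    percentile: float  # percentile of the observed value within the null

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.null_values, q)


def _varexp(X: np.ndarray, groups: dict[str, np.ndarray], tot: float) -> float:
    _, _, axes = _group_axes(X, groups)
    if axes.shape[1] == 0:
        return 0.0
    scores = X @ axes  # centering constant does not change variances
    return float(np.var(scores, axis=0, ddof=1).sum() / tot)


def permutation_baseline(
    matrix: ChronospaceMatrix,
    factor: str,
    n_perm: int = 99,
    seed: int | None = 0,
) -> PermutationBaseline:
    """Calibrate bgPCA's chance-level separation for one factor.

    The total variance explained is recomputed under ``n_perm`` random
    permutations of the factor labels (level sizes preserved); the
    observed value's percentile within that null distribution indicates
    whether the factor separates chronograms beyond what bgPCA produces
    on arbitrary groupings.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = matrix.ages
    groups = _level_indices(matrix.metadata, factor)
    tot = total_variance(X)
    observed = _varexp(X, groups, tot)
    sizes = [len(idx) for idx in groups.values()]
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(X.shape[0])
        shuffled = {
            lv: perm[bounds[i] : bounds[i + 1]] for i, lv in enumerate(groups)
        }
        null[p] = _varexp(X, shuffled, tot)
    percentile = 100.0 * np.mean(null <= observed)
    return PermutationBaseline(observed=observed, null_values=null, percentile=percentile)
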