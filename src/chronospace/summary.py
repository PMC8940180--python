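"""Posterior node-age summaries: medians, HPD intervals, LTT curves.

The highest posterior density (HPD) interval is computed exactly on the
empirical sample — the shortest contiguous window over the sorted draws
containing at least the requested mass — with no kernel smoothing, which
is the convention of the standard phylogenetic summary tools.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trees import Chronogram, ChronogramSet, CladeKey, clade_label

__all__ = [
    "hpd_interval",
    "summarize_ages",
    "interval_probability",
    "ltt",
    "merge_samples",
]


def hpd_interval(values, mass: float = 0.95) -> tuple[float, float]:
    """Shortest window over sorted samples holding >= ``mass`` of them.

    The window holds ``ceil(mass * n)`` consecutive order statistics; a
    tie between equally short windows is broken in favor of the earliest
    (oldest-to-youngest) start.  For multimodal samples the interval need
    not contain the median.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    w = int(np.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + w - 1])


def _age_matrix(samples) -> tuple[np.ndarray, tuple[CladeKey, ...]]:
    if isinstance(samples, ChronogramSet):
        return samples.ages, samples.topology.keys
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    s = ChronogramSet.from_chronograms(samples)
    return s.ages, s.topology.keys


def summarize_ages(samples, mass: float = 0.95) -> pd.DataFrame:
    """Median and HPD interval of the posterior age of every node.

    Parameters
    ----------
    samples : ChronogramSet or sequence of Chronogram
        Posterior draws sharing one topology (>= 2 samples).
    mass : float
        Posterior mass of the HPD interval (default 0.95).

    Returns
    -------
    DataFrame with columns node, clade_size, median, hpd_low, hpd_high, n.
    """
    ages, keys = _age_matrix(samples)
    if ages.shape[0] < 2:
        raise ValueError("need >= 2 posterior samples")
    rows = []
    for j, k in enumerate(keys):
        col = ages[:, j]
        lo, hi = hpd_interval(col, mass)
        rows.append(
            {
                "node": clade_label(k),
                "clade_size": len(k),
                "median": float(np.median(col)),
                "hpd_low": lo,
                "hpd_high": hi,
                "n": len(col),
            }
        )
    return pd.DataFrame(rows)


def interval_probability(
    samples, node: Iterable[str], t_old: float, t_young: float
) -> float:
    """Fraction of posterior samples placing a node's age in
    ``[t_young, t_old]`` (bounds inclusive, Myr).

    This is the posterior probability that the divergence falls within a
    named geological interval.
    """
    if not t_old > t_young >= 0:
        raise ValueError("need t_old > t_young >= 0")
    ages, keys = _age_matrix(samples)
    key = frozenset(node)
    try:
        j = keys.index(key)
    except ValueError:
        raise KeyError(f"clade {clade_label(key)} absent from topology") from None
    col = ages[:, j]
    return float(np.mean((col >= t_young) & (col <= t_old)))


def ltt(chronogram: Chronogram) -> pd.DataFrame:
    """Lineage-through-time curve of a single chronogram.

    Returns steps (age, lineages) from the root age to the present: the
    count starts at 2 immediately after the root, rises at each distinct
    internal-node age (coincident ages merge into one step), and ends at
    the tip count at age 0.
    """
    topo = chronogram.topology
    ages = chronogram.ages
    distinct = np.unique(ages)[::-1]  # oldest first
    steps = []
    for a in distinct:
        at_or_above = ages >= a - 1e-12
        count = 1 + sum(
            topo.n_children(i) - 1 for i in np.flatnonzero(at_or_above)
        )
        steps.append((float(a), int(count)))
    if not steps or steps[-1][0] != 0.0:
        steps.append((0.0, topo.n_tips))
    return pd.DataFrame(steps, columns=["age", "lineages"])


def merge_samples(sets: Sequence[ChronogramSet], equalize: bool = True) -> ChronogramSet:
    """Merge posterior sets from different analysis settings.

    Merged posteriors weight each analysis equally: when set sizes are
    unequal and ``equalize`` is true, every set is down-sampled (evenly
    spaced, deterministic) to the smallest set size before concatenation.
    """
    if not sets:
        raise ValueError("no sets to merge")
    topo = sets[0].topology
    for s in sets[1:]:
        if s.topology != topo:
            raise ValueError("sets do not share a topology")
    sizes = [len(s) for s in sets]
    blocks = []
    for s in sets:
        A = s.ages
        if equalize and len(s) > min(sizes):
            idx = np.linspace(0, len(s) - 1, min(sizes)).round().astype(int)
            A = A[idx]
        blocks.append(A)
    return ChronogramSet(topo, np.vstack(blocks), {"merged_from": len(sets)})
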