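"""Gene-wise delta log-likelihood dissection between two topologies.

Given per-site log-likelihoods of the same alignment under two candidate
resolutions of a contentious node, the per-locus delta score is the sum
over the locus's sites of lnL(T1) - lnL(T2); positive values support T1.
Averaging deltas over datasets of growing size (loci added in order of
decreasing phylogenetic usefulness, in multiples of a fixed step) exposes
whether the signal for one resolution concentrates among the most useful
loci; a second-degree polynomial summarizes the trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteLikelihoodTable",
    "parse_site_lnl",
    "write_site_lnl",
    "read_partitions",
    "genewise_delta",
    "delta_trend",
]

DIALECTS = ("tsv", "iqtree_sitelh", "raxml_perSiteLLs")


@dataclass
class SiteLikelihoodTable:
    """Per-site natural-log likelihoods under two topologies, plus a
    partition map assigning sites to loci (stored half-open, 0-based;
    constructed from the 1-based inclusive convention of partition
    files)."""

    lnl_t1: np.ndarray
    lnl_t2: np.ndarray
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self):
        self.lnl_t1 = np.asarray(self.lnl_t1, dtype=float)
        self.lnl_t2 = np.asarray(self.lnl_t2, dtype=float)
        if self.lnl_t1.shape != self.lnl_t2.shape or self.lnl_t1.ndim != 1:
            raise ValueError("the two site-likelihood vectors must be equal-length")
        n = self.n_sites
        seen: list[tuple[int, int, str]] = []
        for locus, (a, b) in self.partitions.items():
            if not (0 <= a < b <= n):
                raise ValueError(f"partition {locus!r} out of range or empty")
            seen.append((a, b, locus))
        seen.sort()
        for (a1, b1, l1), (a2, b2, l2) in zip(seen, seen[1:]):
            if a2 < b1:
                raise ValueError(f"partitions {l1!r} and {l2!r} overlap")

    @property
    def n_sites(self) -> int:
        return len(self.lnl_t1)

    def swap(self) -> "SiteLikelihoodTable":
        """The same table with the two topologies exchanged."""
        return SiteLikelihoodTable(
            self.lnl_t2.copy(), self.lnl_t1.copy(), dict(self.partitions)
        )


def read_partitions(path) -> dict[str, tuple[int, int]]:
    """Partition TSV (locus, start, end; 1-based inclusive) -> half-open
    0-based ranges."""
    df = pd.read_csv(path, sep="\t")
    need = {"locus", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"partition table needs columns {sorted(need)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["locus"])] = (int(row["start"]) - 1, int(row["end"]))
    return out


def _parse_matrix_dialect(path) -> tuple[np.ndarray, np.ndarray]:
    """Shared reader for the RAxML perSiteLLs / IQ-TREE .sitelh layout:
    a header line with tree and site counts, then one labeled row of
    site log-likelihoods per tree."""
    rows = []
    with open(path) as fh:
        header = fh.readline().split()
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            try:
                values = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise ValueError(f"non-numeric site likelihood in {path}") from exc
            rows.append(np.asarray(values))
    if len(header) >= 2:
        try:
            n_sites = int(header[1])
        except ValueError:
            n_sites = None
        if n_sites is not None:
            for r in rows:
                if len(r) != n_sites:
                    raise ValueError(
                        f"{path}: row length {len(r)} != declared {n_sites} sites"
                    )
    if len(rows) < 2:
        raise ValueError(f"{path}: need site likelihoods for two topologies")
    if len(rows[0]) != len(rows[1]):
        raise ValueError(f"{path}: topology rows have different site counts")
    return rows[0], rows[1]


def parse_site_lnl(
    path,
    dialect: str = "tsv",
    partitions: Mapping[str, tuple[int, int]] | None = None,
    partition_path=None,
) -> SiteLikelihoodTable:
    """Read per-site log-likelihoods under two topologies.

    Dialects: ``tsv`` (columns site, lnl_t1, lnl_t2), ``iqtree_sitelh``
    and ``raxml_perSiteLLs`` (header with counts, then one labeled row
    per tree).  Partitions can be passed directly (half-open 0-based) or
    read from a 1-based inclusive TSV via ``partition_path``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        need = {"site", "lnl_t1", "lnl_t2"}
        if not need <= set(df.columns):
            raise ValueError(f"TSV dialect needs columns {sorted(need)}")
        if df[["lnl_t1", "lnl_t2"]].isna().any().any():
            raise ValueError(f"{path}: non-numeric or missing likelihood values")
        t1 = df["lnl_t1"].to_numpy(float)
        t2 = df["lnl_t2"].to_numpy(float)
    else:
        t1, t2 = _parse_matrix_dialect(path)
    if partitions is None:
        if partition_path is not None:
            partitions = read_partitions(partition_path)
        else:
            partitions = {"all": (0, len(t1))}
    return SiteLikelihoodTable(t1, t2, dict(partitions))


def write_site_lnl(table: SiteLikelihoodTable, path) -> None:
    """Write the TSV dialect (full float precision; round-trips exactly
    to the printed digits)."""
    df = pd.DataFrame(
        {
            "site": np.arange(1, table.n_sites + 1),
            "lnl_t1": table.lnl_t1,
            "lnl_t2": table.lnl_t2,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def genewise_delta(table: SiteLikelihoodTable) -> pd.Series:
    """Per-locus delta: sum over the locus's sites of lnL_T1 - lnL_T2.

    Positive values support topology T1.  Summing over all loci of a
    full partition recovers the total log-likelihood difference.
    """
    diff = table.lnl_t1 - table.lnl_t2
    out = {}
    for locus, (a, b) in table.partitions.items():
        out[locus] = float(diff[a:b].sum())
    return pd.Series(out, name="delta").sort_index()


def delta_trend(
    deltas: Mapping[str, float] | pd.Series,
    order: Sequence[str],
    step: int = 20,
    mode: str = "cumulative",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean per-locus delta for datasets of growing size, plus a
    quadratic fit.

    ``order`` ranks loci (most useful first).  For k = step, 2*step, ...
    the mean delta is taken over the top-k loci (``mode="cumulative"``)
    or over the k-th block of ``step`` loci (``mode="blocks"``).  Returns
    the (k, mean_delta) table and the least-squares second-degree
    polynomial coefficients (highest degree first, numpy convention).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if mode not in ("cumulative", "blocks"):
        raise ValueError("mode must be 'cumulative' or 'blocks'")
    order = list(order)
    if not order:
        raise ValueError("empty locus order")
    d = pd.Series(deltas)
    missing = [l for l in order if l not in d.index]
    if missing:
        raise KeyError(f"loci without delta values: {missing[:5]}")
    values = d[order].to_numpy(float)
    ks, means = [], []
    for k in range(step, len(order) + 1, step):
        ks.append(k)
        if mode == "cumulative":
            means.append(values[:k].mean())
        else:
            means.append(values[k - step : k].mean())
    table = pd.DataFrame({"k": ks, "mean_delta": means})
    deg = min(2, len(ks) - 1)
    if deg < 0:
        raise ValueError(f"no complete bin of {step} loci")
    coeffs = np.polyfit(table["k"], table["mean_delta"], deg)
    coeffs = np.concatenate([np.zeros(3 - len(coeffs)), coeffs])
    return table, coeffs
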