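"""Chronogram I/O and the samples-by-nodes age matrix.

A chronogram is a rooted, ultrametric tree whose branch lengths are in
units of absolute time (Myr before present, tips extant at age 0).  Every
internal node is identified by its *clade key*: the frozen set of tip
labels descending from it, which matches nodes across tree samples that
share a topology.  Posterior samples from a Bayesian dating run are read,
burned-in, thinned and capped here, and stacked into a
:class:`ChronospaceMatrix` — one row per sampled chronogram, one column
per internal node, each cell a node age in Myr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CladeKey",
    "Topology",
    "Chronogram",
    "ChronogramSet",
    "ChronospaceMatrix",
    "parse_chronograms",
    "align_sets",
    "read_set_metadata",
    "load_sets",
    "clade_label",
    "clade_sort_key",
]

#: A clade key: the unordered set of tip labels below one internal node.
CladeKey = frozenset


def clade_sort_key(key: CladeKey) -> tuple:
    """Canonical ordering: clade size, then lexicographic tip list."""
    return (len(key), tuple(sorted(key)))


def clade_label(key: CladeKey) -> str:
    """Stable text label for a clade key (pipe-joined sorted tips)."""
    return "|".join(sorted(key))


class TopologyMismatchError(ValueError):
    """Raised when tree samples do not share an identical topology."""


class UltrametricityError(ValueError):
    """Raised when a tree's root-to-tip paths deviate beyond tolerance."""


class Topology:
    """A fixed rooted topology over a set of extant tips.

    Internal nodes are stored in canonical order (ascending clade size,
    ties broken by the sorted tip list), so the root is always last.
    Node ages of any chronogram on this topology align to ``self.keys``.
    """

    def __init__(
        self,
        tip_labels: Sequence[str],
        keys: Sequence[CladeKey],
        parent: Sequence[int],
        child_nodes: Sequence[Sequence[int]],
        child_tips: Sequence[Sequence[str]],
    ):
        self.tip_labels: tuple[str, ...] = tuple(sorted(tip_labels))
        self.keys: tuple[CladeKey, ...] = tuple(keys)
        self.parent = np.asarray(parent, dtype=int)
        self.child_nodes = [list(c) for c in child_nodes]
        self.child_tips = [list(c) for c in child_tips]
        self.key_index: dict[CladeKey, int] = {k: i for i, k in enumerate(self.keys)}
        self.root_index: int = len(self.keys) - 1
        self._validate()

    def _validate(self) -> None:
        if not self.keys:
            raise ValueError("topology has no internal nodes")
        if self.keys[self.root_index] != frozenset(self.tip_labels):
            raise ValueError("last canonical key must be the root (full tip set)")
        for i, k in enumerate(self.keys):
            n_below = len(self.child_tips[i]) + sum(
                len(self.keys[c]) for c in self.child_nodes[i]
            )
            if n_below != len(k):
                raise ValueError(f"inconsistent children for clade {clade_label(k)}")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_internal(self) -> int:
        return len(self.keys)

    def n_children(self, i: int) -> int:
        return len(self.child_nodes[i]) + len(self.child_tips[i])

    def preorder(self) -> Iterable[int]:
        """Indices root-to-tip (parents before children)."""
        return reversed(range(self.n_internal))

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Topology":
        leaf_sets: dict[int, frozenset] = {}
        records = []  # (key, child keys, child tip labels)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                leaf_sets[id(node)] = frozenset([node.taxon.label])
                continue
            ck, ct = [], []
            tips: set[str] = set()
            for ch in node.child_nodes():
                s = leaf_sets[id(ch)]
                tips |= s
                if len(s) == 1 and ch.is_leaf():
                    ct.append(next(iter(s)))
                else:
                    ck.append(s)
            key = frozenset(tips)
            leaf_sets[id(node)] = key
            records.append((key, ck, ct))
        keys = sorted((r[0] for r in records), key=clade_sort_key)
        index = {k: i for i, k in enumerate(keys)}
        parent = [-1] * len(keys)
        child_nodes: list[list[int]] = [[] for _ in keys]
        child_tips: list[list[str]] = [[] for _ in keys]
        for key, ck, ct in records:
            i = index[key]
            child_tips[i] = sorted(ct)
            for s in ck:
                j = index[s]
                parent[j] = i
                child_nodes[i].append(j)
            child_nodes[i].sort()
        tips = keys[-1] if keys else frozenset()
        return cls(sorted(tips), keys, parent, child_nodes, child_tips)

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.keys == other.keys

    def __hash__(self) -> int:
        return hash(self.keys)

    def __repr__(self) -> str:
        return f"Topology({self.n_tips} tips, {self.n_internal} internal nodes)"


@dataclass
class Chronogram:
    """A single time-calibrated tree: a topology plus internal-node ages.

    ``ages[i]`` is the age (Myr) of ``topology.keys[i]``; tips are
    implicitly at age 0 and the root age is the maximum entry.
    """

    topology: Topology
    ages: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if self.ages.shape != (self.topology.n_internal,):
            raise ValueError("ages must align with the topology's internal nodes")

    @property
    def root_age(self) -> float:
        return float(self.ages[self.topology.root_index])

    @property
    def node_ages(self) -> dict[CladeKey, float]:
        return {k: float(a) for k, a in zip(self.topology.keys, self.ages)}

    def age_of(self, clade: Iterable[str]) -> float:
        return float(self.ages[self.topology.key_index[frozenset(clade)]])

    def validate(self, atol: float = 1e-9) -> None:
        """Assert parent >= child ages and non-negative ages."""
        topo = self.topology
        if np.any(self.ages < -atol):
            raise ValueError("negative node age")
        for i in range(topo.n_internal):
            p = topo.parent[i]
            if p >= 0 and self.ages[i] > self.ages[p] + atol:
                raise ValueError(
                    f"clade {clade_label(topo.keys[i])} older than its parent"
                )
        if abs(self.root_age - self.ages.max()) > atol:
            raise ValueError("root age is not the maximum node age")

    def to_newick(self, precision: int = 12) -> str:
        """Newick string with branch lengths parent_age - child_age."""
        topo = self.topology

        def render(i: int) -> str:
            parts = [
                f"{t}:{self.ages[i]:.{precision}f}" for t in topo.child_tips[i]
            ] + [
                f"{render(j)}:{self.ages[i] - self.ages[j]:.{precision}f}"
                for j in topo.child_nodes[i]
            ]
            return "(" + ",".join(parts) + ")"

        return render(topo.root_index) + ";"


class ChronogramSet:
    """An ordered collection of chronograms from one dating analysis.

    All samples share the topology; ages are stored as an
    (n_samples, n_internal) matrix.  ``metadata`` carries the factor
    levels of the analysis that produced the set (clock model,
    substitution model, node-age prior, loci sampling scheme, run id).
    """

    def __init__(
        self,
        topology: Topology,
        ages: np.ndarray,
        metadata: Mapping[str, object] | None = None,
    ):
        self.topology = topology
        self.ages = np.atleast_2d(np.asarray(ages, dtype=float))
        if self.ages.shape[1] != topology.n_internal:
            raise ValueError("age matrix does not match topology")
        self.metadata: dict[str, object] = dict(metadata or {})

    @classmethod
    def from_chronograms(
        cls, chronograms: Sequence[Chronogram], metadata=None
    ) -> "ChronogramSet":
        if not chronograms:
            raise ValueError("empty chronogram list")
        topo = chronograms[0].topology
        for i, c in enumerate(chronograms[1:], start=1):
            if c.topology != topo:
                diff = set(c.topology.keys) ^ set(topo.keys)
                raise TopologyMismatchError(
                    f"tree {i} topology differs; conflicting clades: "
                    + ", ".join(sorted(clade_label(k) for k in diff))
                )
        return cls(topo, np.vstack([c.ages for c in chronograms]), metadata)

    def __len__(self) -> int:
        return self.ages.shape[0]

    def __getitem__(self, i: int) -> Chronogram:
        return Chronogram(self.topology, self.ages[i].copy())

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


@dataclass
class ChronospaceMatrix:
    """Samples-by-nodes age matrix with per-sample factor metadata.

    Rows are individual posterior chronograms; columns are internal nodes
    in canonical clade order; cells are node ages in Myr.  ``metadata``
    has one row per sample with the factor levels of the analysis the
    sample came from.
    """

    ages: np.ndarray
    node_keys: tuple[CladeKey, ...]
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.node_keys = tuple(self.node_keys)
        if self.ages.ndim != 2 or self.ages.shape[1] != len(self.node_keys):
            raise ValueError("age matrix / node key mismatch")
        if len(self.metadata) != self.ages.shape[0]:
            raise ValueError("metadata rows must match age matrix rows")
        if np.isnan(self.ages).any():
            raise ValueError("age matrix contains missing cells")

    @property
    def n_samples(self) -> int:
        return self.ages.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.ages.shape[1]

    @property
    def node_labels(self) -> list[str]:
        return [clade_label(k) for k in self.node_keys]

    def factors(
        self, exclude: Sequence[str] = ("set_id", "run_id", "sample", "seed")
    ) -> list[str]:
        """Metadata columns usable as grouping factors."""
        return [c for c in self.metadata.columns if c not in exclude]

    def to_frame(self) -> pd.DataFrame:
        ages = pd.DataFrame(self.ages, columns=self.node_labels)
        return pd.concat(
            [self.metadata.reset_index(drop=True), ages], axis=1
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ChronospaceMatrix":
        df = pd.read_csv(path, sep="\t")
        node_cols = [c for c in df.columns if "|" in c]
        keys = tuple(frozenset(c.split("|")) for c in node_cols)
        meta = df[[c for c in df.columns if c not in node_cols]]
        return cls(df[node_cols].to_numpy(float), keys, meta)


def _node_ages_from_dendropy(
    tree: dendropy.Tree,
    topology: Topology | None,
    tolerance: float,
    strict: bool,
    index: int,
) -> tuple[Topology, np.ndarray]:
    """Extract per-clade ages; the age of a node is the mean root-to-tip
    distance below it, which absorbs small rounding drift in published
    chronograms."""
    tree.encode_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=False)
    # bottom-up accumulation of (sum of tip depths below, tip count)
    stats: dict[int, tuple[float, int]] = {}
    ages: dict[CladeKey, float] = {}
    leafsets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (0.0, 1)
            leafsets[id(node)] = frozenset([node.taxon.label])
            continue
        s, n = 0.0, 0
        tips: set[str] = set()
        for ch in node.child_nodes():
            cs, cn = stats[id(ch)]
            bl = ch.edge.length if ch.edge.length is not None else 0.0
            s += cs + cn * bl
            n += cn
            tips |= leafsets[id(ch)]
        stats[id(node)] = (s, n)
        leafsets[id(node)] = frozenset(tips)
        ages[frozenset(tips)] = s / n

    root_key = leafsets[id(tree.seed_node)]
    root_age = ages[root_key]
    # root-to-tip deviation check
    depths = []
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length if node.edge.length is not None else 0.0
            depth[id(node)] = depth[id(node.parent_node)] + bl
        if node.is_leaf():
            depths.append(depth[id(node)])
    depths = np.asarray(depths)
    dev = float(np.max(np.abs(depths - depths.mean()))) if len(depths) else 0.0
    if root_age > 0 and dev > tolerance * root_age:
        msg = (
            f"tree {index}: root-to-tip paths deviate by {dev:.6g} Myr "
            f"(> {tolerance:g} x root age {root_age:.6g})"
        )
        if strict:
            raise UltrametricityError(msg)
        warnings.warn(msg, stacklevel=3)

    if topology is None:
        topology = Topology.from_dendropy(tree)
    keyset = frozenset(ages)
    if keyset != frozenset(topology.keys):
        diff = keyset ^ frozenset(topology.keys)
        raise TopologyMismatchError(
            f"tree {index} topology differs; conflicting clades: "
            + ", ".join(sorted(clade_label(k) for k in diff))
        )
    vec = np.array([ages[k] for k in topology.keys])
    return topology, vec


def burnin_thin_indices(n_trees: int, burnin_fraction: float, thin: int) -> list[int]:
    """Indices surviving burn-in (leading fraction dropped) and thinning."""
    if not 0 <= burnin_fraction < 1:
        raise ValueError("burnin_fraction must be in [0, 1)")
    if thin < 1:
        raise ValueError("thin must be a positive integer")
    start = int(burnin_fraction * n_trees)
    return list(range(start, n_trees, thin))


def parse_chronograms(
    path,
    format: str = "newick",
    burnin_fraction: float = 0.25,
    thin: int = 2,
    per_run_cap: int | None = 200,
    tolerance: float = 1e-4,
    strict: bool = True,
    seed: int | None = 0,
    topology: Topology | None = None,
) -> list[Chronogram]:
    """Read posterior chronogram samples from a Newick or NEXUS file.

    The leading ``burnin_fraction`` of trees is discarded and the rest
    thinned to every ``thin``-th sample; if more than ``per_run_cap``
    survive, a uniform random subsample (seeded) is kept.  Node ages are
    mean root-to-tip distances below each node; a tree whose root-to-tip
    paths deviate by more than ``tolerance`` times its root age raises
    :class:`UltrametricityError` (``strict=False`` downgrades to a
    warning).

    Parameters
    ----------
    path : str or Path
        Tree file containing one or more trees.
    format : {"newick", "nexus"}
    seed : int, optional
        Seed for the capping subsample; recorded so runs reproduce.
    topology : Topology, optional
        Expected topology; inferred from the first tree when omitted.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    trees = dendropy.TreeList.get(path=str(path), schema=format)
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    tipsets = {frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees}
    if len(tipsets) > 1:
        raise ValueError(f"trees in {path} do not share one tip set")

    keep = burnin_thin_indices(len(trees), burnin_fraction, thin)
    if per_run_cap is not None and len(keep) > per_run_cap:
        rng = np.random.default_rng(seed)
        pos = sorted(rng.choice(len(keep), size=per_run_cap, replace=False).tolist())
        keep = [keep[i] for i in pos]

    out: list[Chronogram] = []
    for i in keep:
        try:
            topology, ages = _node_ages_from_dendropy(
                trees[i], topology, tolerance, strict, index=i
            )
        except UltrametricityError:
            raise
        out.append(Chronogram(topology, ages))
    return out


def align_sets(
    sets: Sequence[ChronogramSet],
    restrict_to: Iterable[CladeKey] | None = None,
) -> ChronospaceMatrix:
    """Stack chronogram sets into one samples-by-nodes age matrix.

    All sets must share an identical topology; ``restrict_to`` keeps only
    the named clades as columns (e.g. to drop outgroup nodes).
    """
    if len(sets) < 1:
        raise ValueError("need at least one chronogram set")
    topo = sets[0].topology
    for s in sets[1:]:
        if s.topology != topo:
            diff = set(s.topology.keys) ^ set(topo.keys)
            raise TopologyMismatchError(
                "sets do not share a topology; conflicting clades: "
                + ", ".join(sorted(clade_label(k) for k in diff))
            )
    cols = list(range(topo.n_internal))
    keys = topo.keys
    if restrict_to is not None:
        wanted = {frozenset(k) for k in restrict_to}
        missing = wanted - set(topo.keys)
        if missing:
            raise KeyError(
                "clades not on topology: "
                + ", ".join(sorted(clade_label(k) for k in missing))
            )
        cols = [i for i, k in enumerate(topo.keys) if k in wanted]
        keys = tuple(topo.keys[i] for i in cols)

    blocks, meta_rows = [], []
    for s in sets:
        blocks.append(s.ages[:, cols])
        for j in range(len(s)):
            meta_rows.append({**s.metadata, "sample": j})
    meta = pd.DataFrame(meta_rows)
    return ChronospaceMatrix(np.vstack(blocks), keys, meta)


def write_chronogram_set(chronogram_set: ChronogramSet, path) -> None:
    """Write a set as a plain Newick file, one tree per line."""
    with open(path, "w") as fh:
        for c in chronogram_set:
            fh.write(c.to_newick() + "\n")


REQUIRED_METADATA_COLUMNS = (
    "set_id",
    "path",
    "clock",
    "subst_model",
    "prior",
    "loci_scheme",
    "run_id",
)


def read_set_metadata(path) -> pd.DataFrame:
    """Read the analysis metadata table (TSV, one row per tree file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(REQUIRED_METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def load_sets(metadata_path, **parse_kwargs) -> list[ChronogramSet]:
    """Load every chronogram set listed in a metadata TSV.

    Tree file paths are resolved relative to the metadata file; parse
    keyword arguments are forwarded to :func:`parse_chronograms`.
    """
    meta = read_set_metadata(metadata_path)
    base = Path(metadata_path).parent
    forced_format = parse_kwargs.pop("format", None)
    sets: list[ChronogramSet] = []
    topo: Topology | None = None
    for _, row in meta.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        fmt = forced_format or (
            "nexus" if p.suffix.lower() in (".nex", ".nexus", ".trees") else "newick"
        )
        chrono = parse_chronograms(p, format=fmt, topology=topo, **parse_kwargs)
        topo = chrono[0].topology
        md = {k: row[k] for k in meta.columns if k != "path"}
        sets.append(ChronogramSet.from_chronograms(chrono, md))
    return sets
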