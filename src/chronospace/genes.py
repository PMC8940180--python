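"""Per-locus properties and phylogenomic subsampling schemes.

Seven properties commonly used to rank loci are computed per gene:
proxies for phylogenetic signal (mean bootstrap support, Robinson-Foulds
similarity to a reference species tree) and for systematic bias
(evolutionary rate, root-to-tip variance, saturation, compositional
heterogeneity), plus matrix occupancy.  A PCA of the standardized table
locates the "usefulness" axis — the strongest component along which
signal rises while bias falls — and loci can be selected by usefulness,
signal, clock-likeness (with a rate filter), occupancy, or at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "PROPERTY_COLUMNS",
    "SIGNAL_COLUMNS",
    "BIAS_COLUMNS",
    "read_alignment",
    "write_alignment",
    "compute_gene_properties",
    "UsefulnessAxis",
    "usefulness_axis",
    "select_loci",
    "filter_loci_by_clade_presence",
    "write_supermatrix",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: default property set; configurable per call
PROPERTY_COLUMNS = (
    "mean_bootstrap",
    "rf_similarity",
    "rate",
    "rtt_variance",
    "saturation_slope",
    "rcfv",
    "occupancy",
)
SIGNAL_COLUMNS = ("mean_bootstrap", "rf_similarity")
BIAS_COLUMNS = ("rate", "rtt_variance", "rcfv")


def read_alignment(path) -> dict[str, str]:
    """Read an amino-acid FASTA alignment as {taxon: sequence}."""
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not aln:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: sequences have unequal lengths {sorted(lengths)}")
    return aln


def write_alignment(alignment: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in alignment:
            fh.write(f">{name}\n{alignment[name]}\n")


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree.clone(depth=1)
    text = str(tree)
    if "(" not in text and Path(text).exists():
        return dendropy.Tree.get(path=text, schema="newick")
    return dendropy.Tree.get(data=text, schema="newick")


def _tip_labels(tree: dendropy.Tree) -> set[str]:
    return {l.taxon.label for l in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree, taxa: set[str]) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of ``tree`` restricted to ``taxa``.

    Each bipartition is canonicalized as the side not containing the
    lexicographically smallest taxon, so rooted representations of the
    same unrooted tree compare equal.  Polytomies simply contribute fewer
    bipartitions.
    """
    anchor = min(taxa)
    out: set[frozenset] = set()
    below: dict[int, set[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[id(node)] = {lab} if lab in taxa else set()
            continue
        s: set[str] = set()
        for ch in node.child_nodes():
            s |= below[id(ch)]
        below[id(node)] = s
        if node.parent_node is None:
            continue
        side = frozenset(s if anchor not in s else taxa - s)
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(side)
    return out


def rf_similarity(tree_a, tree_b) -> float:
    """1 - |A xor B| / (|A| + |B|) over the two bipartition sets, computed
    on the shared taxa.  Equal to 1 for identical unrooted topologies;
    symmetric in its arguments."""
    ta, tb = _as_tree(tree_a), _as_tree(tree_b)
    shared = _tip_labels(ta) & _tip_labels(tb)
    if len(shared) < 4:
        return 1.0
    ta.retain_taxa_with_labels(sorted(shared))
    tb.retain_taxa_with_labels(sorted(shared))
    A, B = bipartitions(ta, shared), bipartitions(tb, shared)
    denom = len(A) + len(B)
    if denom == 0:
        return 1.0
    return 1.0 - len(A ^ B) / denom


def _mean_bootstrap(tree: dendropy.Tree) -> float:
    vals = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        lab = node.label
        if lab is None:
            continue
        try:
            vals.append(float(lab))
        except ValueError:
            continue
    return float(np.mean(vals)) if vals else float("nan")


def _root_to_tip_variance(tree: dendropy.Tree) -> float:
    t = tree.clone(depth=1)
    t.encode_bipartitions()
    try:
        t.reroot_at_midpoint(update_bipartitions=False)
    except (AssertionError, ValueError):  # zero-length degenerate trees
        pass
    depths = [l.distance_from_root() for l in t.leaf_node_iter()]
    return float(np.var(depths, ddof=1)) if len(depths) > 1 else 0.0


def _p_distance(a: str, b: str) -> float:
    num = den = 0
    for x, y in zip(a, b):
        if x in AMINO_ACIDS and y in AMINO_ACIDS:
            den += 1
            num += x != y
    return num / den if den else float("nan")


def _saturation_slope(alignment: Mapping[str, str], tree: dendropy.Tree) -> float:
    """Zero-intercept regression slope of uncorrected p-distances on
    patristic distances over all taxon pairs; slopes well below 1
    indicate saturation (multiple hits erased by the observed distance)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (t for t in tree.taxon_namespace if t.label in alignment),
        key=lambda t: t.label,
    )
    xs, ys = [], []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            x = pdm.patristic_distance(taxa[i], taxa[j])
            y = _p_distance(alignment[taxa[i].label], alignment[taxa[j].label])
            if np.isfinite(y) and x > 0:
                xs.append(x)
                ys.append(y)
    if not xs:
        return float("nan")
    x = np.asarray(xs)
    y = np.asarray(ys)
    return float((x * y).sum() / (x * x).sum())


def rcfv(alignment: Mapping[str, str]) -> float:
    """Relative composition frequency variability: the summed absolute
    deviation of per-taxon state frequencies from the mean frequency,
    divided by the number of taxa.  Zero for perfectly homogeneous
    composition; grows with compositional heterogeneity."""
    taxa = sorted(alignment)
    states = sorted(AMINO_ACIDS)
    freqs = np.zeros((len(taxa), len(states)))
    for i, t in enumerate(taxa):
        counts = np.array([alignment[t].count(s) for s in states], dtype=float)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"all-gap sequence for taxon {t}")
        freqs[i] = counts / total
    mean = freqs.mean(axis=0)
    return float(np.abs(freqs - mean).sum() / len(taxa))


def compute_gene_properties(
    alignments: Mapping[str, Mapping[str, str]],
    gene_trees: Mapping[str, object],
    reference_tree,
    drop_taxa: Iterable[str] | None = None,
    min_taxa: int = 4,
) -> pd.DataFrame:
    """Per-locus property table for phylogenomic subsampling.

    Parameters
    ----------
    alignments : {locus: {taxon: aa sequence}}
    gene_trees : {locus: newick string / path / dendropy.Tree} with
        bootstrap supports as internal node labels.
    reference_tree : the species tree the RF similarity is measured to
        (a contentious node may be collapsed into a polytomy; bipartition
        sets handle polytomies natively).
    drop_taxa : labels (e.g. outgroups) pruned from every tree and
        alignment before any metric is computed.

    Loci retaining fewer than ``min_taxa`` taxa are skipped with a
    warning.  Columns: mean_bootstrap, rf_similarity, rate (tree length /
    terminals), rtt_variance (midpoint-rooted), saturation_slope, rcfv,
    occupancy (fraction of reference terminals with data).
    """
    drop = set(drop_taxa or ())
    ref = _as_tree(reference_tree)
    if drop:
        keep = sorted(_tip_labels(ref) - drop)
        ref.retain_taxa_with_labels(keep)
    ref_taxa = _tip_labels(ref)
    rows = {}
    for locus in sorted(alignments):
        aln_full = alignments[locus]
        aln = {
            t: s
            for t, s in aln_full.items()
            if t not in drop and any(c in AMINO_ACIDS for c in s)
        }
        gt = _as_tree(gene_trees[locus])
        keep = sorted(_tip_labels(gt) & set(aln))
        if len(keep) < min_taxa:
            warnings.warn(f"{locus}: fewer than {min_taxa} usable taxa; skipped")
            continue
        if len(keep) < len(_tip_labels(gt)):
            gt.retain_taxa_with_labels(keep)
        aln = {t: aln[t] for t in keep}
        lengths = [e.length or 0.0 for e in gt.preorder_edge_iter() if e.tail_node]
        rows[locus] = {
            "mean_bootstrap": _mean_bootstrap(gt),
            "rf_similarity": rf_similarity(gt, ref),
            "rate": float(sum(lengths)) / len(keep),
            "rtt_variance": _root_to_tip_variance(gt),
            "saturation_slope": _saturation_slope(aln, gt),
            "rcfv": rcfv(aln),
            "occupancy": len(set(keep) & ref_taxa) / len(ref_taxa),
        }
    if not rows:
        raise ValueError("no locus retained enough taxa")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "locus"
    return table


@dataclass
class UsefulnessAxis:
    """The PCA axis along which signal rises while bias falls."""

    index: int  # 0-based index among variance-ordered components
    orientation: float  # +1/-1 applied to the raw eigenvector
    loadings: pd.Series
    variance_share: float
    scores: pd.Series  # per-locus usefulness, higher = more useful

    @property
    def component(self) -> str:
        return f"PC{self.index + 1}"


def usefulness_axis(
    table: pd.DataFrame,
    columns: Sequence[str] = PROPERTY_COLUMNS,
    signal_columns: Sequence[str] = SIGNAL_COLUMNS,
    bias_columns: Sequence[str] = BIAS_COLUMNS,
) -> UsefulnessAxis:
    """Locate the usefulness axis of the gene-property table.

    The property columns are z-standardized and a PCA is run on their
    correlation matrix.  Among the components, the highest-variance one
    on which all signal loadings share a sign opposite to all bias
    loadings is selected and oriented so usefulness increases positively.

    Raises
    ------
    ValueError
        If fewer than 8 complete loci are available, or no component
        shows the signal-vs-bias contrast (override the axis manually in
        that case).
    """
    data = table[list(columns)].dropna()
    if len(data) < 8:
        raise ValueError("need >= 8 loci with complete properties")
    X = data.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [c for c, s in zip(columns, sd) if s == 0]
        raise ValueError(f"constant property column(s): {const}")
    Z = (X - mu) / sd
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    sig_idx = [list(columns).index(c) for c in signal_columns]
    bias_idx = [list(columns).index(c) for c in bias_columns]
    for i in range(len(vals)):
        v = vecs[:, i]
        s_sign = np.sign(v[sig_idx])
        b_sign = np.sign(v[bias_idx])
        if np.all(s_sign != 0) and len(set(s_sign)) == 1 and np.all(
            b_sign == -s_sign[0]
        ):
            orient = float(s_sign[0])
            axis = v * orient
            scores = pd.Series(Z @ axis, index=data.index, name="usefulness")
            return UsefulnessAxis(
                index=i,
                orientation=orient,
                loadings=pd.Series(axis, index=list(columns)),
                variance_share=float(vals[i] / vals.sum()),
                scores=scores,
            )
    raise ValueError(
        "no PCA component contrasts signal against bias; inspect the "
        "loadings and select an axis manually"
    )


SCHEMES = ("usefulness", "signal", "clocklike", "occupancy", "random")


def select_loci(
    table: pd.DataFrame,
    scheme: str,
    n: int,
    seed: int | None = 0,
    usefulness_scores: pd.Series | None = None,
    rate_filter_sd: float | None = 1.0,
) -> list[str]:
    """Select ``n`` loci under one of the five sampling schemes.

    usefulness: top usefulness-axis scores; signal: highest RF similarity
    to the species tree; occupancy: highest occupancy; random: seeded
    uniform draw; clocklike: among loci whose rate lies within
    ``rate_filter_sd`` sample standard deviations of the mean rate (the
    filter avoids selecting uninformative ultra-conserved genes), the
    smallest root-to-tip variances.  ``rate_filter_sd=None`` disables the
    filter, reducing clocklike to a plain minimum-variance ranking.  All
    ties break on locus id, so selections are deterministic.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    ids = list(table.index)
    if n > len(ids):
        raise ValueError(f"requested {n} loci but only {len(ids)} available")
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return [ids[i] for i in rng.choice(len(ids), size=n, replace=False)]
    if scheme == "usefulness":
        scores = usefulness_scores
        if scores is None:
            scores = usefulness_axis(table).scores
        ranked = sorted(scores.index, key=lambda l: (-scores[l], l))
        return list(ranked[:n])
    if scheme == "signal":
        col = table["rf_similarity"]
        return sorted(ids, key=lambda l: (-col[l], l))[:n]
    if scheme == "occupancy":
        col = table["occupancy"]
        return sorted(ids, key=lambda l: (-col[l], l))[:n]
    # clocklike
    rates = table["rate"]
    if rate_filter_sd is not None:
        mean, sd = rates.mean(), rates.std(ddof=1)
        candidates = [l for l in ids if abs(rates[l] - mean) <= rate_filter_sd * sd]
    else:
        candidates = ids
    if len(candidates) < n:
        raise ValueError(
            f"rate filter leaves {len(candidates)} loci, fewer than n={n}"
        )
    rtt = table["rtt_variance"]
    return sorted(candidates, key=lambda l: (rtt[l], l))[:n]


def filter_loci_by_clade_presence(
    alignments: Mapping[str, Mapping[str, str]],
    required_clades: Sequence[Iterable[str]],
) -> list[str]:
    """Keep loci in which every required clade has at least one terminal
    with non-gap data (e.g. to ensure occupancy around a contentious
    node)."""
    if not required_clades:
        raise ValueError("required_clades must be non-empty")
    clades = [set(c) for c in required_clades]
    out = []
    for locus in sorted(alignments):
        aln = alignments[locus]
        present = {
            t for t, s in aln.items() if any(ch in AMINO_ACIDS for ch in s)
        }
        if all(present & clade for clade in clades):
            out.append(locus)
    return out


def write_supermatrix(
    alignments: Mapping[str, Mapping[str, str]],
    loci: Sequence[str],
    fasta_path,
    partition_path=None,
) -> None:
    """Concatenate selected loci into a supermatrix FASTA (missing taxa
    padded with gaps) and optionally write a 1-based inclusive partition
    table."""
    taxa = sorted({t for l in loci for t in alignments[l]})
    parts = []
    start = 1
    seqs = {t: [] for t in taxa}
    for locus in loci:
        aln = alignments[locus]
        length = len(next(iter(aln.values())))
        for t in taxa:
            seqs[t].append(aln.get(t, "-" * length))
        parts.append((locus, start, start + length - 1))
        start += length
    write_alignment({t: "".join(seqs[t]) for t in taxa}, fasta_path)
    if partition_path is not None:
        pd.DataFrame(parts, columns=["locus", "start", "end"]).to_csv(
            partition_path, sep="\t", index=False
        )
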