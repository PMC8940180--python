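"""Synthetic data with the statistical structure the analyses assume.

Generates (i) pure-birth ultrametric trees, (ii) posterior-like sets of
chronograms around a true tree, with factor-specific age shifts injected
on chosen clades, (iii) full factorial analysis designs, and (iv)
synthetic amino-acid loci with gene trees of controlled discordance.

Posterior jitter uses a Beta parameterization: each internal node's age
is drawn as a Beta fraction of its (already drawn) parent's age, with
the Beta mean at the node's true relative position.  Samples therefore
satisfy parent >= child and ultrametricity by construction — no
rejection sampling, which would bias ages near constraints.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trees import (
    Chronogram,
    ChronogramSet,
    ChronospaceMatrix,
    CladeKey,
    Topology,
    align_sets,
    clade_label,
    clade_sort_key,
)

__all__ = [
    "SimulationConfig",
    "FactorEffect",
    "simulate_tree",
    "simulate_posterior_set",
    "enumerate_design",
    "default_clock_effect",
    "simulate_chronospace",
    "simulate_loci",
    "DEFAULT_FACTORS",
    "AMINO_ACIDS",
]

#: the factorial design of a typical dating sensitivity study:
#: 5 loci schemes x 2 substitution models x 2 clocks x 2 priors = 40 settings
DEFAULT_FACTORS: dict[str, tuple[str, ...]] = {
    "loci_scheme": ("random", "signal", "usefulness", "clocklike", "occupancy"),
    "subst_model": ("site-homogeneous", "site-heterogeneous"),
    "clock": ("autocorrelated", "uncorrelated"),
    "prior": ("uniform", "cauchy"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FactorEffect:
    """A systematic age shift tied to one level of one factor.

    ``shift`` Myr is added to the true age of every clade in ``clades``
    (clamped to the feasible interval between its children and parent)
    before posterior jitter is applied, for sets run at ``level``.
    """

    factor: str
    level: str
    clades: tuple[CladeKey, ...]
    shift: float


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic chronospace.

    Defaults emulate a factorial dating study: a 60-tip tree with root at
    500 Myr, 40 settings x 2 runs x 200 posterior samples, per-node age
    jitter of sd 5 Myr, 1% log-normal root-age noise, and a +30 Myr
    clock-model effect on 10 clades.
    """

    n_tips: int = 60
    birth_rate: float = 1.0  # events/Myr before rescaling; shape only
    root_age: float = 500.0
    age_jitter_sd: float = 5.0  # Myr; converted to a per-node Beta concentration
    jitter_concentration: float | None = None  # overrides age_jitter_sd if set
    root_age_sd: float = 0.01  # sd of log root age
    n_samples_per_set: int = 200
    runs_per_setting: int = 2
    factors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS)
    )
    factor_effects: tuple[FactorEffect, ...] | None = None  # None -> default clock effect
    n_effect_nodes: int = 10
    effect_shift: float = 30.0
    effect_factor: str = "clock"
    effect_level: str = "autocorrelated"
    seed: int = 0


class _Node:
    __slots__ = ("time", "children", "label")

    def __init__(self, time=None):
        self.time = time
        self.children: list[_Node] = []
        self.label: str | None = None


def simulate_tree(
    n_tips: int,
    root_age: float = 500.0,
    birth_rate: float = 1.0,
    seed: int | None = 0,
) -> Chronogram:
    """Simulate a pure-birth (Yule) chronogram with ``n_tips`` extant tips.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); after the last split the process runs one further waiting
    time so no node sits at age 0, and node times are rescaled to put the
    root at ``root_age`` Myr.  Tips are labeled t01, t02, ... in a
    deterministic traversal order.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    rng = np.random.default_rng(seed)
    root = _Node(time=0.0)
    active = [_Node(), _Node()]
    root.children = list(active)
    now = 0.0
    while len(active) < n_tips:
        k = len(active)
        now += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node.time = now
        node.children = [_Node(), _Node()]
        active.extend(node.children)
    present = now + rng.exponential(1.0 / (birth_rate * n_tips))
    width = len(str(n_tips))
    counter = itertools.count(1)
    ages: dict[CladeKey, float] = {}

    def finalize(node: _Node) -> frozenset:
        if not node.children:
            node.time = present
            node.label = f"t{next(counter):0{width}d}"
            return frozenset([node.label])
        tips = frozenset().union(*(finalize(c) for c in node.children))
        ages[tips] = (present - node.time) * root_age / present
        return tips

    def newick(node: _Node) -> str:
        if not node.children:
            return node.label
        return "(" + ",".join(newick(c) for c in node.children) + ")"

    finalize(root)
    topo = Topology.from_newick(newick(root) + ";")
    return Chronogram(topo, np.array([ages[k] for k in topo.keys]))


def _shifted_true_ages(
    tree: Chronogram,
    effects: Sequence[FactorEffect],
    level_assignment: Mapping[str, str],
) -> tuple[np.ndarray, list[str]]:
    """Apply matching factor effects to the true ages, clamped to the
    feasible interval; returns shifted ages plus clamp warnings."""
    topo = tree.topology
    ages = tree.ages.copy()
    notes: list[str] = []
    targets: list[tuple[int, float]] = []
    for eff in effects:
        if str(level_assignment.get(eff.factor)) != str(eff.level):
            continue
        for clade in eff.clades:
            key = frozenset(clade)
            if key not in topo.key_index:
                raise KeyError(f"effect clade {clade_label(key)} not on topology")
            targets.append((topo.key_index[key], eff.shift))
    # root-to-tip order so a shifted parent widens its children's interval
    order = {i: r for r, i in enumerate(topo.preorder())}
    for i, shift in sorted(targets, key=lambda t: order[t[0]]):
        p = topo.parent[i]
        hi = ages[p] if p >= 0 else np.inf
        lo = max((ages[j] for j in topo.child_nodes[i]), default=0.0)
        margin = 1e-6 * (hi - lo) if np.isfinite(hi) else 0.0
        new = float(np.clip(ages[i] + shift, lo + margin, hi - margin))
        realized = new - ages[i]
        if abs(realized) < 0.5 * abs(shift):
            notes.append(
                f"shift on {clade_label(topo.keys[i])} clamped to "
                f"{realized:+.3g} of {shift:+.3g} Myr"
            )
        ages[i] = new
    return ages, notes


def simulate_posterior_set(
    tree: Chronogram,
    level_assignment: Mapping[str, str],
    n_samples: int = 200,
    seed: int | None = 0,
    effects: Sequence[FactorEffect] = (),
    age_jitter_sd: float = 5.0,
    root_age_sd: float = 0.01,
    jitter_concentration: float | None = None,
    metadata: Mapping[str, object] | None = None,
) -> ChronogramSet:
    """Draw a posterior-like set of chronograms around a true tree.

    Per sample, the root age is log-normal around the (possibly shifted)
    true root age with log-sd ``root_age_sd``; each internal node age is
    then assigned root-to-tip as a Beta fraction of its parent's realized
    age, the Beta mean sitting at the node's true relative position.  The
    Beta concentration is chosen per node so the marginal age sd is about
    ``age_jitter_sd`` Myr (or fixed, if ``jitter_concentration`` is
    given); zero values of both noise parameters reproduce the true ages
    exactly.  Factor effects matching ``level_assignment`` shift the true
    ages before jitter; a clamped shift realizing less than half its
    nominal size emits a warning.
    """
    topo = tree.topology
    true_ages, notes = _shifted_true_ages(tree, effects, level_assignment)
    for note in notes:
        warnings.warn(note, stacklevel=2)
    rng = np.random.default_rng(seed)
    ages = np.empty((n_samples, topo.n_internal))
    r = topo.root_index
    root_true = true_ages[r]
    if root_age_sd > 0:
        ages[:, r] = root_true * np.exp(rng.normal(0.0, root_age_sd, n_samples))
    else:
        ages[:, r] = root_true
    for i in topo.preorder():
        if i == r:
            continue
        p = topo.parent[i]
        m = float(np.clip(true_ages[i] / true_ages[p], 1e-9, 1 - 1e-9))
        if jitter_concentration is not None:
            kappa = jitter_concentration
        elif age_jitter_sd > 0:
            kappa = max(
                m * (1 - m) * (true_ages[p] / age_jitter_sd) ** 2 - 1.0, 0.5
            )
        else:
            kappa = None
        if kappa is None:
            ages[:, i] = m * ages[:, p]
        else:
            b = rng.beta(m * kappa, (1 - m) * kappa, n_samples)
            ages[:, i] = b * ages[:, p]
    md = dict(level_assignment)
    md.update(metadata or {})
    md.setdefault("seed", seed)
    return ChronogramSet(topo, ages, md)


def enumerate_design(
    factors: Mapping[str, Sequence[str]],
    runs_per_setting: int = 2,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Cartesian product of factor levels times replicate runs.

    Returns one row per (setting, run) with a stable ``set_id`` and a
    per-row seed derived by hashing the master seed together with the
    setting's factor levels and run number, so adding further levels or
    runs never changes the seeds of existing rows.
    """
    if not factors:
        raise ValueError("need at least one factor")
    names = list(factors)
    for f in names:
        if not factors[f]:
            raise ValueError(f"factor {f!r} has an empty level list")
    if runs_per_setting < 1:
        raise ValueError("runs_per_setting must be >= 1")
    rows = []
    idx = 0
    for combo in itertools.product(*(factors[f] for f in names)):
        for run in range(1, runs_per_setting + 1):
            key = "|".join([str(master_seed), *map(str, combo), str(run)])
            digest = hashlib.sha256(key.encode()).digest()
            seed = int.from_bytes(digest[:4], "big") % 2**31
            rows.append(
                {
                    "set_id": f"s{idx:03d}",
                    **dict(zip(names, combo)),
                    "run_id": f"run{run}",
                    "seed": seed,
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def default_clock_effect(
    tree: Chronogram,
    n_nodes: int = 10,
    shift: float = 30.0,
    factor: str = "clock",
    level: str = "autocorrelated",
) -> FactorEffect:
    """Pick the ``n_nodes`` non-root clades with the most headroom below
    their parent (deterministically) and attach a +``shift`` Myr effect."""
    topo = tree.topology
    candidates = [
        (tree.ages[topo.parent[i]] - tree.ages[i], i)
        for i in range(topo.n_internal)
        if topo.parent[i] >= 0
    ]
    candidates.sort(key=lambda t: (-t[0], clade_sort_key(topo.keys[t[1]])))
    clades = tuple(topo.keys[i] for _, i in candidates[:n_nodes])
    return FactorEffect(factor=factor, level=level, clades=clades, shift=shift)


@dataclass
class SimulatedChronospace:
    """A synthetic study: true tree, design table, sets and age matrix."""

    tree: Chronogram
    design: pd.DataFrame
    sets: list[ChronogramSet]
    matrix: ChronospaceMatrix
    effects: tuple[FactorEffect, ...]


def simulate_chronospace(config: SimulationConfig | None = None, **overrides) -> SimulatedChronospace:
    """Run the full synthetic study described by ``config``.

    Simulates the true tree, enumerates the factorial design, draws one
    posterior-like chronogram set per design row (seeds propagate
    hierarchically: master -> design row -> samples) and stacks them into
    a :class:`ChronospaceMatrix`.
    """
    config = replace(config or SimulationConfig(), **overrides)
    tree = simulate_tree(
        config.n_tips, config.root_age, config.birth_rate, seed=config.seed
    )
    effects = config.factor_effects
    if effects is None:
        effects = (
            default_clock_effect(
                tree,
                n_nodes=config.n_effect_nodes,
                shift=config.effect_shift,
                factor=config.effect_factor,
                level=config.effect_level,
            ),
        )
    effects = tuple(effects)
    design = enumerate_design(
        config.factors, config.runs_per_setting, master_seed=config.seed
    )
    factor_names = list(config.factors)
    sets = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamped shifts are expected on tight clades
        for _, row in design.iterrows():
            assignment = {f: row[f] for f in factor_names}
            sets.append(
                simulate_posterior_set(
                    tree,
                    assignment,
                    n_samples=config.n_samples_per_set,
                    seed=int(row["seed"]),
                    effects=effects,
                    age_jitter_sd=config.age_jitter_sd,
                    root_age_sd=config.root_age_sd,
                    jitter_concentration=config.jitter_concentration,
                    metadata={"set_id": row["set_id"], "run_id": row["run_id"]},
                )
            )
    matrix = align_sets(sets)
    return SimulatedChronospace(tree, design, sets, matrix, effects)


# ---------------------------------------------------------------------------
# synthetic loci


def _to_dendropy(tree: Chronogram):
    import dendropy

    return dendropy.Tree.get(data=tree.to_newick(), schema="newick")


def _nni(tree, rng) -> bool:
    """One random nearest-neighbor interchange; returns False if the tree
    has no eligible internal edge."""
    edges = [
        e
        for e in tree.preorder_edge_iter()
        if e.tail_node is not None
        and e.head_node.is_internal()
        and len(e.tail_node.child_nodes()) >= 2
    ]
    if not edges:
        return False
    e = edges[int(rng.integers(len(edges)))]
    u, v = e.tail_node, e.head_node
    a = v.child_nodes()[int(rng.integers(len(v.child_nodes())))]
    siblings = [c for c in u.child_nodes() if c is not v]
    b = siblings[int(rng.integers(len(siblings)))]
    v.remove_child(a)
    u.remove_child(b)
    v.add_child(b)
    u.add_child(a)
    return True


def _evolve_alignment(tree, labels, length, rate, rng) -> dict[str, str]:
    """Per-site substitution along the tree under a uniform-exchange
    20-state process (prob. exp(-rate*t) of retaining the state, else a
    uniform redraw)."""
    n_states = len(AMINO_ACIDS)
    seqs: dict[str, np.ndarray] = {}

    root_states = rng.integers(n_states, size=length)

    def walk(node, states):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            keep = rng.random(length) < np.exp(-rate * t)
            new = np.where(keep, states, rng.integers(n_states, size=length))
            if child.is_leaf():
                seqs[child.taxon.label] = new
            else:
                walk(child, new)

    walk(tree.seed_node, root_states)
    alphabet = np.array(list(AMINO_ACIDS))
    return {lab: "".join(alphabet[seqs[lab]]) for lab in labels if lab in seqs}


def simulate_loci(
    species_tree: Chronogram,
    n_loci: int,
    nni_moves_per_locus: int | Sequence[int] = 2,
    alignment_length: int = 200,
    seed: int | None = 0,
    base_rate: float = 0.002,
    rate_log_sd: float = 0.5,
    branch_length_log_sd: float = 0.2,
    taxon_dropout: float = 0.0,
) -> dict[str, dict]:
    """Simulate per-locus alignments and gene trees from a species tree.

    Each gene tree is the species tree after ``k`` seeded NNI moves with
    multiplicative log-normal branch-length noise; internal-branch
    supports decrease with ``k``.  Amino-acid alignments evolve along the
    gene tree under a uniform-exchange 20-state process, with per-locus
    rates log-normal around ``base_rate`` substitutions/site/Myr.
    Optionally, taxa drop out of a locus independently with probability
    ``taxon_dropout`` (at least four are always retained).

    Returns ``{locus_id: {"alignment": {taxon: seq}, "tree": newick,
    "nni_moves": k, "rate": r}}``.
    """
    if n_loci < 1:
        raise ValueError("need n_loci >= 1")
    if isinstance(nni_moves_per_locus, (int, np.integer)):
        moves = [int(nni_moves_per_locus)] * n_loci
    else:
        moves = [int(k) for k in nni_moves_per_locus]
        if len(moves) != n_loci:
            raise ValueError("nni_moves_per_locus length must equal n_loci")
    rng = np.random.default_rng(seed)
    labels = list(species_tree.topology.tip_labels)
    width = max(3, len(str(n_loci)))
    out: dict[str, dict] = {}
    for li in range(n_loci):
        k = moves[li]
        gt = _to_dendropy(species_tree)
        done = 0
        for _ in range(k):
            done += _nni(gt, rng)
        rate = base_rate * float(np.exp(rng.normal(0.0, rate_log_sd)))
        for e in gt.preorder_edge_iter():
            if e.length is not None:
                e.length = float(e.length * np.exp(rng.normal(0.0, branch_length_log_sd)))
        if taxon_dropout > 0 and len(labels) > 4:
            keep = [l for l in labels if rng.random() >= taxon_dropout]
            if len(keep) < 4:
                keep = sorted(rng.choice(labels, size=4, replace=False).tolist())
            if len(keep) < len(labels):
                gt.retain_taxa_with_labels(keep)
        else:
            keep = labels
        aln = _evolve_alignment(gt, keep, alignment_length, rate, rng)
        for node in gt.preorder_node_iter():
            if node.is_internal() and node.parent_node is not None:
                support = 98 - 12 * done + rng.normal(0.0, 4.0)
                node.label = str(int(np.clip(round(support), 0, 100)))
        newick = gt.as_string(
            schema="newick", suppress_rooting=True, suppress_annotations=True
        ).strip()
        out[f"locus{li + 1:0{width}d}"] = {
            "alignment": aln,
            "tree": newick,
            "nni_moves": done,
            "rate": rate,
        }
    return out
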