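import numpy as np
import pandas as pd
import pytest

from chronospace import (
    compute_gene_properties,
    filter_loci_by_clade_presence,
    rf_similarity,
    select_loci,
    simulate_loci,
    simulate_tree,
    usefulness_axis,
    write_supermatrix,
)
from chronospace.genes import rcfv, read_alignment

from brute import brute_newick_bipartitions

REF5 = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"


def _aln(taxa, length=60, seed=0):
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return {t: "".join(rng.choice(aas, length)) for t in taxa}


class TestProperties:
    def test_ultrametric_gene_tree_has_zero_rtt_variance(self):
        gt = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"
        table = compute_gene_properties(
            {"L1": _aln("ABCDE")}, {"L1": gt}, REF5
        )
        assert table.loc["L1", "rtt_variance"] == pytest.approx(0.0, abs=1e-12)

    def test_gene_tree_identical_to_reference_has_rf_one(self):
        table = compute_gene_properties({"L1": _aln("ABCDE")}, {"L1": REF5}, REF5)
        assert table.loc["L1", "rf_similarity"] == 1.0

    def test_rate_is_tree_length_over_terminals(self):
        gt = "(A:1,B:2,C:3);"
        table = compute_gene_properties(
            {"L1": _aln("ABC")}, {"L1": gt}, "(A:1,B:1,C:1);", min_taxa=3
        )
        assert table.loc["L1", "rate"] == pytest.approx(6.0 / 3.0)

    def test_rf_against_bipartition_enumeration_oracle(self):
        # one NNI away from the reference: C and E exchanged
        nni = "((A:1,B:1):1,((E:1,D:1):1,C:2):1);"
        got = rf_similarity(nni, REF5)
        A = brute_newick_bipartitions(nni)
        B = brute_newick_bipartitions(REF5)
        expected = 1 - len(A ^ B) / (len(A) + len(B))
        assert got == pytest.approx(expected)
        assert got < 1.0
        # symmetry and rotation invariance
        assert rf_similarity(REF5, nni) == pytest.approx(got)
        rotated = "(((D:1,C:1):1,E:2):1,(B:1,A:1):1);"
        assert rf_similarity(rotated, REF5) == 1.0

    def test_rf_handles_polytomy_in_reference(self):
        collapsed = "((A:1,B:1):1,(C:1,D:1,E:1):1);"  # contentious node collapsed
        resolved = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"
        sim = rf_similarity(resolved, collapsed)
        # resolved tree has one extra bipartition {C,D}; collapsed has none extra
        assert 0 < sim < 1
        A = brute_newick_bipartitions(resolved)
        B = brute_newick_bipartitions(collapsed)
        assert sim == pytest.approx(1 - len(A ^ B) / (len(A) + len(B)))

    def test_rcfv_hand_computation(self):
        # taxon X all alanine, taxon Y all cysteine: per-state mean freq is
        # 0.5 for A and C; each taxon deviates by 0.5 in both states
        assert rcfv({"X": "AAAA", "Y": "CCCC"}) == pytest.approx(
            (0.5 + 0.5 + 0.5 + 0.5) / 2
        )
        assert rcfv({"X": "AAAA", "Y": "AAAA"}) == 0.0

    def test_saturation_slope_zero_intercept_regression(self):
        # star tree, all patristic distances 2; p-distances 0.2, 0.4, 0.4
        aln = {"A": "A" * 100, "B": "A" * 80 + "C" * 20, "C": "A" * 60 + "D" * 40}
        table = compute_gene_properties(
            {"L1": aln}, {"L1": "(A:1,B:1,C:1);"}, "(A:1,B:1,C:1);", min_taxa=3
        )
        expected = (2 * (0.2 + 0.4 + 0.4)) / (3 * 4)
        assert table.loc["L1", "saturation_slope"] == pytest.approx(expected)

    def test_outgroups_removed_before_metrics(self):
        gt = "(((A:1,B:1):1,(C:1,D:1):1):1,OUT:5);"
        table = compute_gene_properties(
            {"L1": _aln(["A", "B", "C", "D", "OUT"])},
            {"L1": gt},
            "((A:1,B:1):1,(C:1,D:1):1,OUT:2);",
            drop_taxa={"OUT"},
        )
        # rate computed on the pruned 4-taxon tree
        assert table.loc["L1", "occupancy"] == 1.0
        assert table.loc["L1", "rate"] < 2.0

    def test_locus_with_too_few_taxa_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            table = compute_gene_properties(
                {"L1": _aln("ABC"), "L2": _aln("ABCDE")},
                {"L1": "(A:1,B:1,C:1);", "L2": REF5},
                REF5,
            )
        assert list(table.index) == ["L2"]

    def test_mean_bootstrap_averages_labeled_branches(self):
        gt = "((A:1,B:1)90:1,((C:1,D:1)50:1,E:2):1);"  # one unlabeled branch
        table = compute_gene_properties({"L1": _aln("ABCDE")}, {"L1": gt}, REF5)
        assert table.loc["L1", "mean_bootstrap"] == pytest.approx(70.0)


def block_table(n=40, seed=0):
    """Gene table with a latent usefulness factor: signal columns rise
    with it, bias columns fall with it, the rest is independent noise."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, 1, n)
    df = pd.DataFrame(
        {
            "mean_bootstrap": 70 + 15 * u + rng.normal(0, 2, n),
            "rf_similarity": 0.7 + 0.1 * u + rng.normal(0, 0.02, n),
            "rate": 2.0 - 0.5 * u + rng.normal(0, 0.1, n),
            "rtt_variance": 1.0 - 0.2 * u + rng.normal(0, 0.05, n),
            "saturation_slope": 0.8 + rng.normal(0, 0.05, n),
            "rcfv": 0.2 - 0.05 * u + rng.normal(0, 0.01, n),
            "occupancy": np.clip(0.8 + rng.normal(0, 0.1, n), 0, 1),
        },
        index=[f"g{i:03d}" for i in range(n)],
    )
    df.index.name = "locus"
    return df, u


class TestUsefulnessAxis:
    def test_dominant_contrast_is_pc1(self):
        table, u = block_table()
        axis = usefulness_axis(table)
        assert axis.index == 0  # the latent contrast dominates
        # scores track the latent factor
        assert np.corrcoef(axis.scores.to_numpy(), u)[0, 1] > 0.95

    def test_orientation_points_toward_signal(self):
        table, _ = block_table(seed=3)
        axis = usefulness_axis(table)
        assert axis.loadings["mean_bootstrap"] > 0
        assert axis.loadings["rf_similarity"] > 0
        assert axis.loadings["rate"] < 0
        assert axis.loadings["rtt_variance"] < 0
        assert axis.loadings["rcfv"] < 0
        top = axis.scores.idxmax()
        assert table.loc[top, "mean_bootstrap"] > table["mean_bootstrap"].median()
        assert table.loc[top, "rate"] < table["rate"].median()

    def test_no_contrast_axis_raises(self):
        rng = np.random.default_rng(1)
        u = rng.normal(0, 1, 30)
        cols = {}
        for i, c in enumerate(
            ["mean_bootstrap", "rf_similarity", "rate", "rtt_variance",
             "saturation_slope", "rcfv", "occupancy"]
        ):
            cols[c] = u * 10 + rng.normal(0, 0.01, 30)  # all co-vary positively
        table = pd.DataFrame(cols, index=[f"g{i}" for i in range(30)])
        with pytest.raises(ValueError, match="manually"):
            usefulness_axis(table)

    def test_too_few_loci_rejected(self):
        table, _ = block_table(n=40)
        with pytest.raises(ValueError, match=">= 8"):
            usefulness_axis(table.head(5))


class TestSelection:
    @pytest.fixture
    def table(self):
        t, _ = block_table(n=20, seed=4)
        return t

    def test_clocklike_rate_filter_hand_oracle(self):
        # rates {1,2,3,10}: mean 4, sd ~4.082 -> 10 is filtered out
        df = pd.DataFrame(
            {
                "rate": [1.0, 2.0, 3.0, 10.0],
                "rtt_variance": [0.4, 0.3, 0.2, 0.01],
                "rf_similarity": [0.5] * 4,
                "occupancy": [1.0] * 4,
            },
            index=["g1", "g2", "g3", "g4"],
        )
        got = select_loci(df, "clocklike", 3)
        assert set(got) == {"g1", "g2", "g3"}
        assert got == ["g3", "g2", "g1"]  # smallest rtt variance first
        with pytest.raises(ValueError, match="fewer than"):
            select_loci(df, "clocklike", 4)

    def test_relaxed_rate_filter_reduces_to_min_variance(self):
        df = pd.DataFrame(
            {
                "rate": [1.0, 2.0, 3.0, 10.0],
                "rtt_variance": [0.4, 0.3, 0.2, 0.01],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        got = select_loci(df, "clocklike", 2, rate_filter_sd=None)
        assert got == ["g4", "g3"]
        # filtered selection is a subset of the relaxed candidate pool
        filtered = select_loci(df, "clocklike", 3)
        assert set(filtered) <= set(select_loci(df, "clocklike", 4, rate_filter_sd=None))

    def test_full_selection_returns_all_in_scheme_order(self, table):
        got = select_loci(table, "signal", len(table))
        assert set(got) == set(table.index)
        rf = table["rf_similarity"]
        assert all(rf[a] >= rf[b] for a, b in zip(got, got[1:]))

    def test_random_scheme_is_seed_reproducible(self, table):
        a = select_loci(table, "random", 5, seed=11)
        b = select_loci(table, "random", 5, seed=11)
        c = select_loci(table, "random", 5, seed=12)
        assert a == b
        assert len(set(a)) == 5
        assert a != c  # overwhelmingly likely for 20 choose 5

    def test_usefulness_scheme_ranks_by_axis_score(self, table):
        axis = usefulness_axis(table)
        got = select_loci(table, "usefulness", 4)
        expected = list(axis.scores.sort_values(ascending=False).index[:4])
        assert got == expected


class TestCladePresenceFilter:
    def test_missing_clade_excludes_locus(self):
        alns = {
            "keep": {"A": "AC", "C": "AC", "E": "AC"},
            "drop": {"A": "AC", "B": "AC", "E": "--"},
        }
        got = filter_loci_by_clade_presence(alns, [{"A", "B"}, {"E"}])
        assert got == ["keep"] if "E" in alns["keep"] else got == []
        # 'drop' has E all-gap, so the {E} clade has no data
        assert "drop" not in got

    def test_one_member_per_clade_suffices(self):
        alns = {"L": {"A": "AA", "D": "AA"}}
        assert filter_loci_by_clade_presence(alns, [{"A", "B"}, {"C", "D"}]) == ["L"]

    def test_matches_brute_force_set_checks(self):
        rng = np.random.default_rng(6)
        taxa = [f"t{i}" for i in range(8)]
        clades = [{"t0", "t1"}, {"t4", "t5", "t6"}]
        alns = {}
        for li in range(30):
            present = [t for t in taxa if rng.random() > 0.4]
            alns[f"L{li:02d}"] = {t: "AC" for t in present}
        got = filter_loci_by_clade_presence(alns, clades)
        expected = [
            l for l in sorted(alns)
            if all(set(alns[l]) & c for c in clades)
        ]
        assert got == expected


class TestSimulatedLociIntegration:
    def test_identical_gene_trees_give_rf_one(self):
        tree = simulate_tree(10, seed=2)
        loci = simulate_loci(tree, 3, nni_moves_per_locus=0, alignment_length=50,
                             seed=5, branch_length_log_sd=0.0)
        table = compute_gene_properties(
            {k: v["alignment"] for k, v in loci.items()},
            {k: v["tree"] for k, v in loci.items()},
            tree.to_newick(),
        )
        assert (table["rf_similarity"] == 1.0).all()

    def test_supermatrix_concatenation(self, tmp_path):
        tree = simulate_tree(8, seed=2)
        loci = simulate_loci(tree, 4, nni_moves_per_locus=1, alignment_length=30, seed=3)
        alns = {k: v["alignment"] for k, v in loci.items()}
        ids = sorted(alns)[:3]
        fa = tmp_path / "super.fasta"
        parts = tmp_path / "parts.tsv"
        write_supermatrix(alns, ids, fa, parts)
        back = read_alignment(fa)
        assert {len(s) for s in back.values()} == {90}
        pt = pd.read_csv(parts, sep="\t")
        assert list(pt["start"]) == [1, 31, 61]
        assert list(pt["end"]) == [30, 60, 90]
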