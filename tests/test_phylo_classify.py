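"""Phylogeny oracles: MSA behaviour, JC closed form, NJ exactness, bootstrap, clades."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from brine18s import synthetic_data as synth
from brine18s.phylo_classify import (
    MSA,
    NOVEL,
    assign_clades,
    bootstrap_support,
    clade_abundance_matrix,
    classify_representatives,
    jc_distance,
    jc_distance_matrix,
    nj_tree,
    progressive_msa,
    tree_bipartitions,
    trim_alignment,
)
from brine18s.otu_clustering import cluster_greedy, global_align

BASES = list("ACGT")


def mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def random_additive_tree(n, rng):
    """Random unrooted binary tree with uniform branch lengths."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (j, i):
            child = nodes.pop(k)
            child.length = float(rng.uniform(0.1, 1.0))
            parent.append(child)
        nodes.append(parent)
    root = TreeNode()
    for child in nodes:
        child.length = float(rng.uniform(0.1, 1.0))
        root.append(child)
    return root


def sp_score(rows, match=1.0, mismatch=-1.0, gap=-2.0):
    total = 0.0
    for a, b in itertools.combinations(rows, 2):
        for x, y in zip(a, b):
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total += gap
            else:
                total += match if x == y else mismatch
    return total


class TestProgressiveMSA:
    def test_two_sequences_equal_pairwise(self):
        msa = progressive_msa([("a", "ACGTACGT"), ("b", "ACGTCGT")])
        aln = global_align("ACGTACGT", "ACGTCGT", free_end_gaps=True)
        assert msa.rows == [aln.aligned_a, aln.aligned_b]

    def test_identical_sequences_gap_free(self):
        seq = "ACGTACGTACGTAGG"
        msa = progressive_msa([(f"s{i}", seq) for i in range(5)])
        assert all(row == seq for row in msa.rows)

    def test_beats_row_shuffled_control(self):
        rng = np.random.default_rng(4)
        base = "ACGTTGCAACGTG______".replace("_", "")
        seqs = [("s%d" % i, mutate(rng, base + "ACGTT", 0.1)) for i in range(6)]
        msa = progressive_msa(seqs)
        score = sp_score(msa.rows)
        # control: same residues, gaps placed randomly per row
        control_scores = []
        for _ in range(5):
            control = []
            for row in msa.rows:
                residues = list(row.replace("-", ""))
                pos = sorted(rng.choice(msa.n_cols, size=len(residues), replace=False))
                new = ["-"] * msa.n_cols
                for p, r in zip(pos, residues):
                    new[p] = r
                control.append("".join(new))
            control_scores.append(sp_score(control))
        assert score >= max(control_scores)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa([("a", "ACGT")])


class TestTrimAlignment:
    def test_gap_free_unchanged(self):
        msa = MSA(["a", "b"], ["ACGTACGT", "ACCTACGT"])
        out = trim_alignment(msa)
        assert out.rows == msa.rows

    def test_gap_dominated_tail_removed(self):
        core = "ACGTACGTAC"
        rows = [core + "-" * 20 for _ in range(19)] + [core + "A" * 20]
        msa = MSA([f"s{i}" for i in range(20)], rows)
        out = trim_alignment(msa, max_gap_fraction=0.9)
        assert out.n_cols == len(core)

    def test_column_count_never_increases(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGT-"), 30)) for _ in range(5)]
        msa = MSA([f"s{i}" for i in range(5)], rows)
        assert trim_alignment(msa, 0.5).n_cols <= msa.n_cols

    def test_all_columns_removed_errors(self):
        msa = MSA(["a", "b", "c"], ["A---", "-C--", "--G-"])
        with pytest.raises(ValueError):
            trim_alignment(msa, max_gap_fraction=0.1)


class TestJukesCantor:
    def test_identical_rows(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_p_tenth(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        assert jc_distance(row_a, row_b) == pytest.approx(0.1073256, abs=1e-6)

    def test_matches_highprecision_formula(self):
        """Random pairs vs an arbitrary-precision Decimal evaluation."""
        import decimal

        decimal.getcontext().prec = 50
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(30, 200))
            a = "".join(rng.choice(BASES, n))
            b = mutate(rng, a, float(rng.uniform(0, 0.4)))
            mism = sum(x != y for x, y in zip(a, b))
            p = decimal.Decimal(mism) / decimal.Decimal(n)
            if p >= decimal.Decimal(3) / 4:
                continue
            expected = -(decimal.Decimal(3) / 4) * (1 - 4 * p / 3).ln()
            assert jc_distance(a, b) == pytest.approx(float(expected), abs=1e-12)

    def test_monotone_in_p(self):
        ds = []
        for k in range(0, 60, 5):
            row_b = "C" * k + "A" * (100 - k)
            ds.append(jc_distance("A" * 100, row_b))
        assert all(x < y for x, y in zip(ds, ds[1:]))

    def test_saturation_capped(self):
        assert jc_distance("A" * 100, "C" * 100) == 5.0

    def test_no_shared_columns_errors(self):
        with pytest.raises(ValueError):
            jc_distance("A---", "---C")

    def test_matrix_agrees_with_pairwise_op(self):
        rng = np.random.default_rng(12)
        rows = ["".join(rng.choice(BASES + ["-"], 120)) for _ in range(6)]
        msa = MSA([f"s{i}" for i in range(6)], rows)
        dist, unreliable = jc_distance_matrix(msa)
        for i, j in itertools.combinations(range(6), 2):
            if not unreliable.iloc[i, j]:
                assert dist.iloc[i, j] == pytest.approx(jc_distance(rows[i], rows[j]))


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        D = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = nj_tree(D)
        for a, b in itertools.combinations("ABCD", 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(D.loc[a, b])
        sides = {frozenset(s) for s in tree_bipartitions(tree)}
        assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides

    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 4, 5], [4, 0, 7], [5, 7, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        tree = nj_tree(D)
        assert tree.find("A").length == pytest.approx((4 + 5 - 7) / 2)
        assert tree.find("B").length == pytest.approx((4 + 7 - 5) / 2)
        assert tree.find("C").length == pytest.approx((5 + 7 - 4) / 2)

    def test_random_additive_matrices_recovered(self):
        """Path metric of the NJ tree equals the additive input to 1e-9."""
        for seed in range(7):
            rng = np.random.default_rng(100 + seed)
            true_tree = random_additive_tree(int(rng.integers(5, 10)), rng)
            dm = true_tree.tip_tip_distances()
            out = nj_tree((list(dm.ids), dm.data))
            for a, b in itertools.combinations(dm.ids, 2):
                assert out.find(a).distance(out.find(b)) == pytest.approx(
                    dm[a, b], abs=1e-9
                )

    def test_topology_matches_skbio_reference(self):
        rng = np.random.default_rng(200)
        true_tree = random_additive_tree(8, rng)
        dm = true_tree.tip_tip_distances()
        ours = nj_tree((list(dm.ids), dm.data))
        theirs = skbio_nj(DistanceMatrix(dm.data, list(dm.ids)))
        assert ours.compare_rfd(theirs) == 0.0

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree((list("ABC"), D))


def two_group_msa(rng, n_per_group=3, n_cols=500, inter=0.15, intra=0.005):
    ancestor = "".join(rng.choice(BASES, n_cols))
    root_a, root_b = mutate(rng, ancestor, inter), mutate(rng, ancestor, inter)
    ids, rows = [], []
    for g, root in (("A", root_a), ("B", root_b)):
        for i in range(n_per_group):
            ids.append(f"{g}{i}")
            rows.append(mutate(rng, root, intra))
    return MSA(ids, rows)


class TestBootstrap:
    def test_planted_deep_split_strongly_supported(self):
        msa = two_group_msa(np.random.default_rng(14))
        tree = bootstrap_support(msa, n_replicates=100, seed=15)
        split = frozenset({"A0", "A1", "A2"})
        biparts = tree_bipartitions(tree)
        node = biparts.get(split) or biparts.get(frozenset({"B0", "B1", "B2"}))
        assert node is not None
        assert node.support >= 0.95

    def test_single_replicate_supports_binary(self):
        msa = two_group_msa(np.random.default_rng(16))
        tree = bootstrap_support(msa, n_replicates=1, seed=17)
        for node in tree_bipartitions(tree).values():
            assert node.support in (0.0, 1.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(18)
        msa = two_group_msa(rng)
        perm = [3, 0, 5, 2, 4, 1]
        msa_perm = MSA([msa.ids[i] for i in perm], [msa.rows[i] for i in perm])
        t1 = bootstrap_support(msa, n_replicates=50, seed=19)
        t2 = bootstrap_support(msa_perm, n_replicates=50, seed=19)
        s1 = {b: n.support for b, n in tree_bipartitions(t1).items()}
        s2 = {b: n.support for b, n in tree_bipartitions(t2).items()}
        assert set(s1) == set(s2)
        # same bipartitions exist; supports agree in distribution given the seed
        assert all(abs(s1[b] - s2[b]) <= 0.2 for b in s1)

    def test_replicate_count_validated(self):
        msa = two_group_msa(np.random.default_rng(20))
        with pytest.raises(ValueError):
            bootstrap_support(msa, n_replicates=0)


@pytest.fixture(scope="module")
def classification():
    rng = np.random.default_rng(25)
    panel = synth.generate_reference_panel(4, 3, 300, 0.30, 0.05, seed=25)
    mutable = synth._mutable_mask(300, panel.layout())
    reps, expected = {}, {}
    # planted queries from each kingdom
    for i, (eid, kingdom, seq) in enumerate(panel.entries[::3]):
        arr = np.frombuffer(seq.encode(), np.uint8)
        reps[f"Q{i}"] = synth._mutate(rng, arr, 0.01, mutable).tobytes().decode()
        expected[f"Q{i}"] = kingdom
    # an exact copy of a reference
    reps["COPY"] = panel.entries[0][2]
    expected["COPY"] = panel.entries[0][1]
    # an unrelated random query
    reps["RAND"] = "".join(rng.choice(BASES, 300))
    expected["RAND"] = NOVEL
    result = classify_representatives(reps, panel, n_replicates=50, seed=26)
    return panel, reps, expected, result


class TestCladeAssignment:
    def test_planted_kingdoms_recovered(self, classification):
        panel, reps, expected, result = classification
        a = result["assignments"]
        for q, kingdom in expected.items():
            if kingdom == NOVEL:
                continue
            assert kingdom in a.loc[q, "clade_label"].split("+")

    def test_exact_reference_copy_gets_its_kingdom(self, classification):
        panel, reps, expected, result = classification
        assert expected["COPY"] in result["assignments"].loc["COPY", "clade_label"].split("+")

    def test_random_query_is_novel(self, classification):
        panel, reps, expected, result = classification
        assert result["assignments"].loc["RAND", "clade_label"] == NOVEL

    def test_tree_without_references_rejected(self):
        D = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("XYZ"), columns=list("XYZ"),
            dtype=float,
        )
        tree = nj_tree(D)
        with pytest.raises(ValueError, match="reference"):
            assign_clades(tree, {"R": "K01"})


class TestCladeAbundanceMatrix:
    @staticmethod
    def _table(counts_by_otu):
        from collections import Counter

        derep = []
        for i, counts in enumerate(counts_by_otu):
            seq = "".join(np.random.default_rng(i).choice(BASES, 200))
            derep.append((seq, Counter(counts)))
        return cluster_greedy(derep, 0.01)

    def test_single_clade_row_is_100(self):
        table = self._table([{"S": 10}])
        assignments = pd.DataFrame(
            {"clade_label": ["K01"]}, index=[table.otus[0].otu_id]
        )
        m = clade_abundance_matrix(assignments, table)
        assert m.loc["S", "K01"] == 100.0

    def test_thirty_seventy_split(self):
        table = self._table([{"S": 30}, {"S": 70}])
        labels = {
            otu.otu_id: ("X" if otu.total_count == 30 else "Y") for otu in table.otus
        }
        assignments = pd.DataFrame({"clade_label": pd.Series(labels)})
        m = clade_abundance_matrix(assignments, table)
        assert m.loc["S", "X"] == pytest.approx(30.0)
        assert m.loc["S", "Y"] == pytest.approx(70.0)

    def test_rows_sum_to_100_and_match_bruteforce_tally(self):
        rng = np.random.default_rng(31)
        table = self._table(
            [{s: int(rng.integers(0, 20)) for s in "AB"} for _ in range(6)]
        )
        labels = [rng.choice(["K1", "K2", "K3"]) for _ in table.otus]
        assignments = pd.DataFrame(
            {"clade_label": labels}, index=[o.otu_id for o in table.otus]
        )
        m = clade_abundance_matrix(assignments, table)
        assert np.allclose(m.sum(axis=1), 100.0, atol=1e-9)
        counts = table.count_matrix()
        for sample in m.index:
            for clade in m.columns:
                expected = sum(
                    counts.loc[o.otu_id, sample]
                    for o, lab in zip(table.otus, labels)
                    if lab == clade
                )
                assert m.loc[sample, clade] == pytest.approx(
                    100.0 * expected / counts[sample].sum()
                )

    def test_unassigned_otu_errors_with_ids(self):
        table = self._table([{"S": 5}, {"S": 5}])
        assignments = pd.DataFrame(
            {"clade_label": ["K01"]}, index=[table.otus[0].otu_id]
        )
        with pytest.raises(ValueError, match=table.otus[1].otu_id):
            clade_abundance_matrix(assignments, table)
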