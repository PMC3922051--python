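"""De novo phylogeny-based placement of OTU representatives.

Representatives of the 20%-dissimilarity OTUs are aligned together with a
kingdom-labelled reference panel (progressive profile-profile alignment on
a UPGMA guide tree), the alignment is trimmed beyond the extent of the
reads, Jukes-Cantor distances feed a neighbor-joining tree, and bootstrap
resampling of alignment columns yields support values.  Each query is then
assigned the kingdom set of the smallest supported clade (support >= 0.5 by
default, mirroring the posterior-probability acceptance rule of Bayesian
consensus trees) that contains it together with at least one reference.
Queries whose only supported reference-containing clade is the whole tree,
or that sit on conspicuously long terminal branches (above the 95th
percentile of reference terminal branches — a long-branch-attraction
guard), are reported as NOVEL lineages.

The per-sample percentages of reads falling in each clade form the
clade-abundance matrix consumed by the ordination stage.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from brine18s._align import GAP, encode_onehot, nw_align, substitution_matrix
from brine18s.otu_clustering import OTUTable, global_align
from brine18s.synthetic_data import ReferencePanel

NOVEL = "NOVEL"

JC_MAX_DISTANCE = 5.0
MIN_SHARED_COLUMNS = 20


@dataclasses.dataclass
class MSA:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(one-hot (n, L, 4), non-gap mask (n, L)) numpy views of the MSA."""
        onehot = np.stack([encode_onehot(r).T for r in self.rows])
        mask = np.stack(
            [np.frombuffer(r.encode(), dtype=np.uint8) != ord(GAP) for r in self.rows]
        )
        return onehot, mask


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _guide_linkage(seqs: list[str], k: int = 6) -> np.ndarray:
    """UPGMA guide from shared-k-mer distances."""
    n = len(seqs)
    sets = [_kmer_set(s, k) for s in seqs]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            d = 1.0 - len(sets[i] & sets[j]) / denom
            dm[i, j] = dm[j, i] = d
    return linkage(squareform(dm, checks=False), method="average")


def _profile_freq(rows: list[str]) -> np.ndarray:
    """(4, L) base-frequency matrix; gap positions contribute nothing."""
    return np.mean([encode_onehot(r) for r in rows], axis=0)


def progressive_msa(
    sequences: list[tuple[str, str]],
    guide: np.ndarray | None = None,
    scoring: tuple[float, float, float] = (1.0, -1.0, -2.0),
) -> MSA:
    """Progressive multiple alignment along a UPGMA guide tree.

    ``guide`` may be a precomputed scipy linkage matrix over the sequences
    (in input order); by default one is built from shared 6-mer distances.
    Profile-profile alignment maximises the expected match/mismatch score
    between column base-frequency profiles under linear gap costs, and is
    fully deterministic.
    """
    if len(sequences) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [i for i, _ in sequences]
    seqs = [s.upper() for _, s in sequences]
    if len(sequences) == 2:
        aln = global_align(seqs[0], seqs[1], *scoring, free_end_gaps=True)
        return MSA(ids, [aln.aligned_a, aln.aligned_b])
    Z = _guide_linkage(seqs) if guide is None else np.asarray(guide)
    match, mismatch, gap = scoring
    M = substitution_matrix(match, mismatch)
    # cluster index -> (member indices, aligned rows)
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    nxt = len(seqs)
    for a, b, _, _ in Z:
        ia, rows_a = profiles.pop(int(a))
        ib, rows_b = profiles.pop(int(b))
        FA, FB = _profile_freq(rows_a), _profile_freq(rows_b)
        S = FA.T @ M @ FB
        _, ops = nw_align(S, gap, free_ends=True)
        new_a = [[] for _ in rows_a]
        new_b = [[] for _ in rows_b]
        i = j = 0
        for di, dj in ops:
            for r, row in enumerate(rows_a):
                new_a[r].append(row[i] if di else GAP)
            for r, row in enumerate(rows_b):
                new_b[r].append(row[j] if dj else GAP)
            i += di
            j += dj
        profiles[nxt] = (ia + ib, ["".join(r) for r in new_a] + ["".join(r) for r in new_b])
        nxt += 1
    (indices, rows), = profiles.values()
    order = np.argsort(indices)
    return MSA([ids[indices[k]] for k in order], [rows[k] for k in order])


def trim_alignment(msa: MSA, max_gap_fraction: float = 0.9) -> MSA:
    """Strip leading/trailing column blocks dominated by gaps.

    Emulates trimming the alignment beyond the extent of the amplicon
    reads: contiguous end blocks whose per-column gap fraction exceeds
    ``max_gap_fraction`` are removed; interior columns are never touched.
    """
    arr = np.array([list(r) for r in msa.rows])
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("trimming would remove every alignment column")
    start = int(np.argmax(keep))
    end = int(len(keep) - np.argmax(keep[::-1]))
    return MSA(list(msa.ids), [r[start:end] for r in msa.rows])


def jc_distance(row_i: str, row_j: str) -> float:
    """Jukes-Cantor distance between two gapped alignment rows.

    p is the mismatch fraction over columns where both rows have a base;
    d = -(3/4) ln(1 - 4p/3), capped at 5.0 when p >= 0.75.
    """
    if len(row_i) != len(row_j):
        raise ValueError("rows must have equal (aligned) length")
    pairs = [
        (a, b) for a, b in zip(row_i.upper(), row_j.upper()) if a != GAP and b != GAP
    ]
    if not pairs:
        raise ValueError("no shared ungapped columns between rows")
    p = sum(1 for a, b in pairs if a != b) / len(pairs)
    if p >= 0.75:
        return JC_MAX_DISTANCE
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def jc_distance_matrix(msa: MSA) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs JC distances; returns (distances, reliability flags).

    A pair is flagged unreliable when fewer than 20 ungapped columns are
    shared; such pairs (including zero overlap) are assigned the
    saturation cap — a distance estimated from almost no columns carries
    no signal and the pair should sit on long branches.
    """
    onehot, mask = msa.to_arrays()
    n, L = mask.shape
    flat = onehot.reshape(n, L * 4)
    matches = flat @ flat.T
    shared = mask.astype(np.float64) @ mask.T.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, 1.0 - matches / np.maximum(shared, 1.0), 1.0)
    p = np.clip(p, 0.0, 1.0)
    d = np.where(
        (p < 0.75) & (shared >= MIN_SHARED_COLUMNS),
        -0.75 * np.log(np.clip(1.0 - 4.0 * p / 3.0, 1e-300, None)),
        JC_MAX_DISTANCE,
    )
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    dist = pd.DataFrame(d, index=msa.ids, columns=msa.ids)
    unreliable = pd.DataFrame(shared < MIN_SHARED_COLUMNS, index=msa.ids, columns=msa.ids)
    return dist, unreliable


def _as_matrix(dm) -> tuple[list[str], np.ndarray]:
    if isinstance(dm, pd.DataFrame):
        return list(dm.index), dm.to_numpy(dtype=float)
    ids, mat = dm
    return list(ids), np.asarray(mat, dtype=float)


def nj_tree(dm) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    ``dm`` is a pandas DataFrame or ``(ids, matrix)``.  Ties in the
    Q-criterion are broken by the smallest index pair; negative branch
    lengths are clamped to zero with the deficit moved to the sibling edge
    so pairwise path lengths are preserved.
    """
    ids, D = _as_matrix(dm)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    D = D.copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first minimum: smallest i, then smallest j
        f, g = int(iu[0][k]), int(iu[1][k])
        lf = 0.5 * D[f, g] + (r[f] - r[g]) / (2.0 * (m - 2))
        lg = D[f, g] - lf
        if lf < 0:
            lf, lg = 0.0, D[f, g]
        elif lg < 0:
            lf, lg = D[f, g], 0.0
        parent = TreeNode()
        nodes[f].length = float(lf)
        nodes[g].length = float(lg)
        parent.append(nodes[f])
        parent.append(nodes[g])
        du = np.maximum(0.5 * (D[f] + D[g] - D[f, g]), 0.0)
        keep = [i for i in range(m) if i not in (f, g)]
        D = np.vstack([D[keep][:, keep], du[keep]])
        D = np.hstack([D, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[i] for i in keep] + [parent]
    a, b, c = 0, 1, 2
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(length)
        root.append(node)
    return root


def _canonical_bipartition(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    return min(side, other, key=lambda s: (len(s), tuple(sorted(s))))


def tree_bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Map canonical internal bipartitions to tree nodes (root excluded)."""
    all_leaves = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            out[_canonical_bipartition(side, all_leaves)] = node
    return out


def bootstrap_support(msa: MSA, n_replicates: int = 100, seed: int = 0) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the full-data tree is the
    fraction of replicate trees containing it, stored on the nodes as
    ``.support``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if len(msa.rows) < 4:
        raise ValueError("bootstrap supports need at least 4 rows")
    dist, _ = jc_distance_matrix(msa)
    tree = nj_tree(dist)
    target = tree_bipartitions(tree)
    counts: Counter = Counter()
    rng = np.random.default_rng(seed)
    onehot, mask = msa.to_arrays()
    n, L = mask.shape
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        oh = onehot[:, cols, :].reshape(n, L * 4)
        mk = mask[:, cols].astype(np.float64)
        matches = oh @ oh.T
        shared = mk @ mk.T
        p = np.clip(1.0 - matches / np.maximum(shared, 1.0), 0.0, 1.0)
        d = np.where(
            (p < 0.75) & (shared >= MIN_SHARED_COLUMNS),
            -0.75 * np.log(np.clip(1.0 - 4.0 * p / 3.0, 1e-300, None)),
            JC_MAX_DISTANCE,
        )
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
        rep_tree = nj_tree((msa.ids, d))
        counts.update(tree_bipartitions(rep_tree).keys())
    for bipart, node in target.items():
        node.support = counts[bipart] / n_replicates
    return tree


def _support_lookup(tree: TreeNode) -> dict[frozenset, float]:
    all_leaves = frozenset(t.name for t in tree.tips())
    out = {}
    for bipart, node in tree_bipartitions(tree).items():
        out[bipart] = float(getattr(node, "support", 1.0))
    return out


def assign_clades(
    tree: TreeNode,
    reference_labels: dict[str, str],
    min_support: float = 0.5,
    dm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label each query leaf by the smallest supported reference clade.

    The tree is midpoint-rooted; for every query the smallest ancestral
    clade with support >= ``min_support`` containing at least one reference
    determines the label (the set of reference kingdoms inside it, joined
    with '+').  A query is NOVEL when that clade is the whole tree or when
    its terminal branch exceeds the 95th percentile of reference terminal
    branch lengths.  ``dm`` (a distance DataFrame) adds nearest-reference
    columns.
    """
    leaf_names = [t.name for t in tree.tips()]
    refs = set(reference_labels) & set(leaf_names)
    if not refs:
        raise ValueError("tree contains no reference leaves")
    queries = [name for name in leaf_names if name not in reference_labels]
    supports = _support_lookup(tree)
    all_leaves = frozenset(leaf_names)
    rooted = tree.root_at_midpoint()
    ref_terminal = np.array(
        [t.length or 0.0 for t in rooted.tips() if t.name in refs]
    )
    long_branch_cutoff = float(np.percentile(ref_terminal, 95))

    def clade_support(node: TreeNode) -> float:
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
            return 1.0
        return supports.get(_canonical_bipartition(side, all_leaves), 0.0)

    rows = []
    tip_by_name = {t.name: t for t in rooted.tips()}
    for q in queries:
        tip = tip_by_name[q]
        label, support = NOVEL, float("nan")
        if (tip.length or 0.0) <= long_branch_cutoff:
            node = tip.parent
            while node is not None:
                members = {t.name for t in node.tips()}
                kingdoms = sorted({reference_labels[r] for r in members & refs})
                if kingdoms:
                    s = clade_support(node)
                    if s >= min_support:
                        if node.is_root():
                            label, support = NOVEL, s
                        else:
                            label, support = "+".join(kingdoms), s
                        break
                node = node.parent
        row = {"otu_id": q, "clade_label": label, "support": support}
        if dm is not None:
            ref_d = dm.loc[q, sorted(refs)]
            row["nearest_ref"] = ref_d.idxmin()
            row["nearest_dist"] = float(ref_d.min())
        rows.append(row)
    return pd.DataFrame(rows).set_index("otu_id")


def clade_abundance_matrix(assignments: pd.DataFrame, table: OTUTable) -> pd.DataFrame:
    """Samples x clades matrix of read percentages; rows sum to 100."""
    labels = assignments["clade_label"]
    missing = [otu.otu_id for otu in table.otus if otu.otu_id not in labels.index]
    if missing:
        raise ValueError(f"OTUs without clade assignment: {missing}")
    counts = table.count_matrix()
    clade_counts = counts.groupby(labels.loc[counts.index]).sum()
    totals = clade_counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        import warnings

        warnings.warn(f"excluding read-free samples from clade matrix: {empty}")
        clade_counts = clade_counts.drop(columns=empty)
        totals = totals.drop(empty)
    pct = 100.0 * clade_counts / totals
    return pct.T.sort_index(axis=1)


def classify_representatives(
    representatives: dict[str, str],
    panel: ReferencePanel,
    n_replicates: int = 100,
    seed: int = 0,
    min_support: float = 0.5,
    max_gap_fraction: float = 0.9,
    drop_ids: set[str] | None = None,
) -> dict:
    """Full placement stage: MSA + trim + JC + NJ + bootstrap + assignment.

    ``drop_ids`` removes named query OTUs before alignment (the curation
    hook for manually excluded representatives).
    """
    queries = {
        otu_id: seq
        for otu_id, seq in representatives.items()
        if not drop_ids or otu_id not in drop_ids
    }
    sequences = [(eid, seq) for eid, _, seq in panel.entries]
    sequences += sorted(queries.items())
    msa = trim_alignment(progressive_msa(sequences), max_gap_fraction)
    dist, unreliable = jc_distance_matrix(msa)
    tree = bootstrap_support(msa, n_replicates=n_replicates, seed=seed)
    labels = {eid: kingdom for eid, kingdom, _ in panel.entries}
    assignments = assign_clades(tree, labels, min_support=min_support, dm=dist)
    return {
        "msa": msa,
        "distances": dist,
        "unreliable_pairs": unreliable,
        "tree": tree,
        "assignments": assignments,
    }


def write_newick(tree: TreeNode, path) -> None:
    """Write the tree with bootstrap supports as internal node labels."""
    clone = tree.copy()
    for node in clone.traverse(include_self=False):
        if not node.is_tip() and hasattr(node, "support"):
            node.name = f"{node.support:.3f}"
    clone.write(str(path))
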