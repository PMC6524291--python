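"""Ortholog clustering, core-genome extraction, and a bootstrapped
neighbor-joining phylogeny.

Orthologous gene clusters are connected components of a protein similarity
graph (edges where a bidirectional alignment passes identity/coverage
thresholds).  The core genome is the set of clusters represented in every
input genome; single-copy core clusters (exactly one member per genome)
feed the distance computation, while multi-copy core clusters are counted
as paralogous and excluded.

Core distances: instead of aligning and concatenating core proteins into a
supermatrix, each single-copy core gene contributes its pairwise p-distance
(1 - identity/100 from a global alignment) and genes are combined by
length-weighted averaging — numerically equivalent to distances read off a
concatenated alignment, without a multiple-alignment step.  The tree is
built with the canonical Saitou-Nei neighbor-joining agglomeration and
rooted on a designated outgroup; bootstrap supports come from resampling
core genes with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import ProteinIndex
from .seqcore import PROTEIN, SequenceRecord, align


@dataclass(frozen=True)
class OrthologCluster:
    cluster_id: str
    members: tuple[tuple[str, str], ...]   # (genome id, gene id)

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def is_core(self, n_genomes: int) -> bool:
        return len(self.genomes()) == n_genomes

    def is_single_copy(self, n_genomes: int) -> bool:
        return self.is_core(n_genomes) and len(self.members) == n_genomes


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, a: int) -> int:
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def cluster_orthologs(
    proteomes: dict[str, Sequence[SequenceRecord]],
    min_identity: float = 50.0,
    min_cov: float = 0.5,
) -> list[OrthologCluster]:
    """Connected-component clustering of a bidirectional-hit graph.

    An edge joins two proteins when the local alignment reaches
    *min_identity* and covers *min_cov* of **both** sequences.  Every input
    gene lands in exactly one cluster (singletons included); cluster ids are
    deterministic, assigned over clusters sorted by member list.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 genomes")
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"genome {gid} has zero proteins; core genome undefined")
    flat: list[tuple[str, SequenceRecord]] = []
    for gid in sorted(proteomes):
        for p in proteomes[gid]:
            flat.append((gid, p))
    idx = ProteinIndex([p for _, p in flat])
    uf = _UnionFind(len(flat))
    by_id = {p.id: i for i, (_, p) in enumerate(flat)}
    for i, (_, q) in enumerate(flat):
        for j in idx.candidates(q.seq):
            if j <= i:
                continue
            s = flat[j][1]
            aln = align(q, s, mode="local")
            if aln.identity < min_identity:
                continue
            qlen, slen = len(q.seq), len(s.seq)
            aligned_q = aln.query_coverage * qlen
            if aligned_q < min_cov * qlen or aligned_q < min_cov * slen:
                continue
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(uf.find(i), []).append(i)
    member_lists = sorted(
        tuple(sorted((flat[i][0], flat[i][1].id) for i in g)) for g in groups.values()
    )
    return [
        OrthologCluster(cluster_id=f"COG{k:05d}", members=m)
        for k, m in enumerate(member_lists, 1)
    ]


def core_single_copy(
    clusters: Sequence[OrthologCluster], n_genomes: int
) -> tuple[list[OrthologCluster], list[OrthologCluster], int]:
    """(core clusters, single-copy core clusters, number of paralogous core
    clusters excluded)."""
    core = [c for c in clusters if c.is_core(n_genomes)]
    single = [c for c in core if c.is_single_copy(n_genomes)]
    return core, single, len(core) - len(single)


# ---------------------------------------------------------------------------
# distances


def _gene_pdist(
    cluster: OrthologCluster,
    proteins_by_id: dict[str, SequenceRecord],
    taxa: Sequence[str],
) -> tuple[np.ndarray, float]:
    """(p-distance matrix over taxa, mean protein length) for one gene."""
    member = {g: proteins_by_id[pid] for g, pid in cluster.members}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align(member[taxa[i]], member[taxa[j]], mode="global")
            D[i, j] = D[j, i] = 1.0 - aln.identity / 100.0
    mean_len = float(np.mean([len(member[t].seq) for t in taxa]))
    return D, mean_len


def core_distances(
    single_copy_core: Sequence[OrthologCluster],
    proteomes: dict[str, Sequence[SequenceRecord]],
    taxa: Sequence[str] | None = None,
) -> tuple[list[str], np.ndarray, list[np.ndarray], np.ndarray]:
    """Length-weighted mean per-gene p-distance matrix.

    Returns (taxa, D, per-gene matrices, per-gene lengths); the per-gene
    pieces let the bootstrap resample genes without re-aligning.
    """
    if not single_copy_core:
        raise ValueError("no single-copy core genes; cannot compute distances")
    taxa = list(taxa) if taxa else sorted(proteomes)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    proteins_by_id = {p.id: p for prots in proteomes.values() for p in prots}
    mats, lens = [], []
    for cl in single_copy_core:
        D_g, l_g = _gene_pdist(cl, proteins_by_id, taxa)
        mats.append(D_g)
        lens.append(l_g)
    lens_arr = np.array(lens)
    D = sum(m * l for m, l in zip(mats, lens_arr)) / lens_arr.sum()
    return taxa, D, mats, lens_arr


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0          # branch length to parent
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (as the smaller-side leaf set is not
        canonical, store the clade side below each internal edge)."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            for c in node.children:
                if not c.is_leaf:
                    side = frozenset(c.leaf_names())
                    if 1 < len(side) < len(all_leaves) - 1:
                        parts.add(min(side, all_leaves - side, key=sorted))
                walk(c)

        walk(self)
        return parts


def nj_tree(D: np.ndarray, taxa: Sequence[str], outgroup: str | None = None) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Q-matrix minimization with ties broken by the smallest (i, j) index pair
    in the current working order; negative branch lengths are clamped to 0
    and the deficit moved to the sibling branch.  The final unrooted tree is
    rooted at the midpoint of the outgroup's pendant edge (or left with a
    trifurcating root if no outgroup is given).
    """
    D = np.asarray(D, dtype=float)
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match taxa")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if outgroup is not None and outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    work = D.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = work[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # ties: smallest (i, j) in current working order
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i_loc, j_loc = min((min(a, b), max(a, b)) for a, b in cand)
        d_ij = sub[i_loc, j_loc]
        li = d_ij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        elif lj < 0:
            lj, li = 0.0, d_ij
        gi, gj = active[i_loc], active[j_loc]
        left, right = nodes[gi], nodes[gj]
        left.length, right.length = li, lj
        parent = TreeNode(children=[left, right])
        # distances from the new node to the remaining ones
        new_row = 0.5 * (work[gi, :] + work[gj, :] - d_ij)
        work = np.pad(work, ((0, 1), (0, 1)))
        work[-1, : len(new_row)] = new_row
        work[: len(new_row), -1] = new_row
        work[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [len(nodes) - 1]

    # join the last two
    a, b = active
    d_ab = work[a, b]
    na, nb = nodes[a], nodes[b]
    if na.is_leaf and not nb.is_leaf:
        na, nb = nb, na
    # attach the simpler node onto the other: unrooted tree with the final
    # edge of length d_ab
    nb.length = d_ab
    if na.is_leaf:
        root = TreeNode(children=[na, nb])
        nb.length = d_ab / 2
        na.length = d_ab / 2
    else:
        na.children.append(nb)
        root = na

    if outgroup is not None:
        root = _root_on_outgroup(root, outgroup)
    return root


def _detach_root(root: TreeNode) -> TreeNode:
    """Collapse a root with a single child."""
    while len(root.children) == 1:
        child = root.children[0]
        child.length += root.length
        root = child
    return root


def _root_on_outgroup(root: TreeNode, outgroup: str) -> TreeNode:
    """Re-root the (unrooted, stored as rooted) tree at the midpoint of the
    outgroup's pendant edge."""
    # build parent links
    parent: dict[int, TreeNode | None] = {id(root): None}

    def walk(node: TreeNode):
        for c in node.children:
            parent[id(c)] = node
            walk(c)

    walk(root)
    og = next(l for l in root.leaves() if l.name == outgroup)
    # path from og's parent up to the old root gets reversed
    new_root = TreeNode()
    p = parent[id(og)]
    og_len = og.length
    og.length = og_len / 2
    new_root.children.append(og)

    # reverse edges along the path p -> ... -> old root
    prev = new_root
    carry = og_len / 2  # length of edge between new_root and p
    node = p
    child_to_remove: TreeNode = og
    while node is not None:
        up = parent[id(node)]
        node.children = [c for c in node.children if c is not child_to_remove]
        next_carry = node.length
        node.length = carry
        prev.children.append(node)
        child_to_remove = node
        prev = node
        carry = next_carry
        node = up
    # the old root may now have a single child; splice it out
    def splice(node: TreeNode):
        node.children = [
            splice_child(c) for c in node.children
        ]
        return node

    def splice_child(node: TreeNode) -> TreeNode:
        while len(node.children) == 1:
            only = node.children[0]
            only.length += node.length
            node = only
        node.children = [splice_child(c) for c in node.children]
        return node

    new_root.children = [splice_child(c) for c in new_root.children]
    return new_root


def bootstrap_supports(
    tree: TreeNode,
    gene_mats: Sequence[np.ndarray],
    gene_lens: np.ndarray,
    taxa: Sequence[str],
    outgroup: str | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Gene-resampling bootstrap: per replicate, draw core genes with
    replacement, rebuild the weighted distance matrix and the NJ tree, and
    count how often each internal edge (bipartition) of *tree* recurs.
    Supports are percentages attached to the internal nodes of *tree*.
    """
    if n_reps <= 0:
        return tree
    if len(gene_mats) < 2:
        import warnings

        warnings.warn("fewer than 2 core genes: bootstrap supports undefined")
        return tree
    rng = np.random.default_rng(seed)
    target = tree.bipartitions()
    counts = {b: 0 for b in target}
    G = len(gene_mats)
    stack = np.stack(gene_mats)          # (G, n, n)
    lens = np.asarray(gene_lens, dtype=float)
    for _ in range(n_reps):
        pick = rng.integers(0, G, size=G)
        w = lens[pick]
        Db = np.tensordot(w, stack[pick], axes=(0, 0)) / w.sum()
        rep = nj_tree(Db, taxa, outgroup=outgroup)
        got = rep.bipartitions()
        for b in target:
            if b in got:
                counts[b] += 1

    all_leaves = frozenset(tree.leaf_names())

    def annotate(node: TreeNode):
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaf_names())
                if 1 < len(side) < len(all_leaves) - 1:
                    key = min(side, all_leaves - side, key=sorted)
                    c.support = 100.0 * counts[key] / n_reps
            annotate(c)

    annotate(tree)
    return tree


def matrix_to_phylip(taxa: Sequence[str], D: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, t in enumerate(taxa):
            fh.write(t + "\t" + "\t".join(f"{D[i, j]:.6f}" for j in range(len(taxa))) + "\n")


def clusters_to_tsv(clusters: Sequence[OrthologCluster], n_genomes: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tn_members\tn_genomes\tis_core\tis_single_copy\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{len(c.members)}\t{len(c.genomes())}\t"
                f"{int(c.is_core(n_genomes))}\t{int(c.is_single_copy(n_genomes))}\t"
                + ";".join(f"{g}:{p}" for g, p in c.members) + "\n"
            )
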