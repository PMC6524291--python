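"""Ortholog clustering, core-genome extraction, NJ trees, bootstraps.

NJ correctness is checked three independent ways: round-trips on additive
matrices from known random trees, exhaustive least-squares topology search
for 5 taxa, and scikit-bio's NJ implementation on a shared matrix.
"""

import itertools

import numpy as np
import pytest

from novitax.pangenome import (
    OrthologCluster,
    bootstrap_supports,
    cluster_orthologs,
    core_distances,
    core_single_copy,
    nj_tree,
)
from novitax.seqcore import PROTEIN, SequenceRecord
from novitax.simulate import _mutate_protein, synthetic_pangenome

# ---------------------------------------------------------------------------
# helpers: random additive trees


def random_additive_tree(taxa, rng):
    """Random unrooted binary tree as (edges, leaf-name map)."""
    edges = []
    names = {}
    nid = [1]

    def new():
        nid[0] += 1
        return nid[0] - 1

    for t in taxa[:3]:
        v = new()
        names[v] = t
        edges.append((0, v, rng.uniform(0.05, 0.5)))
    for t in taxa[3:]:
        a, b, l = edges.pop(rng.integers(0, len(edges)))
        mid, leaf = new(), new()
        names[leaf] = t
        x = rng.uniform(0.2, 0.8) * l
        edges += [(a, mid, x), (mid, b, l - x), (mid, leaf, rng.uniform(0.05, 0.5))]
    return edges, names


def additive_matrix(edges, names, taxa):
    import networkx as nx

    G = nx.Graph()
    for a, b, l in edges:
        G.add_edge(a, b, weight=l)
    inv = {v: k for k, v in names.items()}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = nx.shortest_path_length(G, inv[taxa[i]], inv[taxa[j]], weight="weight")
    return D


def true_bipartitions(edges, names, taxa):
    import networkx as nx

    G = nx.Graph()
    for a, b, _ in edges:
        G.add_edge(a, b)
    allt = frozenset(taxa)
    parts = set()
    for a, b, _ in edges:
        H = G.copy()
        H.remove_edge(a, b)
        side = frozenset(names[n] for n in nx.node_connected_component(H, a) if n in names)
        if 1 < len(side) < len(taxa) - 1:
            parts.add(min(side, allt - side, key=sorted))
    return parts


def tree_path_lengths(tree, taxa):
    paths = {}

    def walk(node, acc):
        acc = acc + [(id(node), node.length)]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree, [])
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[taxa[i]], paths[taxa[j]]
            k = 0
            while k < min(len(pa), len(pb)) and pa[k][0] == pb[k][0]:
                k += 1
            D[i, j] = D[j, i] = sum(l for _, l in pa[k:]) + sum(l for _, l in pb[k:])
    return D


# ---------------------------------------------------------------------------
# clustering


class TestClusterOrthologs:
    def test_shared_gene_families_form_core_clusters(self):
        rng = np.random.default_rng(70)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        ancestors = ["".join(rng.choice(aa, 200)) for _ in range(10)]
        proteomes = {}
        for g in range(3):
            gid = f"g{g}"
            prots = [
                SequenceRecord(f"{gid}|c{i}", _mutate_protein(anc, 0.05, rng), kind=PROTEIN)
                for i, anc in enumerate(ancestors)
            ]
            prots += [
                SequenceRecord(f"{gid}|a{j}", "".join(rng.choice(aa, 180)), kind=PROTEIN)
                for j in range(4)
            ]
            proteomes[gid] = prots
        clusters = cluster_orthologs(proteomes)
        core = [c for c in clusters if c.is_core(3)]
        assert len(core) == 10

    def test_partition_covers_every_gene_once(self):
        proteomes, _ = synthetic_pangenome(n_genomes=3, n_core=8, n_paralogous=2,
                                           n_accessory_per_genome=3, seed=71)
        clusters = cluster_orthologs(proteomes)
        all_ids = [p.id for prots in proteomes.values() for p in prots]
        clustered = [pid for c in clusters for _, pid in c.members]
        assert sorted(clustered) == sorted(all_ids)

    def test_duplicated_gene_makes_cluster_non_single_copy(self):
        proteomes, truth = synthetic_pangenome(n_genomes=4, n_core=6, n_paralogous=1,
                                               n_accessory_per_genome=0, seed=72)
        clusters = cluster_orthologs(proteomes)
        core, single, n_par = core_single_copy(clusters, 4)
        assert len(core) == 6
        assert len(single) == 5
        assert n_par == 1

    def test_unrelated_proteomes_no_multi_genome_clusters(self):
        rng = np.random.default_rng(73)
        aa = list("ARNDCQEGHILKMFPSTWYV")
        proteomes = {
            gid: [SequenceRecord(f"{gid}|p{i}", "".join(rng.choice(aa, 150)), kind=PROTEIN)
                  for i in range(5)]
            for gid in ("g0", "g1")
        }
        clusters = cluster_orthologs(proteomes)
        assert all(len(c.genomes()) == 1 for c in clusters)

    def test_zero_protein_genome_rejected(self):
        with pytest.raises(ValueError, match="zero proteins"):
            cluster_orthologs({"a": [], "b": [SequenceRecord("b|p", "MKLV" * 20, kind=PROTEIN)]})


class TestCoreDistances:
    def test_identical_proteomes_zero_matrix(self):
        proteomes, _ = synthetic_pangenome(n_genomes=3, n_core=5, n_paralogous=0,
                                           n_accessory_per_genome=0, aa_divergence=0.0, seed=74)
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, 3)
        taxa, D, _, _ = core_distances(single, proteomes)
        assert np.allclose(D, 0.0)

    def test_divergence_recovered(self):
        proteomes, _ = synthetic_pangenome(n_genomes=4, n_core=30, n_paralogous=0,
                                           n_accessory_per_genome=0, aa_divergence=0.05, seed=75)
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, 4)
        taxa, D, _, _ = core_distances(single, proteomes)
        off = D[np.triu_indices(4, 1)]
        # two branches at 5% each, minus coincident hits
        expected = 2 * 0.05 * (1 - 0.05) + 2 * 0.05 * 0.05 * (1 / 19)
        assert np.all(np.abs(off - expected) < 0.02)

    def test_single_gene_core_degenerates_to_gene_matrix(self):
        proteomes, _ = synthetic_pangenome(n_genomes=3, n_core=1, n_paralogous=0,
                                           n_accessory_per_genome=0, seed=76)
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, 3)
        taxa, D, mats, _ = core_distances(single, proteomes)
        assert np.allclose(D, mats[0])


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        P = tree_path_lengths(tree, ["a", "b", "c"])
        assert np.allclose(P, D, atol=1e-12)

    def test_additive_round_trip_up_to_12_taxa(self):
        rng = np.random.default_rng(80)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            taxa = [f"t{i}" for i in range(n)]
            edges, names = random_additive_tree(taxa, rng)
            D = additive_matrix(edges, names, taxa)
            tree = nj_tree(D, taxa, outgroup=taxa[0])
            assert tree.bipartitions() == true_bipartitions(edges, names, taxa)
            assert np.allclose(tree_path_lengths(tree, taxa), D, atol=1e-9)

    def test_five_taxon_least_squares_oracle(self):
        """NJ topology matches the best least-squares fit over all 15
        enumerated unrooted 5-taxon topologies."""
        rng = np.random.default_rng(81)
        taxa = list("abcde")

        def ls_rss(D, topo_edges, leaf_of):
            # edge-path incidence regression
            import networkx as nx

            G = nx.Graph()
            for k, (u, v) in enumerate(topo_edges):
                G.add_edge(u, v, idx=k)
            rows, y = [], []
            for i in range(5):
                for j in range(i + 1, 5):
                    path = nx.shortest_path(G, leaf_of[taxa[i]], leaf_of[taxa[j]])
                    row = np.zeros(len(topo_edges))
                    for u, v in zip(path, path[1:]):
                        row[G[u][v]["idx"]] = 1
                    rows.append(row)
                    y.append(D[i, j])
            A = np.array(rows)
            sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
            return float(np.sum((A @ sol - y) ** 2))

        # every unrooted binary 5-taxon topology is two cherries + one lone
        # leaf on the internal path; enumerating unordered cherry pairs
        # gives all 15
        def topo_edges(pair1, pair2, lone):
            leaf_of = {taxa[i]: f"L{i}" for i in range(5)}
            edges = [
                (f"L{pair1[0]}", "X"), (f"L{pair1[1]}", "X"),
                (f"L{pair2[0]}", "Y"), (f"L{pair2[1]}", "Y"),
                (f"L{lone}", "Z"), ("X", "Z"), ("Y", "Z"),
            ]
            return edges, leaf_of

        def nj_split_pairs(tree):
            # the two cherries of the NJ tree identify its topology
            allt = frozenset(taxa)
            out = set()
            for side in tree.bipartitions():
                cherry = side if len(side) == 2 else allt - side
                out.add(tuple(sorted(taxa.index(t) for t in cherry)))
            return out

        for _ in range(20):
            edges, names = random_additive_tree(taxa, rng)
            D = additive_matrix(edges, names, taxa)
            tree = nj_tree(D, taxa)
            best_rss, best_topo = None, None
            for pair1 in itertools.combinations(range(5), 2):
                rest = [x for x in range(5) if x not in pair1]
                for p2i in itertools.combinations(range(3), 2):
                    pair2 = (rest[p2i[0]], rest[p2i[1]])
                    if pair1 > tuple(sorted(pair2)):
                        continue
                    lone = [x for x in rest if x not in pair2][0]
                    e, leaf_of = topo_edges(pair1, pair2, lone)
                    rss = ls_rss(D, e, leaf_of)
                    if best_rss is None or rss < best_rss - 1e-12:
                        best_rss, best_topo = rss, {tuple(sorted(pair1)), tuple(sorted(pair2))}
            assert nj_split_pairs(tree) == best_topo

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [1, 0]]), ["a", "b"])
        D = np.zeros((3, 3))
        D[0, 1] = np.nan
        with pytest.raises(ValueError):
            nj_tree(D, ["a", "b", "c"])
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), list("abc"))

    def test_matches_scikit_bio_topology(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(82)
        taxa = [f"t{i}" for i in range(8)]
        edges, names = random_additive_tree(taxa, rng)
        D = additive_matrix(edges, names, taxa)
        ours = nj_tree(D, taxa).bipartitions()
        sk = skbio_nj(DistanceMatrix(D, taxa))
        allt = frozenset(taxa)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                theirs.add(min(side, allt - side, key=sorted))
        assert ours == theirs


@pytest.fixture(scope="module")
def two_clade_pangenome():
    """Two clades of 3 genomes: strong between-clade signal (5% between
    clades, 0.5% within, 50 core genes)."""
    rng = np.random.default_rng(90)
    aa = list("ARNDCQEGHILKMFPSTWYV")
    ancestors = ["".join(rng.choice(aa, 250)) for _ in range(50)]
    clade_versions = {
        "A": [_mutate_protein(a, 0.05, rng) for a in ancestors],
        "B": [_mutate_protein(a, 0.05, rng) for a in ancestors],
    }
    proteomes = {}
    for clade in ("A", "B"):
        for k in range(3):
            gid = f"{clade}{k}"
            proteomes[gid] = [
                SequenceRecord(f"{gid}|c{i}", _mutate_protein(v, 0.005, rng), kind=PROTEIN)
                for i, v in enumerate(clade_versions[clade])
            ]
    return proteomes


class TestBootstrap:
    def test_clade_edge_gets_high_support(self, two_clade_pangenome):
        proteomes = two_clade_pangenome
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, len(proteomes))
        assert len(single) == 50
        taxa, D, mats, lens = core_distances(single, proteomes)
        tree = nj_tree(D, taxa, outgroup="A0")
        tree = bootstrap_supports(tree, mats, lens, taxa, outgroup="A0",
                                  n_reps=200, seed=4)
        clade_b = frozenset(["B0", "B1", "B2"])
        allt = frozenset(taxa)
        key = min(clade_b, allt - clade_b, key=sorted)
        supports = {}

        def walk(node):
            for c in node.children:
                if not c.is_leaf:
                    side = frozenset(c.leaf_names())
                    if 1 < len(side) < len(taxa) - 1:
                        supports[min(side, allt - side, key=sorted)] = c.support
                walk(c)

        walk(tree)
        assert supports[key] >= 95.0

    def test_same_seed_reproducible(self, two_clade_pangenome):
        proteomes = two_clade_pangenome
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, len(proteomes))
        taxa, D, mats, lens = core_distances(single, proteomes)

        def run():
            t = nj_tree(D, taxa, outgroup="A0")
            return bootstrap_supports(t, mats, lens, taxa, outgroup="A0",
                                      n_reps=50, seed=9).newick()

        assert run() == run()

    def test_zero_reps_leaves_supports_unset(self, two_clade_pangenome):
        proteomes = two_clade_pangenome
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, len(proteomes))
        taxa, D, mats, lens = core_distances(single, proteomes)
        tree = nj_tree(D, taxa)
        tree = bootstrap_supports(tree, mats, lens, taxa, n_reps=0, seed=1)
        assert all(
            c.support is None
            for c in tree.children if not c.is_leaf
        )

    def test_supports_invariant_to_taxon_order(self, two_clade_pangenome):
        proteomes = two_clade_pangenome
        clusters = cluster_orthologs(proteomes)
        _, single, _ = core_single_copy(clusters, len(proteomes))
        taxa, D, mats, lens = core_distances(single, proteomes)
        perm = [3, 0, 5, 1, 4, 2]
        taxa2 = [taxa[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        mats2 = [m[np.ix_(perm, perm)] for m in mats]

        def supports(taxa_, D_, mats_):
            t = nj_tree(D_, taxa_, outgroup="A0")
            t = bootstrap_supports(t, mats_, lens, taxa_, outgroup="A0", n_reps=100, seed=3)
            allt = frozenset(taxa_)
            out = {}

            def walk(node):
                for c in node.children:
                    if not c.is_leaf:
                        side = frozenset(c.leaf_names())
                        if 1 < len(side) < len(taxa_) - 1:
                            out[min(side, allt - side, key=sorted)] = c.support
                    walk(c)

            walk(t)
            return out

        assert supports(taxa, D, mats) == supports(taxa2, D2, mats2)
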