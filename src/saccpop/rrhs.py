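"""Repeated random haplotype sampling (RRHS) consensus phylogenetics.

Diploid genotype matrices cannot be fed to haplotype-based tree
builders directly: heterozygous IUPAC calls have no single nucleotide
state.  RRHS resolves every heterozygous site independently and
uniformly to one of its two encoded alleles, builds one tree per
resolved (pseudo-haploid) matrix, and summarises the replicate trees in
a majority-rule consensus with mean branch lengths and split supports.

The per-replicate tree engine here is neighbor-joining on pairwise
p-distances; the protocol accepts any builder that returns a tree over
the same taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treesum

from saccpop.snpcall import GenotypeMatrix, IUPAC_ALLELES


def sample_haplotype(matrix: GenotypeMatrix,
                     seed: int | tuple[int, ...]) -> GenotypeMatrix:
    """Resolve every het call to one of its two alleles, uniformly and
    independently; non-het calls are unchanged.  Reproducible by seed."""
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    pick_second = rng.random(calls.shape) < 0.5
    for code, (a, b) in IUPAC_ALLELES.items():
        mask = calls == code
        calls[mask & ~pick_second] = a
        calls[mask & pick_second] = b
    return GenotypeMatrix(list(matrix.isolates), matrix.chrom, matrix.pos,
                          matrix.ref, calls)


def p_distance(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Mismatch proportion with pairwise deletion of N sites.

    Raises when no site is comparable rather than silently returning 0.
    """
    if row_a.size != row_b.size:
        raise ValueError("rows have different site counts")
    comparable = (row_a != "N") & (row_b != "N")
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable sites: p-distance undefined")
    return float((row_a[comparable] != row_b[comparable]).sum() / n)


def distance_matrix(matrix: GenotypeMatrix) -> np.ndarray:
    n = len(matrix.isolates)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(matrix.calls[i], matrix.calls[j])
    return d


def check_distance_matrix(d: np.ndarray, atol: float = 1e-12) -> list[str]:
    """Report (never repair) symmetry and triangle-inequality violations."""
    issues = []
    if not np.allclose(d, d.T, atol=atol):
        issues.append("matrix is not symmetric")
    if np.any(np.abs(np.diag(d)) > atol):
        issues.append("diagonal is not zero")
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if d[i, j] > d[i, k] + d[k, j] + atol:
                    issues.append(
                        f"triangle inequality violated at ({i},{j},{k})")
    return issues


def nj_tree(d: np.ndarray, labels: list[str],
            taxon_namespace: dendropy.TaxonNamespace | None = None,
            ) -> dendropy.Tree:
    """Neighbor-joining on a symmetric distance matrix.

    Deterministic: ties in the Q-criterion break towards the earlier
    taxon pair in input order.  Negative branch lengths are clamped to
    zero.  The returned tree is unrooted with a trifurcating seed node.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")

    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = False
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxon_namespace.get_taxon(lab))
        nodes.append(node)

    active = list(range(n))
    dist = d.copy()
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # first minimum in row-major order = taxon order
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        li = 0.5 * sub[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = sub[i, j] - li
        parent = dendropy.Node()
        ci, cj = nodes[ai], nodes[aj]
        parent.add_child(ci)
        parent.add_child(cj)
        ci.edge.length = max(li, 0.0)
        cj.edge.length = max(lj, 0.0)
        new_row = 0.5 * (dist[ai, :] + dist[aj, :] - dist[ai, aj])
        dist = np.vstack([dist, new_row])
        new_col = np.append(new_row, 0.0)
        dist = np.column_stack([dist, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [dist.shape[0] - 1]
    # join the last three nodes on a central trifurcation
    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    center = tree.seed_node
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = max(length, 0.0)
    return tree


@dataclass
class ConsensusTree:
    """Majority-rule consensus with per-split supports (%) and mean branch
    lengths over the replicates containing each split."""

    tree: dendropy.Tree
    replicates: int

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def split_supports(self) -> dict[frozenset[str], float]:
        """Support (%) for each non-trivial split, keyed by the smaller
        side's taxon labels."""
        self.tree.encode_bipartitions()
        all_taxa = self.leaf_labels()
        out = {}
        for node in self.tree.preorder_internal_node_iter():
            if node is self.tree.seed_node or node.label is None:
                continue
            side = {leaf.taxon.label for leaf in node.leaf_iter()}
            other = frozenset(all_taxa - side)
            key = frozenset(side) if len(side) <= len(other) else other
            if 0 < len(key) < len(all_taxa):
                out[key] = float(node.label)
        return out


def rrhs_trees(matrix: GenotypeMatrix, replicates: int = 100, seed: int = 0,
               ) -> dendropy.TreeList:
    """One NJ tree per RRHS replicate; replicate r uses stream (seed, r)."""
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    tns = dendropy.TaxonNamespace(matrix.isolates)
    trees = dendropy.TreeList(taxon_namespace=tns)
    for r in range(replicates):
        sample = sample_haplotype(matrix, (seed, r))
        d = distance_matrix(sample)
        trees.append(nj_tree(d, list(matrix.isolates), taxon_namespace=tns))
    return trees


def consensus_from_trees(trees: dendropy.TreeList,
                         min_freq: float = 0.5) -> ConsensusTree:
    """Majority-rule consensus with supports (%) and mean branch lengths.

    Uses dendropy's split-distribution summarizer, i.e. the same
    summarisation as the SumTrees program.
    """
    for t in trees:
        t.is_rooted = False
        t.encode_bipartitions()
        for e in t.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
    tsum = treesum.TreeSummarizer(support_as_labels=True,
                                  support_as_percentages=True)
    sd = dendropy.SplitDistribution(taxon_namespace=trees.taxon_namespace)
    tsum.count_splits_on_trees(trees, split_distribution=sd)
    con = tsum.tree_from_splits(sd, min_freq=min_freq, rooted=False,
                                include_edge_lengths=True)
    return ConsensusTree(con, len(trees))


def rrhs_consensus(matrix: GenotypeMatrix, replicates: int = 100,
                   seed: int = 0) -> ConsensusTree:
    """The full RRHS protocol: sample, build, summarise."""
    if len(matrix.isolates) < 3:
        raise ValueError("need at least 3 isolates")
    return consensus_from_trees(rrhs_trees(matrix, replicates, seed))
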