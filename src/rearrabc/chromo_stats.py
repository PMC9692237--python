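"""Chromosome-level summary statistics for the multi-chromosome model.

A *tip* is the first or last gene of a chromosome, orientation
disregarded.  A *minimalized chromosome* (MC) is the ordered signed pair
of a chromosome's two tips; since the strand choice of a whole chromosome
is arbitrary, [A, B] and [-B, -A] are the same MC while [-A, B] is not.
A single-gene chromosome [x] has MC [x, x].

Internal tree nodes get the union of their children's MC sets (and the
induced tip sets).  Differences between the sets of siblings signal
chromosome-number events:

* a *unique tip* of a node is a tip absent from every sibling's tip set;
* a *probable fission-fusion* (PFF) at an internal node is an MC [A, B]
  present in at least one child, absent (in both orientations) from some
  other child whose tip set nevertheless contains both A and B.
"""

from __future__ import annotations

import numpy as np

from .genomes import Genome, GenomeSet, PhyloTree

__all__ = [
    "mc_canonical",
    "mc_set",
    "tip_set",
    "propagate_node_sets",
    "leaf_chromosome_stats",
    "unique_tip_count",
    "pff_count",
    "m1_summary",
    "M1_STAT_NAMES",
]

MC = tuple[int, int]


def mc_canonical(a: int, b: int) -> MC:
    """Strand-insensitive representative of the MC [a, b]: min of [a, b]
    and [-b, -a]."""
    return min((a, b), (-b, -a))


def mc_set(genome: Genome) -> frozenset[MC]:
    """One canonical MC per chromosome."""
    return frozenset(mc_canonical(c[0], c[-1]) for c in genome.chromosomes)


def tip_set(mcs: frozenset[MC]) -> frozenset[int]:
    """All tip magnitudes occurring in a set of MCs."""
    return frozenset(abs(x) for mc in mcs for x in mc)


def leaf_chromosome_stats(gs: GenomeSet) -> tuple[int, int, float, float]:
    """(min, max, mean, population variance) of leaf chromosome counts."""
    counts = np.array([g.n_chromosomes for g in gs.genomes.values()], dtype=float)
    return (
        int(counts.min()),
        int(counts.max()),
        float(counts.mean()),
        float(counts.var()),  # population variance (ddof=0)
    )


def propagate_node_sets(
    tree: PhyloTree, gs: GenomeSet
) -> dict[int, tuple[frozenset[MC], frozenset[int]]]:
    """Postorder union of MC sets up the tree.

    Returns a mapping ``id(node) -> (mc_set, tip_set)`` for every node;
    leaves take their genome's sets, internal nodes the union over children.
    """
    tree.check_leaves(gs.names())
    sets: dict[int, tuple[frozenset[MC], frozenset[int]]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            mcs = mc_set(gs[node.taxon.label])
        else:
            mcs = frozenset().union(
                *(sets[id(ch)][0] for ch in node.child_nodes())
            )
        sets[id(node)] = (mcs, tip_set(mcs))
    return sets


def unique_tip_count(tree: PhyloTree, nodesets) -> int:
    """Size of the union, over all non-root nodes, of tips present in the
    node's tip set but in no sibling's tip set."""
    unique: set[int] = set()
    for node in tree.tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        for ch in children:
            own = nodesets[id(ch)][1]
            sibs: set[int] = set()
            for other in children:
                if other is not ch:
                    sibs |= nodesets[id(other)][1]
            unique |= own - sibs
    return len(unique)


def pff_count(tree: PhyloTree, nodesets) -> int:
    """Total probable fission-fusion signatures over internal nodes.

    Counts one per (internal node, canonical MC): the MC must be present in
    >= 1 child, absent in both orientations from >= 1 other child, and that
    other child's tip set must contain both of the MC's tips.
    """
    total = 0
    for node in tree.tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        node_mcs = frozenset().union(*(nodesets[id(ch)][0] for ch in children))
        for mc in node_mcs:
            tips = {abs(mc[0]), abs(mc[1])}
            for ch in children:
                ch_mcs, ch_tips = nodesets[id(ch)]
                if mc not in ch_mcs and tips <= ch_tips:
                    total += 1
                    break
    return total


M1_STAT_NAMES = [
    "chrom_min",
    "chrom_max",
    "chrom_mean",
    "chrom_var",
    "root_mc_set_size",
    "root_tip_set_size",
    "unique_tips",
    "pff",
]


def m1_summary(gs: GenomeSet, tree: PhyloTree) -> np.ndarray:
    """The 8 chromosome-level statistics, ordered as
    [min, max, mean, var, root MC-set size, root tip-set size,
    unique tips, PFFs]."""
    nodesets = propagate_node_sets(tree, gs)
    mn, mx, mean, var = leaf_chromosome_stats(gs)
    root = tree.tree.seed_node
    root_mcs, root_tips = nodesets[id(root)]
    return np.array(
        [
            mn,
            mx,
            mean,
            var,
            len(root_mcs),
            len(root_tips),
            unique_tip_count(tree, nodesets),
            pff_count(tree, nodesets),
        ],
        dtype=float,
    )
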