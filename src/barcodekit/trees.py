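"""Distance-tree construction and tree utilities.

Trees are `dendropy.Tree` objects whose tip labels are record ids.
Neighbour-joining serves the tree-based identification criteria; UPGMA
provides an ultrametric tree suitable for branching-rate species
delimitation when no externally dated (e.g. Bayesian relaxed-clock) tree
is supplied.  Newick is the interchange format throughout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .io import BarcodeRecord

ULTRAMETRIC_TOL = 1e-6


def _pdm_from_matrix(m: DistanceMatrix) -> dendropy.PhylogeneticDistanceMatrix:
    if np.isnan(m.d).any():
        raise ValueError(
            "distance matrix contains undefined entries; raise min_overlap "
            "coverage or drop the affected sequences before building a tree"
        )
    buf = _io.StringIO()
    pd.DataFrame(m.d, index=m.ids, columns=m.ids).to_csv(buf)
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")


def _clamp_negative_branches(tree: dendropy.Tree) -> None:
    """Zero out negative NJ branch lengths, moving the excess to the sibling."""
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2:
            a, b = children
            for x, y in ((a, b), (b, a)):
                if x.edge.length is not None and x.edge.length < 0:
                    excess = -x.edge.length
                    x.edge.length = 0.0
                    if y.edge.length is not None:
                        y.edge.length += excess
        for c in children:
            if c.edge.length is not None and c.edge.length < 0:
                c.edge.length = 0.0


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree from a p-distance matrix.

    The result is an unrooted topology stored with an arbitrary root;
    negative branch lengths are clamped to zero with the excess moved to
    the sibling branch so that path lengths are preserved as closely as
    possible.
    """
    if m.n < 3:
        raise ValueError("neighbour-joining requires at least 3 taxa")
    tree = _pdm_from_matrix(m).nj_tree()
    _clamp_negative_branches(tree)
    # NJ is unrooted; store midpoint-rooted so clade-based criteria see a
    # deterministic, sensible root (midpoint falls on the longest path,
    # normally a between-species branch)
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def upgma_tree(m: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average-linkage) tree; ultrametric by construction."""
    if m.n < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    return _pdm_from_matrix(m).upgma_tree()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def root_tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip."""
    depths: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent_depth = 0.0 if node.parent_node is None else node.parent_node._depth
        node._depth = parent_depth + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._depth
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> bool:
    depths = list(root_tip_depths(tree).values())
    return (max(depths) - min(depths)) <= tol


def node_ages(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> dict:
    """Map each node to its age (time before present; tips at 0).

    Requires an ultrametric tree.
    """
    if not is_ultrametric(tree, tol):
        raise ValueError("tree is not ultrametric within tolerance")
    depths = root_tip_depths(tree)
    height = max(depths.values())
    ages = {}
    for node in tree.preorder_node_iter():
        ages[node] = max(0.0, height - node._depth)
    return ages


def collapse_identical(
    records: Sequence[BarcodeRecord],
) -> tuple[list[BarcodeRecord], dict[str, list[str]]]:
    """Deduplicate identical sequence strings before tree-based delimitation.

    Returns one representative record per distinct sequence (the first
    occurrence, in input order) and a map representative id -> all member
    ids, so entities delimited on the collapsed tree can be re-expanded.
    """
    reps: list[BarcodeRecord] = []
    membership: dict[str, list[str]] = {}
    by_seq: dict[str, str] = {}
    for r in records:
        rep = by_seq.get(r.sequence)
        if rep is None:
            by_seq[r.sequence] = r.id
            reps.append(r)
            membership[r.id] = [r.id]
        else:
            membership[rep].append(r.id)
    return reps, membership


def root_on(tree: dendropy.Tree, outgroup_tip: str) -> dendropy.Tree:
    """Root the tree on the branch subtending the given outgroup tip."""
    clone = tree.clone(depth=1)
    node = None
    for leaf in clone.leaf_node_iter():
        if leaf.taxon.label == outgroup_tip:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup tip {outgroup_tip!r} not found in tree")
    length = node.edge.length or 0.0
    clone.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2,
                         update_bipartitions=False)
    return clone


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=False, unquoted_underscores=True)


def write_membership(membership: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"representative": rep, "member": mem}
        for rep, members in membership.items()
        for mem in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
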