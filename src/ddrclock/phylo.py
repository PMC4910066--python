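"""Neighbor-joining trees and the single-duplication bipartition test.

The applicability test for the repeat-divergence clock follows the classic
paralog-rooting logic of Gogarten and Iwabe: build one tree from the first
and second repeat copies of every gene in the family; if the family arose
from a single tandem duplication, some internal edge must split the leaves
exactly into {all first repeats} versus {all second repeats}. A later
re-duplication in any lineage destroys that clean bipartition.

Tree construction and Newick serialization are delegated to scikit-bio
(Saitou–Nei neighbor joining with negative branch lengths clamped to 0);
trees are unrooted and are exposed as ``skbio.TreeNode`` objects.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import skbio
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from ddrclock.distances import DistanceMatrix, DistanceModel, as_model, distance_matrix
from ddrclock.repeatio import AlignmentSet


class TreeError(ValueError):
    """Invalid input to tree construction or parsing."""


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining on a finite distance matrix.

    Additive matrices are recovered exactly (tree path lengths equal the
    input distances). Negative branch lengths produced by NJ on noisy
    matrices are clamped to zero. Saturated (non-finite) entries are
    rejected before construction.
    """
    if len(dm.labels) < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise TreeError(
            f"matrix contains saturated/non-finite pairs: {dm.saturated_pairs}"
        )
    sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.labels)
    return _skbio_nj(sk_dm, neg_as_zero=True)


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string (strict dialect, unquoted labels)."""
    try:
        return TreeNode.read(io.StringIO(newick))
    except Exception as err:  # skbio raises NewickFormatError
        raise TreeError(f"malformed Newick: {err}") from err


def tip_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Path-length (patristic) distances between all tips."""
    dm = tree.tip_tip_distances()
    return DistanceMatrix(
        labels=list(dm.ids), values=np.asarray(dm.data), model=as_model("p")
    )


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> float:
    return float(t1.compare_rfd(t2))


@dataclass(frozen=True)
class DuplicationTestResult:
    """Outcome of the single-duplication (criterion 1) test.

    ``separation_score`` is the best achievable agreement over all tree
    edges between an edge's bipartition and the first/second repeat
    labeling, as a fraction of leaves on their correct side; it equals 1.0
    iff some edge separates the repeats perfectly (``passed``).
    """

    passed: bool
    separating_edge: frozenset[str] | None
    separation_score: float
    misplaced: tuple[str, ...]


def _bipartitions(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets under every edge of the (unrooted) tree."""
    out = []
    for node in tree.traverse(include_self=False):
        out.append(frozenset(t.name for t in node.tips(include_self=True)))
    return out


def duplication_once_test(
    aln: AlignmentSet,
    model: "DistanceModel | str" = "mcl_composite",
    tree: TreeNode | None = None,
) -> DuplicationTestResult:
    """Test whether a repeat family is consistent with one duplication.

    Builds the NJ tree over all first+second repeat sequences (unless a
    prebuilt ``tree`` over the same leaf ids is supplied) and searches for
    an edge whose bipartition is exactly {first repeats} | {second
    repeats}. The test is symmetric in which copy is called "first" and
    invariant to leaf input order.
    """
    missing = [r.id for r in aln.records if r.id not in aln.metadata]
    if missing:
        raise TreeError(f"records without repeat_index metadata: {missing}")
    genes = {m.gene for m in aln.metadata.values()}
    if len(genes) < 2:
        raise TreeError("duplication test needs repeats from >= 2 genes")
    firsts = frozenset(
        rid for rid, m in aln.metadata.items() if m.repeat_index == 1
    )
    leaves = frozenset(aln.ids)
    if tree is None:
        tree = neighbor_joining(distance_matrix(aln, model))
    n_leaves = len(leaves)
    best_score = 0.5
    best_edge: frozenset[str] | None = None
    best_misplaced: tuple[str, ...] = tuple(sorted(leaves - firsts))
    for side in _bipartitions(tree):
        for target in (firsts, leaves - firsts):
            agree = len(side & target) + len((leaves - side) - target)
            score = agree / n_leaves
            if score > best_score:
                best_score = score
                best_edge = side
                best_misplaced = tuple(
                    sorted((side - target) | ((leaves - side) & target))
                )
    passed = math.isclose(best_score, 1.0)
    return DuplicationTestResult(
        passed=passed,
        separating_edge=best_edge,
        separation_score=best_score,
        misplaced=() if passed else best_misplaced,
    )


def ladderize_by_ddr(tree: TreeNode, ddr_by_gene: dict[str, float]) -> TreeNode:
    """Reorder children by mean per-gene repeat divergence (display only).

    Mirrors the node-swapping used to present repeat trees ordered by
    d_DR; the topology and branch lengths are unchanged.
    """
    tree = tree.copy()

    def node_key(node: TreeNode) -> float:
        vals = [
            ddr_by_gene.get(t.name.rsplit("__r", 1)[0], math.inf)
            for t in node.tips(include_self=True)
        ]
        return float(np.mean(vals)) if vals else math.inf

    for node in tree.traverse(include_self=True):
        if not node.is_tip():
            node.children.sort(key=node_key)
    return tree
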