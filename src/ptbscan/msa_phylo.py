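"""Alignment conservation annotation, distance matrices, NJ trees, midpoint rooting.

This is the computational core behind the survey's phylogenies: per-column
conservation categories against a two-sequence reference (the presentation
used for PTB orthologue alignments), uncorrected p-distances (optionally
Poisson-corrected, so branch lengths are in substitutions per site),
neighbor joining, and midpoint rooting with Newick output.

Trees are held as :class:`skbio.TreeNode`.  NJ is delegated to scikit-bio
(Q-criterion agglomeration with Studier-Keppler branch lengths); negative
estimated branch lengths are clamped to zero with a warning.  Midpoint
rooting is implemented here so the diameter tie-break (lexicographically
smallest endpoint label pair) is documented and deterministic.
"""

from __future__ import annotations

import io
import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ptbscan.errors import AlignmentError, ParameterError
from ptbscan.seq_io import GAP, Alignment

logger = logging.getLogger(__name__)

CATEGORIES = ("reference-identical", "shared-in-≥2", "nonconserved")


@dataclass(frozen=True)
class ConservationAnnotation:
    """Per-cell conservation categories for the non-reference rows.

    ``categories[row_id][col]`` is one of :data:`CATEGORIES`;
    ``ambiguous[row_id][col]`` flags reference-identical calls made in
    columns where the two reference rows disagree.
    """

    reference_ids: tuple[str, str]
    row_ids: tuple[str, ...]
    categories: dict[str, list[str]]
    ambiguous: dict[str, list[bool]]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for row in self.categories.values():
            for c in row:
                out[c] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid in self.row_ids:
            for j, cat in enumerate(self.categories[rid]):
                rows.append((j + 1, rid, cat, self.ambiguous[rid][j]))
        return pd.DataFrame(rows, columns=["column", "row", "category", "ambiguous_reference"])


def annotate_conservation(alignment: Alignment, reference_ids: tuple[str, str]) -> ConservationAnnotation:
    """Categorize every non-reference cell against the two reference rows.

    A residue is *reference-identical* when it equals the (agreeing)
    reference residue; if the references disagree in a column, matching
    either is counted reference-identical with an ambiguity flag.
    Otherwise a residue shared by at least two non-reference rows is
    *shared-in->=2*; everything else (including gaps) is *nonconserved*.
    """
    if len(reference_ids) != 2:
        raise ParameterError("exactly two reference ids are required")
    for rid in reference_ids:
        if rid not in alignment.ids:
            raise AlignmentError(f"reference id {rid!r} not in alignment")
    ref_rows = [alignment.row(r) for r in reference_ids]
    other_ids = tuple(i for i in alignment.ids if i not in reference_ids)
    if not other_ids:
        raise AlignmentError("alignment has no non-reference rows to annotate")
    other_rows = {i: alignment.row(i) for i in other_ids}

    categories = {i: [] for i in other_ids}
    ambiguous = {i: [] for i in other_ids}
    for j in range(alignment.length):
        r1, r2 = ref_rows[0][j], ref_rows[1][j]
        col = {i: other_rows[i][j] for i in other_ids}
        residue_counts: dict[str, int] = {}
        for x in col.values():
            if x != GAP:
                residue_counts[x] = residue_counts.get(x, 0) + 1
        for i in other_ids:
            x = col[i]
            if x == GAP:
                categories[i].append("nonconserved")
                ambiguous[i].append(False)
            elif r1 == r2 and r1 != GAP and x == r1:
                categories[i].append("reference-identical")
                ambiguous[i].append(False)
            elif r1 != r2 and x in (r1, r2) and x != GAP:
                categories[i].append("reference-identical")
                ambiguous[i].append(True)
            elif residue_counts.get(x, 0) >= 2:
                categories[i].append("shared-in-≥2")
                ambiguous[i].append(False)
            else:
                categories[i].append("nonconserved")
                ambiguous[i].append(False)
    return ConservationAnnotation(
        reference_ids=tuple(reference_ids), row_ids=other_ids, categories=categories, ambiguous=ambiguous
    )


def pdistance_matrix(
    alignment: Alignment,
    correction: str = "none",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise p-distances (optionally Poisson-corrected) from an alignment.

    p = mismatches / compared columns; columns with a gap in either row of
    the pair are excluded (``deletion='pairwise'``), or columns with a gap
    in any row are excluded globally (``deletion='complete'``).  The
    Poisson correction d = -ln(1 - p) estimates substitutions per site.
    """
    if correction not in ("none", "poisson"):
        raise ParameterError(f"unknown correction {correction!r}")
    if deletion not in ("pairwise", "complete"):
        raise ParameterError(f"unknown deletion mode {deletion!r}")
    ids = alignment.ids
    rows = [alignment.row(i) for i in ids]
    length = alignment.length
    if deletion == "complete":
        keep = [j for j in range(length) if all(r[j] != GAP for r in rows)]
        rows = ["".join(r[j] for j in keep) for r in rows]
        length = len(keep)
    n = len(ids)
    mat = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        ra, rb = rows[a], rows[b]
        compared = mismatch = 0
        for j in range(length):
            if ra[j] == GAP or rb[j] == GAP:
                continue
            compared += 1
            if ra[j] != rb[j]:
                mismatch += 1
        if compared == 0:
            raise AlignmentError(f"no comparable columns between {ids[a]!r} and {ids[b]!r}")
        p = mismatch / compared
        if correction == "poisson":
            if p >= 1.0:
                raise AlignmentError(f"p-distance 1.0 between {ids[a]!r} and {ids[b]!r}: Poisson correction undefined")
            d = -math.log(1.0 - p)
        else:
            d = p
        mat[a, b] = mat[b, a] = d
    return DistanceMatrix(mat, ids=list(ids))


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (>= 3 taxa).

    Standard NJ (Q-criterion, Studier-Keppler branch lengths) via
    scikit-bio; the matrix is label-sorted first so tie-breaking is
    deterministic and label-order independent.  Negative branch-length
    estimates are clamped to zero with a warning.
    """
    if len(matrix.ids) < 3:
        raise ParameterError("nj_tree needs at least 3 taxa")
    order = sorted(matrix.ids)
    matrix = matrix.filter(order)
    tree = nj(matrix, neg_as_zero=False)
    clamped = []
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped.append(node.name or "<internal>")
            node.length = 0.0
    if clamped:
        logger.warning("negative NJ branch lengths clamped to 0 for: %s", clamped)
    return tree


def _adjacency(tree: TreeNode) -> tuple[dict, dict]:
    """Undirected weighted adjacency over the tree's nodes.

    Zero-length (or None-length) root edges collapse naturally because the
    root carries no length; returns (adjacency, leaf-name -> node map).
    """
    adj: dict[TreeNode, list[tuple[TreeNode, float]]] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(node, [])
        for child in node.children:
            w = float(child.length or 0.0)
            adj[node].append((child, w))
            adj.setdefault(child, []).append((node, w))
    leaves = {t.name: t for t in tree.tips()}
    return adj, leaves


def _leaf_distances(adj: dict, start) -> dict:
    dist = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    The two diameter endpoints end up equidistant from the root.  Ties
    between equal-length diameters are broken by the lexicographically
    smallest (sorted) endpoint label pair.  If every branch length is zero
    the tree is rooted at an internal node arbitrarily, with a warning.
    """
    tree = tree.copy()
    adj, leaves = _adjacency(tree)
    names = sorted(leaves)
    if len(names) < 2:
        raise ParameterError("midpoint rooting needs at least 2 leaves")
    best: tuple[float, tuple[str, str]] | None = None
    dists = {}
    for a in names:
        dists[a] = _leaf_distances(adj, leaves[a])
    for a, b in itertools.combinations(names, 2):
        d = dists[a][leaves[b]]
        key = tuple(sorted((a, b)))
        if best is None or d > best[0] + 1e-15 or (abs(d - best[0]) <= 1e-15 and key < best[1]):
            best = (d, key)
    diameter, (end_a, end_b) = best
    if diameter <= 0:
        logger.warning("all branch lengths are zero; rooting at an arbitrary internal node")
        internal = next(n for n in adj if n.children)
        rooted = tree.root_at(internal)
        return rooted

    # walk the a->b path and find the edge containing the midpoint
    da = dists[end_a]
    path = [leaves[end_b]]
    while path[-1] is not leaves[end_a]:
        u = path[-1]
        # predecessor on the shortest (unique) path back to end_a
        pred = min(
            (v for v, w in adj[u] if abs(da[v] + w - da[u]) <= 1e-12),
            key=lambda v: da[v],
        )
        path.append(pred)
    path.reverse()  # end_a ... end_b
    half = diameter / 2.0
    for u, v in zip(path, path[1:]):
        if da[v] >= half - 1e-15:
            # midpoint lies on edge (u, v), at (half - da[u]) from u
            child = u if u.parent is v else v
            dist_from_child = (half - da[u]) if child is u else (da[v] - half)
            return _root_on_edge(tree, child, dist_from_child)
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


def _root_on_edge(tree: TreeNode, child: TreeNode, dist_from_child: float) -> TreeNode:
    """Insert a new root on the edge above ``child``, ``dist_from_child`` up from it."""
    edge_len = float(child.length or 0.0)
    dist_from_child = min(max(dist_from_child, 0.0), edge_len)
    parent = child.parent
    new_node = TreeNode(name=None, length=edge_len - dist_from_child)
    parent.remove(child)
    parent.append(new_node)
    child.length = dist_from_child
    new_node.append(child)
    rooted = tree.root_at(new_node)
    # root_at leaves the old attachment as a unifurcation through new_node's
    # former parent; skbio handles that internally, but ensure the root
    # itself is clean and lengthless.
    rooted.length = None
    return rooted


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string (branch lengths kept, labels quoted as needed)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string."""
    return TreeNode.read(io.StringIO(text), format="newick")
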