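"""Distance trees, bootstrap supports, and dual-tree clade delineation.

Maximum-likelihood reconstruction is consumed, not computed: trees from
any external tool can be read from newick (supports as internal node
labels).  The built-in neighbor-joining builder plus classical
Felsenstein column-resampling bootstrap exists so the clade rule can be
exercised end-to-end on synthetic alignments.

The clade rule: a leaf set is a clade when it appears as a supported
bipartition side in *both* trees, with at least ``min_members`` members
and at least ``min_support`` percent bootstrap support in each tree;
only maximal such sets are reported, so the result is disjoint.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "Clade",
    "nj_tree",
    "p_distance_matrix",
    "bootstrap_supports",
    "supported_sides",
    "delineate_clades",
    "sister_group_labels",
    "read_support_tree",
    "write_support_tree",
]


@dataclass
class Clade:
    id: str
    members: frozenset[str]
    support_a: float
    support_b: float


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


def nj_tree(
    distances: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None
) -> TreeNode:
    """Neighbor-joining tree from a symmetric, zero-diagonal matrix."""
    if not isinstance(distances, DistanceMatrix):
        arr = np.asarray(distances, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if ids is None:
            ids = [f"t{i}" for i in range(arr.shape[0])]
        distances = DistanceMatrix(arr, list(ids))
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(distances)
    for node in tree.traverse():
        if not node.is_tip():
            node.support = None
    return tree


def p_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise proportion-of-differing-columns distances."""
    labels = sorted(alignment)
    mat = _alignment_array(alignment, labels)
    return DistanceMatrix(_pdist_from_array(mat), labels)


def _alignment_array(alignment: Mapping[str, str], labels: Sequence[str]) -> np.ndarray:
    lens = {len(alignment[x]) for x in labels}
    if len(lens) != 1:
        raise ValueError("alignment rows must have equal length")
    return np.array(
        [np.frombuffer(alignment[x].encode(), dtype=np.uint8) for x in labels]
    )


def _pdist_from_array(mat: np.ndarray) -> np.ndarray:
    diff = (mat[:, None, :] != mat[None, :, :]).mean(axis=2)
    np.fill_diagonal(diff, 0.0)
    return diff


def _canonical(side: frozenset, all_leaves: frozenset, ref: str) -> frozenset:
    """Key a bipartition by the side not containing the reference leaf."""
    return frozenset(all_leaves - side) if ref in side else side


def bootstrap_supports(
    alignment: Mapping[str, str],
    tree_builder: Callable[[DistanceMatrix], TreeNode] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Tree from the full alignment with column-resampling bootstrap
    supports (percent of replicates containing the same bipartition) on
    internal nodes.  ``n_reps`` = 0 leaves supports absent."""
    builder = tree_builder or nj_tree
    labels = sorted(alignment)
    mat = _alignment_array(alignment, labels)
    if mat.shape[1] < 1:
        raise ValueError("alignment needs at least one column")
    main = builder(DistanceMatrix(_pdist_from_array(mat), labels))
    if n_reps == 0:
        return main

    all_leaves = frozenset(labels)
    ref = min(labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = builder(DistanceMatrix(_pdist_from_array(mat[:, cols]), labels))
        for node in rep.non_tips():
            key = _canonical(frozenset(node.subset()), all_leaves, ref)
            if 0 < len(key) < len(labels):
                counts[key] = counts.get(key, 0) + 1

    for node in main.non_tips(include_self=False):
        key = _canonical(frozenset(node.subset()), all_leaves, ref)
        node.support = 100.0 * counts.get(key, 0) / n_reps
    return main


def supported_sides(
    tree: TreeNode, min_support: float, outgroup: str | None = None
) -> dict[frozenset, float]:
    """Supported clade-side leaf sets of a tree.

    For each internal edge with support >= ``min_support``, the clade
    side is the side not containing ``outgroup`` when given, otherwise
    the minority side of the bipartition (ties broken lexicographically).
    """
    leaves = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is None or support < min_support:
            continue
        side = frozenset(node.subset())
        comp = leaves - side
        if not side or not comp:
            continue
        if outgroup is not None:
            chosen = comp if outgroup in side else side
        elif len(side) != len(comp):
            chosen = side if len(side) < len(comp) else comp
        else:
            chosen = min(side, comp, key=lambda s: sorted(s))
        prev = out.get(chosen)
        if prev is None or support > prev:
            out[chosen] = float(support)
    return out


def delineate_clades(
    tree_a: TreeNode,
    tree_b: TreeNode,
    min_support: float = 90.0,
    min_members: int = 3,
    outgroup: str | None = None,
) -> list[Clade]:
    """Maximal leaf sets supported as clades in both trees.

    Both trees must share the same leaf set.  Reported clades are
    pairwise disjoint; when two non-nested candidates overlap (possible
    across two trees, never within one), neither is reported and a
    warning is emitted.
    """
    leaves_a = frozenset(t.name for t in tree_a.tips())
    leaves_b = frozenset(t.name for t in tree_b.tips())
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    sides_a = supported_sides(tree_a, min_support, outgroup)
    sides_b = supported_sides(tree_b, min_support, outgroup)
    common = [
        s for s in sides_a if s in sides_b and len(s) >= min_members
    ]
    common.sort(key=lambda s: (-len(s), sorted(s)))
    kept: list[frozenset] = []
    dropped: set[frozenset] = set()
    for s in common:
        if any(s <= k for k in kept):
            continue
        crossing = [k for k in kept if (s & k) and not (s <= k)]
        if crossing:
            warnings.warn(
                "overlapping non-nested clade candidates across trees; "
                "reporting neither"
            )
            dropped.update(crossing)
            dropped.add(s)
            continue
        kept.append(s)
    kept = [k for k in kept if k not in dropped]
    kept.sort(key=lambda s: sorted(s))
    return [
        Clade(
            id=_roman(i + 1), members=s,
            support_a=sides_a[s], support_b=sides_b[s],
        )
        for i, s in enumerate(kept)
    ]


def sister_group_labels(
    tree: TreeNode, query: Sequence[str], label_map: Mapping[str, str]
) -> tuple[dict[str, int], bool]:
    """Taxonomy labels of the sister group of the smallest clade
    containing ``query``; also reports whether the query is monophyletic.

    Returns a label -> count multiset.  If the containing clade is the
    whole (rooted) tree, the sister multiset is empty.
    """
    names = set(query)
    lca = tree.lca([t for t in tree.tips() if t.name in names])
    in_clade = set(t.name for t in lca.tips()) if not lca.is_tip() else {lca.name}
    mono = in_clade == names
    parent = lca.parent
    labels: dict[str, int] = {}
    if parent is not None:
        for child in parent.children:
            if child is lca:
                continue
            tips = [child] if child.is_tip() else list(child.tips())
            for t in tips:
                lab = label_map.get(t.name, "unknown")
                labels[lab] = labels.get(lab, 0) + 1
    return labels, mono


# ---------------------------------------------------------------------------
# newick I/O with supports as internal node labels


def read_support_tree(source) -> TreeNode:
    """Read newick; internal node labels are parsed as bootstrap supports.

    Values in [0, 1] are auto-scaled to percent with a warning (both
    dialects occur in the wild).
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    tree = TreeNode.read(source, convert_underscores=False)
    tree.assign_supports()
    vals = [
        node.support
        for node in tree.non_tips(include_self=True)
        if node.support is not None
    ]
    if vals and max(vals) <= 1.0:
        warnings.warn("supports in [0, 1]; scaling to percent")
        for node in tree.non_tips(include_self=True):
            if node.support is not None:
                node.support = 100.0 * node.support
    else:
        for node in tree.non_tips(include_self=True):
            if node.support is not None:
                node.support = float(node.support)
    return tree


def write_support_tree(tree: TreeNode, handle) -> None:
    """Write newick with supports as internal node labels (the skbio
    writer emits ``node.support`` in the label position)."""
    tree.write(handle)
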