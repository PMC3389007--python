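"""Tree construction and handling: NJ, UPGMA, bootstrap, Newick, node ages.

Trees are held as :class:`dendropy.Tree` objects.  This module adds the
conventions the delimitation pipeline relies on:

* neighbor-joining and UPGMA built from a :class:`DistanceMatrix` with
  deterministic tie-breaking (lowest row/column index) and negative branch
  estimates clamped to zero,
* nonparametric bootstrap over alignment columns with bipartition-based
  support annotation on a reference tree,
* ultrametricity checking (relative tolerance 1e-6 of tree height) and
  extraction of node ages / branching times for the GMYC model.

Supports are stored on nodes as proportions in [0, 1]; Newick percentage
supports (values > 1) are auto-detected and rescaled on parse.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .io_formats import Alignment
from .subst_models import (
    DistanceMatrix,
    SubstitutionModel,
    _ml_distance_from_counts,
    _pair_counts,
    encode_alignment,
    p_distance_matrix,
)

__all__ = [
    "Clade",
    "parse_newick",
    "write_newick",
    "neighbor_joining",
    "upgma",
    "bootstrap_support",
    "well_supported_clades",
    "branching_times",
    "node_ages",
    "is_ultrametric",
    "midpoint_root",
    "leaf_labels",
    "UltrametricityError",
]

logger = logging.getLogger(__name__)

#: relative tolerance (fraction of tree height) for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6


class UltrametricityError(ValueError):
    """Raised when a tree that must be ultrametric is not."""


@dataclass(frozen=True)
class Clade:
    """A supported clade: its tip labels, bootstrap support and node handle."""

    labels: frozenset
    support: float
    node: dendropy.Node = None

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("clade must contain at least one tip")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support must be in [0, 1], got {self.support}")

    @property
    def size(self) -> int:
        return len(self.labels)


def leaf_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Newick I/O

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; internal-node labels are read as supports.

    Numeric internal labels become node ``support`` values; values above 1
    are taken to be percentages and divided by 100.
    """
    from dendropy.dataio.newickreader import NewickReader

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    supports = []
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                supports.append((node, float(node.label)))
            except ValueError:
                pass
    if supports:
        scale = 100.0 if max(v for _, v in supports) > 1.0 else 1.0
        for node, value in supports:
            node.support = value / scale
    tree.is_rooted = len(tree.seed_node.child_nodes()) == 2
    return tree


def _format_length(x: float | None) -> str:
    return "" if x is None else f":{x:.10g}"


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise with supports as internal labels and 10-significant-digit lengths."""

    def fmt(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label + _format_length(node.edge.length)
        inner = ",".join(fmt(c) for c in node.child_nodes())
        support = getattr(node, "support", None)
        label = f"{support:.10g}" if support is not None else (node.label or "")
        length = _format_length(node.edge.length) if node.parent_node is not None else ""
        return f"({inner}){label}{length}"

    return fmt(tree.seed_node) + ";"


# ---------------------------------------------------------------------------
# node ages / ultrametricity

def node_ages(
    tree: dendropy.Tree, require_ultrametric: bool = True, rtol: float = ULTRAMETRIC_RTOL
) -> dict[dendropy.Node, float]:
    """Ages (time before present, tips at 0) derived from root-to-node paths.

    Raises :class:`UltrametricityError` when tip depths differ by more than
    ``rtol`` of the tree height and ``require_ultrametric`` is set.
    """
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        length = node.edge.length or 0.0
        depth[node] = (depth[parent] if parent is not None else 0.0) + (
            length if parent is not None else 0.0
        )
    height = max(depth.values())
    if height <= 0:
        raise ValueError("tree has zero height")
    tip_depths = [depth[leaf] for leaf in tree.leaf_node_iter()]
    spread = max(tip_depths) - min(tip_depths)
    if require_ultrametric and spread > rtol * height:
        raise UltrametricityError(
            f"tree is not ultrametric: tip depths spread {spread:g} exceeds "
            f"{rtol:g} of height {height:g}; supply a chronogram or build one "
            "with upgma() on model-corrected distances"
        )
    ages = {}
    for node, d in depth.items():
        age = height - d
        if node.is_leaf():
            age = 0.0
        ages[node] = max(age, 0.0)
        node.age = ages[node]
    return ages


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    try:
        node_ages(tree, require_ultrametric=True, rtol=rtol)
    except UltrametricityError:
        return False
    return True


def branching_times(tree: dendropy.Tree) -> np.ndarray:
    """Internal-node ages sorted descending (root first); ties preserved."""
    if not tree.is_rooted:
        raise ValueError("branching times require a rooted tree")
    ages = node_ages(tree, require_ultrametric=True)
    internal = [a for n, a in ages.items() if not n.is_leaf()]
    return np.array(sorted(internal, reverse=True))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-rooted copy of *tree* (supports carried through re-parse)."""
    copy = parse_newick(write_newick(tree))
    copy.reroot_at_midpoint(update_bipartitions=False)
    copy.is_rooted = True
    return copy


# ---------------------------------------------------------------------------
# agglomerative builders

def _leaf_nodes(labels: Sequence[str], tns: dendropy.TaxonNamespace) -> list[dendropy.Node]:
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        node.support = None
        nodes.append(node)
    return nodes


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamping negative %s branch length %g to 0", context, length)
        return 0.0
    return length


def _argmin_pair(M: np.ndarray) -> tuple[int, int]:
    """Index pair of the minimum, lowest (row, col) first on ties."""
    flat = int(np.argmin(M))
    return divmod(flat, M.shape[1])


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical NJ agglomeration; unrooted, deterministic, negatives clamped."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(dm.labels, tns)
    D = dm.values.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_pair(Q)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(li, "NJ")
        nodes[j].edge.length = _clamp(lj, "NJ")
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
    # final trifurcation: solve the three pairwise equations
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    center = dendropy.Node()
    center.support = None
    for node, length in ((a, (dab + dac - dbc) / 2), (b, (dab + dbc - dac) / 2), (c, (dac + dbc - dab) / 2)):
        center.add_child(node)
        node.edge.length = _clamp(length, "NJ")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage clustering; rooted and ultrametric, ages = half merge distance."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    tns = dendropy.TaxonNamespace()
    nodes = _leaf_nodes(dm.labels, tns)
    for node in nodes:
        node.age = 0.0
    sizes = np.ones(n)
    D = dm.values.copy()
    while len(nodes) > 1:
        M = D.copy()
        np.fill_diagonal(M, np.inf)
        i, j = _argmin_pair(M)
        if i > j:
            i, j = j, i
        age = D[i, j] / 2.0
        parent = dendropy.Node()
        parent.support = None
        parent.age = age
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _clamp(age - nodes[i].age, "UPGMA")
        nodes[j].edge.length = _clamp(age - nodes[j].age, "UPGMA")
        si, sj = sizes[i], sizes[j]
        d_new = (si * D[i] + sj * D[j]) / (si + sj)
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        sizes = np.append(sizes[keep], si + sj)
        nodes = [nodes[k] for k in keep] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# bootstrap

def _node_leafset(node: dendropy.Node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _bipartition_keys(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Nontrivial bipartitions keyed by the side excluding the reference tip.

    The key is invariant under re-rooting: each internal edge maps to the
    leaf-label set on the side of the edge that does not contain the
    lexicographically smallest tip.
    """
    all_labels = frozenset(leaf_labels(tree))
    ref = min(all_labels)
    keys: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = _node_leafset(node)
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            keys.setdefault(side, node)
    return keys


def bootstrap_support(
    aln: Alignment,
    method: str,
    model: SubstitutionModel | None,
    replicates: int,
    seed: int,
    reference: dendropy.Tree,
) -> dendropy.Tree:
    """Annotate *reference* internal edges with column-bootstrap NJ support.

    Columns are resampled with replacement (seeded and reproducible), an NJ
    tree is rebuilt per replicate, and each internal edge of the reference is
    given the proportion of replicates containing the same bipartition.  The
    reference tree is annotated in place and returned.
    """
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    if aln.length < 2:
        raise ValueError("alignment too short to bootstrap (need >= 2 columns)")
    ref_labels = set(leaf_labels(reference))
    if ref_labels != set(aln.labels):
        raise ValueError("reference tree tips do not match alignment labels")
    enc = encode_alignment(aln)
    rng = np.random.default_rng(seed)
    ref_keys = _bipartition_keys(reference)
    counts = dict.fromkeys(ref_keys, 0)
    for _ in range(replicates):
        cols = rng.integers(0, aln.length, aln.length)
        sub = enc[:, cols]
        if method == "p":
            values = p_distance_matrix(sub)
        elif method == "model":
            if model is None:
                raise ValueError("method 'model' requires a SubstitutionModel")
            n = len(sub)
            values = np.zeros((n, n))
            for a in range(n):
                for b in range(a + 1, n):
                    pc = _pair_counts(sub[a], sub[b])
                    values[a, b] = values[b, a] = _ml_distance_from_counts(model, pc).distance
        else:
            raise ValueError(f"unknown distance method {method!r}")
        rep_tree = neighbor_joining(DistanceMatrix(aln.labels, values))
        for key in _bipartition_keys(rep_tree):
            if key in counts:
                counts[key] += 1
    for node in reference.preorder_node_iter():
        node.support = None
    for key, node in ref_keys.items():
        node.support = counts[key] / replicates
    return reference


def well_supported_clades(tree: dendropy.Tree, threshold: float = 0.90) -> list[Clade]:
    """All internal clades with support >= *threshold*, largest first.

    Tips are trivially excluded; nested clades are all returned.  Raises if
    the tree carries no support values at all.
    """
    supported_nodes = [
        node
        for node in tree.preorder_node_iter()
        if not node.is_leaf()
        and node.parent_node is not None
        and getattr(node, "support", None) is not None
    ]
    if not supported_nodes:
        raise ValueError("tree has no bootstrap supports; run bootstrap_support first")
    clades = [
        Clade(_node_leafset(node), node.support, node)
        for node in supported_nodes
        if node.support >= threshold
    ]
    clades.sort(key=lambda c: (-c.size, sorted(c.labels)))
    return clades
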