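"""Distance-based phylogenetics: NJ, bootstrap, rooting, clade tests, Fitch.

Distances come from an MSA under pairwise deletion (columns where either
row is gapped are skipped for that pair) with either the raw proportion of
differing sites (p-distance) or its Poisson multiple-hit correction
−ln(1−p). Trees are built by Saitou–Nei neighbor joining with the
Studier–Keppler Q criterion and held as :class:`dendropy.Tree` objects, so
Newick round-tripping, midpoint rooting and clade queries ride on a
standard toolkit. Bootstrap supports are column-resampling percentages
annotated on the point-estimate tree. Fitch parsimony counts the minimum
number of unordered state changes of a leaf character (here: the second
triad residue) on the tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import dendropy
import numpy as np

from .align import MultipleAlignment

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered label list."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhyloError("distance matrix has a nonzero diagonal")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < -1e-12):
            raise PhyloError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(msa: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from an MSA under pairwise deletion.

    ``model`` is ``"p_distance"`` (proportion of differing comparable
    columns) or ``"poisson"`` (−ln(1−p)). A pair with no comparable
    columns, or with p = 1 under the Poisson model, is an error (listing
    the offending pairs).
    """
    if model not in ("p_distance", "poisson"):
        raise PhyloError(f"unknown distance model {model!r}")
    n = len(msa.ids)
    if n < 3:
        raise PhyloError("need at least 3 sequences for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    gaps = arr == "-"
    d = np.zeros((n, n))
    bad_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~gaps[i] & ~gaps[j]
            total = int(usable.sum())
            if total == 0:
                bad_pairs.append((msa.ids[i], msa.ids[j]))
                continue
            p = float((arr[i][usable] != arr[j][usable]).sum()) / total
            if model == "p_distance":
                dist = p
            else:
                if p >= 1.0:
                    bad_pairs.append((msa.ids[i], msa.ids[j]))
                    continue
                dist = -np.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    if bad_pairs:
        raise PhyloError(f"degenerate distance for pairs: {bad_pairs}")
    return DistanceMatrix(labels=list(msa.ids), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class NJResult:
    tree: dendropy.Tree
    negative_branches_clamped: int = 0


def _new_taxon_namespace(labels: Sequence[str]) -> dendropy.TaxonNamespace:
    return dendropy.TaxonNamespace(list(labels))


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining (Studier–Keppler Q criterion).

    Ties in Q are broken by the lowest (i, j) index pair, so the output is
    deterministic. Negative branch-length estimates are clamped to zero;
    the number of clamped branches is recorded in the tree annotation
    ``negative_branches_clamped``. The returned tree is unrooted with a
    trifurcating seed node.
    """
    n = len(dm)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    tns = _new_taxon_namespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    d = dm.d.copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: first minimum in row-major order
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        vi = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        vj = dij - vi
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(vi)
        nj_.edge.length = clamp(vj)
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0])
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # join the last three nodes at the unrooted seed
    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    seed = tree.seed_node
    for idx, v in ((a, va), (b, vb), (c, vc)):
        seed.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(v)
    tree.is_rooted = False
    tree.annotations.add_new("negative_branches_clamped", clamped)
    if clamped:
        logger.warning("clamped %d negative NJ branch length(s) to 0", clamped)
    return tree


# ---------------------------------------------------------------------------
# Bipartitions & bootstrap
# ---------------------------------------------------------------------------

def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, side-normalised.

    Each internal edge splits the leaves in two; the side not containing
    the lexicographically smallest leaf label is used as the canonical
    representative, so bipartition sets from differently rooted copies of
    the same topology compare equal.
    """
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    bips: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else all_leaves - below
        if 1 < len(side) < len(leaves) - 1:
            bips.add(side)
    return bips


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted topological identity via canonical bipartition sets."""
    return leaf_bipartitions(t1) == leaf_bipartitions(t2)


def _resample_msa(msa: MultipleAlignment, rng: np.random.Generator) -> MultipleAlignment:
    ncol = msa.ncol
    cols = rng.integers(0, ncol, size=ncol)
    rows = ["".join(row[c] for c in cols) for row in msa.rows]
    return MultipleAlignment(ids=list(msa.ids), rows=rows)


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
    tree_builder: Callable[[DistanceMatrix], dendropy.Tree] = nj_tree,
) -> dendropy.Tree:
    """Point-estimate tree with column-resampling bootstrap supports.

    MSA columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition,
    annotated as the internal node label. Replicates whose distance matrix
    is degenerate are skipped with a warning and the denominator adjusted.
    Fully reproducible given ``seed``.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    point = tree_builder(distance_matrix(msa, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {b: 0 for b in leaf_bipartitions(point)}
    used = 0
    for _ in range(n_reps):
        rep_msa = _resample_msa(msa, rng)
        try:
            rep_tree = tree_builder(distance_matrix(rep_msa, model))
        except PhyloError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        used += 1
        rep_bips = leaf_bipartitions(rep_tree)
        for b in counts:
            if b in rep_bips:
                counts[b] += 1
    leaves = sorted(l.taxon.label for l in point.leaf_node_iter())
    ref, all_leaves = leaves[0], frozenset(leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if ref not in below else all_leaves - below
        if side in counts and used > 0:
            node.label = f"{100.0 * counts[side] / used:.0f}"
    point.annotations.add_new("bootstrap_replicates_used", used)
    return point


# ---------------------------------------------------------------------------
# Rooting and clade queries
# ---------------------------------------------------------------------------

def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of its longest leaf-to-leaf path."""
    rooted = tree.clone(depth=1)
    total = sum(e.length or 0.0 for e in rooted.preorder_edge_iter())
    if total == 0.0:
        warnings.warn("zero-length tree: rooting on an arbitrary edge")
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def is_monophyletic(tree: dendropy.Tree, leaf_set: set[str], root_first: bool = True) -> bool:
    """Whether some node's leaf descendants equal ``leaf_set`` exactly.

    Evaluated on the midpoint-rooted tree by default (set
    ``root_first=False`` if the tree is already rooted as desired).
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(leaf_set) - leaves
    if unknown:
        raise PhyloError(f"unknown leaf ids: {sorted(unknown)}")
    if not leaf_set:
        raise PhyloError("empty leaf set")
    work = midpoint_root(tree) if root_first and not tree.is_rooted else tree
    target = frozenset(leaf_set)
    if len(target) == 1 or target == frozenset(leaves):
        return True
    for node in work.preorder_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == target:
            return True
    return False


def mrca_leafset(tree: dendropy.Tree, leaf_set: set[str]) -> frozenset[str]:
    """Leaf labels under the MRCA of ``leaf_set`` (tree must be rooted)."""
    node = tree.mrca(taxon_labels=list(leaf_set))
    if node is None:
        raise PhyloError(f"no MRCA found for {sorted(leaf_set)}")
    return frozenset(l.taxon.label for l in node.leaf_iter())


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_changes(tree: dendropy.Tree, chars: Mapping[str, str]) -> int:
    """Minimum number of unordered state changes of a leaf character.

    Standard Fitch bottom-up pass; at a multifurcation child sets are
    folded pairwise left-to-right, which for the trifurcating seed of an
    unrooted binary tree equals rooting along the first child edge (the
    count is rooting-invariant). Raises if any leaf lacks a state.
    """
    missing = [l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label not in chars]
    if missing:
        raise PhyloError(f"missing character states for leaves: {missing}")
    changes = 0

    def visit(node) -> frozenset[str]:
        nonlocal changes
        if node.is_leaf():
            return frozenset({chars[node.taxon.label]})
        child_sets = [visit(c) for c in node.child_nodes()]
        acc = child_sets[0]
        for s in child_sets[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        return acc

    visit(tree.seed_node)
    return changes


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=False,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
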