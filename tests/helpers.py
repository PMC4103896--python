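"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and direct
counting — and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Alignment enumeration
# ---------------------------------------------------------------------------

def score_alignment(row_a: str, row_b: str, pair_score, gap_open: float,
                    gap_extend: float) -> float:
    """Score a gapped alignment; a gap run of length L costs open+(L-1)*extend."""
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            total -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            total -= gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += pair_score(x, y)
            in_gap_a = in_gap_b = False
    return total


def enumerate_alignments(a: str, b: str):
    """All global alignments (no gap/gap columns) as (row_a, row_b) pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def best_global_score(a: str, b: str, pair_score, gap_open: float,
                      gap_extend: float) -> float:
    return max(
        score_alignment(ra, rb, pair_score, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def best_local_score(a: str, b: str, pair_score, gap_open: float,
                     gap_extend: float) -> float:
    """Best score over all substring pairs; 0 if nothing positive exists."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    s = best_global_score(a[i:j], b[k:l], pair_score,
                                          gap_open, gap_extend)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# Fitch parsimony by exhaustive internal-state assignment
# ---------------------------------------------------------------------------

def exhaustive_parsimony(tree, chars: dict[str, str]) -> int:
    """Minimum state changes over all internal-node assignments (dendropy tree)."""
    states = sorted(set(chars.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for assignment in itertools.product(states, repeat=len(internals)):
        state_of = {id(n): s for n, s in zip(internals, assignment)}
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = chars[node.taxon.label] if node.is_leaf() else state_of[id(node)]
            if s != state_of[id(node.parent_node)]:
                changes += 1
        best = min(best, changes)
    return int(best)


# ---------------------------------------------------------------------------
# 5-leaf topology least squares
# ---------------------------------------------------------------------------

def five_leaf_topologies(labels):
    """All 15 unrooted binary topologies on 5 labels as (pair, pair, single)."""
    labels = list(labels)
    out = []
    for single in labels:
        rest = [x for x in labels if x != single]
        a = rest[0]
        for partner in rest[1:]:
            pair1 = (a, partner)
            pair2 = tuple(x for x in rest[1:] if x != partner)
            out.append((pair1, pair2, single))
    return out


def topology_lstsq_residual(topology, labels, dmat) -> float:
    """Least-squares residual of fitting branch lengths to the distances.

    Topology ((a,b),(c,d),e): 7 edges — 5 pendant + 2 internal (pair1 stem,
    pair2 stem); the single leaf hangs off the central node.
    """
    (a, b), (c, d), e = topology
    idx = {lab: i for i, lab in enumerate(labels)}
    # edge order: pa, pb, pc, pd, pe, s1 (pair1 stem), s2 (pair2 stem)
    def path(x, y):
        row = np.zeros(7)
        pend = {a: 0, b: 1, c: 2, d: 3, e: 4}
        row[pend[x]] = 1
        row[pend[y]] = 1
        in1 = {a, b}
        in2 = {c, d}
        gx = 1 if x in in1 else (2 if x in in2 else 0)
        gy = 1 if y in in1 else (2 if y in in2 else 0)
        if gx != gy:
            if 1 in (gx, gy):
                row[5] = 1
            if 2 in (gx, gy):
                row[6] = 1
        return row

    pairs = list(itertools.combinations([a, b, c, d, e], 2))
    A = np.array([path(x, y) for x, y in pairs])
    y = np.array([dmat[idx[x], idx[y]] for x, y in pairs])
    _, residual, *_ = np.linalg.lstsq(A, y, rcond=None)
    if residual.size == 0:
        fit = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        return float(np.sum((fit - y) ** 2))
    return float(residual[0])


# ---------------------------------------------------------------------------
# Midpoint by exhaustive edge search
# ---------------------------------------------------------------------------

def brute_force_midpoint_height(tree) -> float:
    """Half the tree diameter = optimal max root-to-leaf distance."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    diameter = max(
        pdm.distance(t1, t2) for t1, t2 in itertools.combinations(taxa, 2)
    )
    return diameter / 2.0


def max_root_leaf_distance(tree) -> float:
    best = 0.0
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        best = max(best, d)
    return best
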