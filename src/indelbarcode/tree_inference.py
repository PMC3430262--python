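"""Neighbor-joining on p-distances with nonparametric bootstrap support.

Classical NJ (Saitou & Nei agglomeration on the Q criterion) with a
deterministic tie-break: among equal-Q pairs the lowest (row, column) index
pair in current input order is joined.  Negative limb lengths are clamped to
zero with the deficit transferred to the sibling limb, preserving the joined
pair's distance.  Bootstrap resamples matrix characters — nucleotide columns
and coded indel characters as equal units — rebuilds NJ per replicate and
scores each internal edge of the original tree by the percentage of
replicate trees containing the same bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .distances import DistanceMatrix, PairRule, _p_distance_states, p_distance
from .errors import InferenceError

logger = logging.getLogger(__name__)


class Node:
    """Tree node; ``length`` is the branch above, ``support`` a bootstrap %."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class SupportTree:
    """Unrooted tree over individual ids with bootstrap supports on internal edges."""

    root: Node
    replicates: int = 0
    seed: int | None = None
    discarded_replicates: int = 0

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.root.leaves())

    def internal_edges(self) -> Iterator[tuple[Node, frozenset[str]]]:
        """Yield (child node, leafset below) for every internal edge.

        An edge is internal when both sides contain >=2 leaves.
        """
        n = len(self.leaf_names)

        def walk(node: Node):
            for child in node.children:
                below = frozenset(l.name for l in child.leaves())
                if 2 <= len(below) <= n - 2:
                    yield child, below
                yield from walk(child)

        yield from walk(self.root)

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Nontrivial splits as canonical frozenset pairs {sideA, sideB}."""
        all_leaves = frozenset(self.leaf_names)
        out = set()
        for _, below in self.internal_edges():
            out.add(frozenset({below, all_leaves - below}))
        return out

    def split_supports(self) -> dict[frozenset[frozenset[str]], float | None]:
        all_leaves = frozenset(self.leaf_names)
        return {
            frozenset({below, all_leaves - below}): node.support
            for node, below in self.internal_edges()
        }

    def to_newick(self) -> str:
        def render(node: Node, top: bool = False) -> str:
            if node.is_leaf:
                s = _quote_label(node.name)
            else:
                inner = ",".join(render(c) for c in node.children)
                label = ""
                if node.support is not None:
                    label = f"{node.support:g}"
                s = f"({inner}){label}"
            if not top and node.length is not None:
                s += f":{node.length:.6f}"
            return s

        return render(self.root, top=True) + ";"


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Classical NJ agglomeration; supports left unset.

    Exact on additive matrices; deterministic on ties (lowest index pair).
    """
    n = len(dm.ids)
    if n < 2:
        raise InferenceError("need >=2 sequences for tree inference")
    if not np.all(np.isfinite(dm.values)):
        raise InferenceError("distance matrix contains undefined entries")
    if n == 2:
        d = float(dm.values[0, 1])
        root = Node(
            children=[
                Node(name=dm.ids[0], length=d / 2),
                Node(name=dm.ids[1], length=d / 2),
            ]
        )
        return SupportTree(root=root)
    D = dm.values.astype(float).copy()
    nodes = [Node(name=sid) for sid in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum in row-major order = tie-break
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        new = Node(children=[a, b])
        dnew = 0.5 * (D[i] + D[j] - dij)
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        keep = [k for k in range(m) if k != j]
        drow = dnew[keep]
        D[i, :] = drow
        D[:, i] = drow
        D[i, i] = 0.0
        nodes.pop(j)
        nodes[i] = new
    # closed-form limb lengths for the final three nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    limbs = [
        max(0.0, (d01 + d02 - d12) / 2),
        max(0.0, (d01 + d12 - d02) / 2),
        max(0.0, (d02 + d12 - d01) / 2),
    ]
    for node, limb in zip(nodes, limbs):
        node.length = limb
    return SupportTree(root=Node(children=nodes))


def bipartitions(tree: SupportTree) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of a tree as canonical frozenset pairs."""
    return tree.bipartitions()


def _nj_splits(D: np.ndarray) -> set[frozenset[int]]:
    """Fast NJ returning only the nontrivial splits, as canonical index sets
    (the side not containing leaf 0). Shares the tie-break of
    :func:`neighbor_joining`."""
    n = D.shape[0]
    if n < 4:
        return set()
    D = D.astype(float).copy()
    sets: list[frozenset[int]] = [frozenset([k]) for k in range(n)]
    full = frozenset(range(n))
    splits: set[frozenset[int]] = set()

    def canon(s: frozenset[int]) -> frozenset[int]:
        return (full - s) if 0 in s else s

    while len(sets) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        merged = sets[i] | sets[j]
        if 2 <= len(merged) <= n - 2:
            splits.add(canon(merged))
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        keep = [k for k in range(m) if k != j]
        drow = dnew[keep]
        D[i, :] = drow
        D[:, i] = drow
        D[i, i] = 0.0
        sets.pop(j)
        sets[i] = merged
    return splits


def bootstrap_support(
    matrix,
    pair_rule: PairRule = "pairwise",
    replicates: int = 1000,
    seed: int | None = None,
    method: Literal["edge-frequency", "consensus"] = "edge-frequency",
) -> SupportTree:
    """NJ tree with bootstrap supports from character resampling.

    Characters (nucleotide columns and coded indel characters alike) are
    resampled with replacement; each replicate's NJ splits are tallied.
    Under ``edge-frequency`` the original-matrix NJ tree is returned with
    each internal edge scored by the percentage of valid replicates
    containing its bipartition; ``consensus`` returns the majority-rule
    consensus of the replicate trees instead.  Replicates in which some pair
    has no usable characters are discarded and logged; more than 10%
    discarded raises :class:`InferenceError`.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    dm = p_distance(matrix, pair_rule)
    base = neighbor_joining(dm)
    ids = tuple(matrix.ids)
    n = len(ids)
    full = frozenset(range(n))
    S = matrix.state_matrix()
    L = S.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[int], int] = {}
    valid_reps = 0
    discarded = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        values, usable = _p_distance_states(S[:, cols], pair_rule)
        off_diag = usable[np.triu_indices(n, k=1)]
        if (off_diag == 0).any():
            discarded += 1
            continue
        for sp in _nj_splits(values):
            counts[sp] = counts.get(sp, 0) + 1
    valid_reps = replicates - discarded
    if discarded:
        logger.info(
            "bootstrap: discarded %d/%d replicates with undefined distances",
            discarded,
            replicates,
        )
    if discarded > 0.1 * replicates:
        raise InferenceError(
            f"{discarded}/{replicates} bootstrap replicates had undefined "
            "pairwise distances (>10%)"
        )
    index_of = {sid: k for k, sid in enumerate(ids)}

    if method == "consensus":
        tree = _majority_rule_consensus(counts, ids, valid_reps)
    else:
        tree = base
        for node, below in tree.internal_edges():
            key = frozenset(index_of[x] for x in below)
            if 0 in key:
                key = full - key
            node.support = round(100.0 * counts.get(key, 0) / valid_reps, 1)
    tree.replicates = replicates
    tree.seed = seed
    tree.discarded_replicates = discarded
    return tree


def _majority_rule_consensus(
    counts: dict[frozenset[int], int], ids: tuple[str, ...], valid_reps: int
) -> SupportTree:
    """Build the >50% majority-rule consensus tree from split tallies.

    Splits above half frequency are pairwise compatible, so nesting them
    greedily (largest first) into a star tree is sound.
    """
    n = len(ids)
    majority = [
        (sp, c) for sp, c in counts.items() if c * 2 > valid_reps
    ]
    majority.sort(key=lambda t: (-len(t[0]), sorted(t[0])))
    leaf_nodes = [Node(name=sid, length=None) for sid in ids]
    root = Node(children=list(leaf_nodes))
    # node -> set of leaf indices below it
    below: dict[int, frozenset[int]] = {id(l): frozenset([k]) for k, l in enumerate(leaf_nodes)}
    below[id(root)] = frozenset(range(n))
    for sp, c in majority:
        # the split side not containing leaf 0 is a clade of the rooted-at-0 view
        side = sp if 0 not in sp else frozenset(range(n)) - sp
        # find the shallowest node whose leafset contains side
        host = root
        descended = True
        while descended:
            descended = False
            for child in host.children:
                if side <= below[id(child)] and not child.is_leaf:
                    host = child
                    descended = True
                    break
        moved = [ch for ch in host.children if below[id(ch)] <= side]
        if frozenset().union(*(below[id(ch)] for ch in moved)) != side:
            continue  # incompatible with an already-placed split (ties at 50%)
        for ch in moved:
            host.children.remove(ch)
        new = Node(children=moved, support=round(100.0 * c / valid_reps, 1))
        below[id(new)] = side
        host.children.append(new)
    return SupportTree(root=root)
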