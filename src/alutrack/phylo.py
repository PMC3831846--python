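"""Trees: neighbour joining, rooting, Fitch parsimony, clock test.

Distance trees are built with the classic neighbour-joining agglomeration
and rooted on an outgroup (typically the subfamily consensus sequence).
Ancestral states are reconstructed by Fitch parsimony, and rate
homogeneity is assessed with a likelihood-ratio test comparing a JC69
molecular-clock tree (tips equidistant from the root) against free branch
lengths, with the statistic referred to chi-square on n - 2 degrees of
freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "-": 16}
_BIT_ORDER = "ACGT-"  # ambiguity resolution order
_NUC = {"A": 0, "C": 1, "G": 2, "T": 3}


class LineageTree:
    """Rooted or unrooted tree with branch lengths and leaf labels.

    Nodes are integer ids; ``lengths[v]`` is the length of the edge from
    ``v`` to its parent (0 for the root). An unrooted tree is stored with
    a trifurcating anchor node and ``rooted == False``.
    """

    def __init__(self) -> None:
        self.parent: dict[int, int | None] = {}
        self.children: dict[int, list[int]] = {}
        self.lengths: dict[int, float] = {}
        self.labels: dict[int, str] = {}
        self.root: int | None = None
        self.rooted: bool = False
        self._next = 0

    def add_node(
        self, parent: int | None, length: float = 0.0, label: str | None = None
    ) -> int:
        nid = self._next
        self._next += 1
        self.parent[nid] = parent
        self.children[nid] = []
        self.lengths[nid] = length
        if parent is not None:
            self.children[parent].append(nid)
        if label is not None:
            self.labels[nid] = label
        return nid

    # -- queries ----------------------------------------------------------
    def leaves(self) -> list[int]:
        return [n for n in self.children if not self.children[n]]

    def leaf_labels(self) -> list[str]:
        return [self.labels[n] for n in self.leaves()]

    def leaf_by_label(self, label: str) -> int:
        for n in self.leaves():
            if self.labels.get(n) == label:
                return n
        raise KeyError(label)

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        return order[::-1]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(
            len(c) in (0, 2) for n, c in self.children.items() if n != self.root
        ) and len(self.children[self.root]) in (2, 3)

    # -- serialization -----------------------------------------------------
    def _newick_node(self, n: int) -> str:
        if not self.children[n]:
            body = self.labels.get(n, f"n{n}")
        else:
            body = "(" + ",".join(self._newick_node(c) for c in self.children[n]) + ")"
        if n == self.root:
            return body
        return f"{body}:{self.lengths[n]:.6f}"

    def newick(self) -> str:
        return self._newick_node(self.root) + ";"

    # -- structure helpers -------------------------------------------------
    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {n: [] for n in self.children}
        for n, p in self.parent.items():
            if p is not None:
                adj[n].append((p, self.lengths[n]))
                adj[p].append((n, self.lengths[n]))
        return adj

    def leaf_distances(self) -> tuple[list[str], np.ndarray]:
        """All pairwise leaf path lengths (labels, matrix)."""
        adj = self.adjacency()
        leaves = self.leaves()
        labels = [self.labels[n] for n in leaves]
        idx = {n: i for i, n in enumerate(leaves)}
        D = np.zeros((len(leaves), len(leaves)))
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for n, i in idx.items():
                D[idx[src], i] = dist[n]
        return labels, D

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf splits, for topology comparison."""
        all_leaves = frozenset(self.leaf_labels())
        parts: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if not self.children[n]:
                below[n] = frozenset([self.labels[n]])
            else:
                acc: frozenset[str] = frozenset()
                for c in self.children[n]:
                    acc |= below[c]
                below[n] = acc
        for n, part in below.items():
            if n == self.root:
                continue
            side = min(part, all_leaves - part, key=lambda s: (len(s), sorted(s)))
            if 2 <= len(side) <= len(all_leaves) - 2:
                parts.add(frozenset(side))
        return parts


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def build_nj_tree(dist: np.ndarray, labels: list[str]) -> LineageTree:
    """Neighbour-joining tree from a symmetric distance matrix (unrooted).

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of representative labels (for internal nodes, the smallest leaf
    label underneath), making the agglomeration deterministic. Negative
    branch lengths are clamped to zero with a warning.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix/label size mismatch")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distances must be >= 0 with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 taxa")

    tree = LineageTree()
    nodes = [tree.add_node(None, 0.0, lab) for lab in labels]
    reps = list(labels)  # representative label per active node

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                logger.warning("negative NJ branch length %.3g clamped to 0", x)
            return 0.0
        return x

    D = dist.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in ties
            if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = tree.add_node(None, 0.0)
        for child, ln in ((nodes[ai], clamp(li)), (nodes[aj], clamp(lj))):
            tree.parent[child] = parent
            tree.children[parent].append(child)
            tree.lengths[child] = ln
        nodes.append(parent)
        reps.append(min(reps[ai], reps[aj]))
        # distances from the new node
        new_idx = D.shape[0]
        drow = np.full(new_idx + 1, 0.0)
        for k_pos, ak in enumerate(active):
            if k_pos in (i, j):
                continue
            drow[ak] = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, : new_idx + 1] = drow
        D[: new_idx + 1, new_idx] = drow
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    center = tree.add_node(None, 0.0)
    if len(active) == 3:
        i, j, k = active
        la = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lb = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lc = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        pend = [la, lb, lc]
    else:  # 2 taxa
        i, j = active
        pend = [D[i, j] / 2, D[i, j] / 2]
    for a, ln in zip(active, pend):
        tree.parent[nodes[a]] = center
        tree.children[center].append(nodes[a])
        tree.lengths[nodes[a]] = clamp(ln)
    tree.root = center
    tree.rooted = False
    return tree


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: LineageTree, outgroup_label: str) -> LineageTree:
    """Root on the midpoint of the outgroup's pendant edge.

    All other adjacencies and path lengths are preserved; unary nodes
    produced by re-orientation are suppressed.
    """
    og = tree.leaf_by_label(outgroup_label)
    adj = tree.adjacency()
    if len(adj[og]) != 1:
        raise ValueError("outgroup must be a leaf")
    nbr, edge_len = adj[og][0]

    new = LineageTree()
    root = new.add_node(None, 0.0)
    new.add_node(root, edge_len / 2, tree.labels[og])

    def grow(old_node: int, came_from: int, parent_new: int, length: float) -> None:
        nbrs = [(v, w) for v, w in adj[old_node] if v != came_from]
        if not nbrs:  # leaf
            new.add_node(parent_new, length, tree.labels.get(old_node))
            return
        if len(nbrs) == 1:  # unary pass-through: merge edges
            v, w = nbrs[0]
            grow(v, old_node, parent_new, length + w)
            return
        nid = new.add_node(parent_new, length, tree.labels.get(old_node))
        for v, w in nbrs:
            grow(v, old_node, nid, w)

    grow(nbr, og, root, edge_len / 2)
    new.root = root
    new.rooted = True
    return new


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def fitch_ancestral(
    tree: LineageTree, leaf_states: dict[str, str]
) -> tuple[dict[int, str], int]:
    """Fitch ancestral reconstruction on a rooted binary tree.

    ``leaf_states`` maps leaf label to a state string over {A,C,G,T,-}.
    Returns per-node reconstructed state strings (ambiguities resolved
    deterministically in A < C < G < T < '-' order, preferring the parent's
    state when compatible) and the total parsimony length.
    """
    if not tree.rooted:
        raise ValueError("fitch_ancestral requires a rooted tree")
    leaves = tree.leaves()
    n_sites = len(next(iter(leaf_states.values())))
    masks: dict[int, np.ndarray] = {}
    length = 0
    for n in tree.postorder():
        if not tree.children[n]:
            label = tree.labels.get(n)
            if label not in leaf_states:
                raise ValueError(f"leaf {label!r} missing states")
            s = leaf_states[label]
            if len(s) != n_sites:
                raise ValueError("leaf state strings must have equal length")
            masks[n] = np.array([_BIT.get(c, 31) for c in s], dtype=np.uint8)
        else:
            c1, c2 = tree.children[n][0], tree.children[n][1]
            if len(tree.children[n]) != 2:
                raise ValueError("fitch_ancestral requires a binary tree")
            inter = masks[c1] & masks[c2]
            union = masks[c1] | masks[c2]
            empty = inter == 0
            length += int(empty.sum())
            masks[n] = np.where(empty, union, inter)

    lowest = np.zeros(32, dtype=np.uint8)
    for v in range(1, 32):
        lowest[v] = v & (~v + 1)  # lowest set bit
    bit_to_char = {1 << i: c for i, c in enumerate(_BIT_ORDER)}

    states: dict[int, str] = {}
    chosen: dict[int, np.ndarray] = {}
    for n in reversed(tree.postorder()):  # preorder
        p = tree.parent[n]
        if p is None:
            pick = lowest[masks[n]]
        else:
            keep = chosen[p] & masks[n]
            pick = np.where(keep > 0, keep, lowest[masks[n]])
        chosen[n] = pick.astype(np.uint8)
        states[n] = "".join(bit_to_char[int(b)] for b in pick)
    return states, length


# ---------------------------------------------------------------------------
# JC69 likelihood and the molecular-clock LRT
# ---------------------------------------------------------------------------

@dataclass
class ClockTestResult:
    lnL_clock: float
    lnL_noclock: float
    statistic: float
    df: int
    p_value: float


def _compress(alignment: dict[str, str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Site-pattern compression, excluding any column containing a gap/N."""
    labels = sorted(alignment)
    cols = np.array(
        [[_NUC.get(c, -1) for c in alignment[lab]] for lab in labels], dtype=np.int8
    )
    keep = (cols >= 0).all(axis=0)
    cols = cols[:, keep]
    if cols.shape[1] == 0:
        raise ValueError("no gap-free sites")
    patterns, counts = np.unique(cols, axis=1, return_counts=True)
    return labels, patterns, counts.astype(float)


def _jc_p(t: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    e = np.exp(-4.0 * np.asarray(t, dtype=float) / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


class _Pruner:
    """Felsenstein pruning for JC69 on a fixed rooted topology."""

    def __init__(self, tree: LineageTree, alignment: dict[str, str]) -> None:
        labels, patterns, counts = _compress(alignment)
        self.counts = counts
        self.npat = patterns.shape[1]
        self.order = tree.postorder()
        self.tree = tree
        self.leaf_part: dict[int, np.ndarray] = {}
        lab_idx = {lab: i for i, lab in enumerate(labels)}
        for n in tree.leaves():
            row = patterns[lab_idx[tree.labels[n]]]
            part = np.zeros((self.npat, 4))
            part[np.arange(self.npat), row] = 1.0
            self.leaf_part[n] = part
        # edges: every node except root has a branch to its parent
        self.edge_nodes = [n for n in self.order if tree.parent[n] is not None]
        self.edge_index = {n: i for i, n in enumerate(self.edge_nodes)}

    def loglik(self, lengths: np.ndarray) -> float:
        part: dict[int, np.ndarray] = {}
        for n in self.order:
            if not self.tree.children[n]:
                part[n] = self.leaf_part[n]
                continue
            acc = np.ones((self.npat, 4))
            for c in self.tree.children[n]:
                p0, p1 = _jc_p(lengths[self.edge_index[c]])
                lc = part[c]
                tot = lc.sum(axis=1, keepdims=True)
                acc = acc * (p1 * tot + (p0 - p1) * lc)
            part[n] = acc
        site = part[self.tree.root].sum(axis=1) * 0.25
        return float(np.dot(self.counts, np.log(np.maximum(site, 1e-300))))


def _node_heights(tree: LineageTree) -> dict[int, float]:
    """Mean root-to-tip-consistent heights (distance above farthest leaf)."""
    depth: dict[int, float] = {tree.root: 0.0}
    for n in reversed(tree.postorder()):
        if n != tree.root:
            depth[n] = depth[tree.parent[n]] + tree.lengths[n]
    heights: dict[int, float] = {}
    for n in tree.postorder():
        if not tree.children[n]:
            heights[n] = 0.0
        else:
            # mean tip depth below n, relative to n
            heights[n] = max(
                np.mean([depth[m] - depth[n] for m in _tips_below(tree, n)]), 1e-6
            )
    return heights


def _tips_below(tree: LineageTree, node: int) -> list[int]:
    out = []
    stack = [node]
    while stack:
        u = stack.pop()
        if not tree.children[u]:
            out.append(u)
        stack.extend(tree.children[u])
    return out


def clock_lrt(
    tree: LineageTree, alignment: dict[str, str], tol: float = 1e-6
) -> ClockTestResult:
    """Likelihood-ratio test of the molecular clock under JC69.

    The unconstrained model optimizes all branch lengths freely; the clock
    model parameterizes node heights with tips at height zero. The
    statistic 2(lnL_free - lnL_clock) is referred to chi-square with
    n_leaves - 2 degrees of freedom.
    """
    if not tree.rooted:
        raise ValueError("clock_lrt requires a rooted tree")
    n_leaves = tree.n_leaves()
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    pruner = _Pruner(tree, alignment)
    lo, hi = 1e-8, 5.0

    # ---- free branch lengths ----
    x0 = np.array(
        [max(tree.lengths[n], 1e-4) for n in pruner.edge_nodes], dtype=float
    )

    def neg_free(x: np.ndarray) -> float:
        return -pruner.loglik(x)

    res_free = optimize.minimize(
        neg_free, x0, method="L-BFGS-B", bounds=[(lo, hi)] * len(x0),
        options={"maxiter": 200, "ftol": tol * 1e-3},
    )

    # ---- clock: heights ----
    internal = [
        n
        for n in pruner.order
        if tree.children[n] and tree.parent[n] is not None
    ]
    heights0 = _node_heights(tree)
    h_root0 = max(heights0[tree.root], 1e-4)

    def heights_to_lengths(h_root: float, props: np.ndarray) -> np.ndarray:
        h = {tree.root: h_root}
        for n in reversed(pruner.order):  # preorder
            if n == tree.root or not tree.children[n]:
                continue
            h[n] = h[tree.parent[n]] * props[internal.index(n)]
        lengths = np.empty(len(pruner.edge_nodes))
        for n in pruner.edge_nodes:
            hn = 0.0 if not tree.children[n] else h[n]
            lengths[pruner.edge_index[n]] = max(h[tree.parent[n]] - hn, 0.0)
        return lengths

    p0 = np.array(
        [
            min(max(heights0[n] / max(heights0[tree.parent[n]], 1e-9), 0.01), 0.99)
            for n in internal
        ]
    )
    xc0 = np.concatenate([[h_root0], p0])

    def neg_clock(x: np.ndarray) -> float:
        return -pruner.loglik(heights_to_lengths(x[0], x[1:]))

    bounds = [(1e-8, 5.0)] + [(1e-6, 1.0)] * len(internal)
    res_clock = optimize.minimize(
        neg_clock, xc0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": tol * 1e-3},
    )
    lnL_clock = -res_clock.fun

    # re-polish the free model from the clock optimum so lnL_free >= lnL_clock
    clock_lengths = heights_to_lengths(res_clock.x[0], res_clock.x[1:])
    res_free2 = optimize.minimize(
        neg_free, np.maximum(clock_lengths, lo), method="L-BFGS-B",
        bounds=[(lo, hi)] * len(x0), options={"maxiter": 200, "ftol": tol * 1e-3},
    )
    lnL_free = max(-res_free.fun, -res_free2.fun, lnL_clock)

    if not np.isfinite(lnL_free) or not np.isfinite(lnL_clock):
        raise FloatingPointError(
            f"non-finite likelihood (free={lnL_free}, clock={lnL_clock})"
        )
    stat = max(2.0 * (lnL_free - lnL_clock), 0.0)
    df = n_leaves - 2
    return ClockTestResult(
        lnL_clock=lnL_clock,
        lnL_noclock=lnL_free,
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
    )


# ---------------------------------------------------------------------------
# group divergence
# ---------------------------------------------------------------------------

def mean_group_divergence(
    groups: dict[str, list],
    consensus_length: int,
    model: str = "k2p",
):
    """Mean pairwise distance within and between element groups.

    Returns a pandas DataFrame with within-group means on the diagonal and
    between-group means off it; singleton groups have NaN within-group
    entries.
    """
    import pandas as pd

    from .align import pairwise_distance

    names = list(groups)
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i, g in enumerate(names):
        for j, h in enumerate(names[: i + 1]):
            if g == h:
                members = groups[g]
                pairs = [
                    pairwise_distance(a, b, model, consensus_length)
                    for k, a in enumerate(members)
                    for b in members[k + 1 :]
                ]
                if pairs:
                    out.loc[g, g] = float(np.mean(pairs))
            else:
                pairs = [
                    pairwise_distance(a, b, model, consensus_length)
                    for a in groups[g]
                    for b in groups[h]
                ]
                val = float(np.mean(pairs)) if pairs else np.nan
                out.loc[g, h] = val
                out.loc[h, g] = val
    return out
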