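"""Best-hit clustering and source/master copy identification.

Recently integrated elements are clustered by their single best-scoring
match; elements whose top two scores tie exactly are omitted, since their
origin cannot be attributed. Within a cluster, a rooted tree (outgroup =
subfamily consensus) plus Fitch ancestral states identify the putative
source copy: the leaf closest to the reconstructed root-adjacent ancestor.
Activity classes follow the master-gene / stealth-driver picture: a master
generates on the order of hundreds of offspring, a stealth driver at least
ten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phylo import LineageTree, fitch_ancestral

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    id: int
    members: tuple[str, ...]
    best_hits: dict[str, tuple[str, float]]  # element -> (best match, score)


@dataclass
class SourceReport:
    cluster_id: int
    source_id: str
    offspring_count: int
    driver_class: str  # master | stealth | inactive
    low_confidence: bool = False


def best_hit_clusters(
    ids: list[str], scores: np.ndarray
) -> tuple[list[Cluster], list[str]]:
    """Group elements into connected components of the best-hit graph.

    ``scores[i, j]`` is the match score between elements i and j (diagonal
    ignored). An element whose two top scores are exactly tied is omitted
    and listed separately - its single best match is undefined.
    """
    n = len(ids)
    if n < 2:
        return [Cluster(0, tuple(ids), {})], []
    scores = np.asarray(scores, dtype=float)
    omitted: list[str] = []
    best: dict[str, tuple[str, float]] = {}
    for i in range(n):
        row = scores[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")
        top, second = row[order[0]], row[order[1]]
        if top == second:
            omitted.append(ids[i])
        else:
            best[ids[i]] = (ids[int(order[0])], float(top))
    if len(omitted) == n:
        logger.warning("all elements tied on best scores; all omitted")
    kept = [i for i in ids if i in best]
    parent = {i: i for i in kept}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, (b, _s) in best.items():
        if b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    comps: dict[str, list[str]] = {}
    for i in kept:
        comps.setdefault(find(i), []).append(i)
    clusters = [
        Cluster(k, tuple(sorted(members)), {m: best[m] for m in members})
        for k, (_root, members) in enumerate(sorted(comps.items()))
    ]
    return clusters, omitted


def identify_source(
    cluster: Cluster,
    tree: LineageTree,
    leaf_states: dict[str, str],
    outgroup_label: str,
    master_min: int = 100,
    stealth_min: int = 10,
) -> SourceReport:
    """Pick the cluster's source copy from a rooted tree.

    The source is the ingroup leaf with the fewest mismatches to the Fitch
    reconstruction of the root-adjacent internal node on the ingroup side
    (ties broken by smaller leaf label and flagged low-confidence). The
    offspring count is the number of other ingroup leaves.
    """
    if not tree.rooted:
        raise ValueError("identify_source requires a rooted tree")
    states, _plen = fitch_ancestral(tree, leaf_states)
    root_children = tree.children[tree.root]
    out_leaf = tree.leaf_by_label(outgroup_label)
    ingroup = [c for c in root_children if c != out_leaf]
    if len(ingroup) != 1:
        raise ValueError("root must split outgroup vs ingroup")
    anc = np.frombuffer(states[ingroup[0]].encode(), dtype=np.uint8)
    counts: list[tuple[int, str]] = []
    for leaf in tree.leaves():
        label = tree.labels[leaf]
        if label == outgroup_label:
            continue
        obs = np.frombuffer(leaf_states[label].encode(), dtype=np.uint8)
        counts.append((int((obs != anc).sum()), label))
    counts.sort()
    source = counts[0][1]
    low_conf = len(counts) > 1 and counts[1][0] == counts[0][0]
    offspring = len(counts) - 1
    if offspring >= master_min:
        klass = "master"
    elif offspring >= stealth_min:
        klass = "stealth"
    else:
        klass = "inactive"
    return SourceReport(
        cluster_id=cluster.id,
        source_id=source,
        offspring_count=offspring,
        driver_class=klass,
        low_confidence=low_conf,
    )


def cross_family_sources(
    child_ids: list[str],
    parent_ids: list[str],
    scores: np.ndarray,
    labels: list[str],
) -> dict[str, tuple[str, float]]:
    """Best parent-set match per child element, if it beats all child matches.

    ``scores`` is the full square score matrix over ``labels``. A child
    whose best overall match is another child gets no entry (it is closer
    to its siblings than to any candidate parent).
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    child_set = set(child_ids)
    out: dict[str, tuple[str, float]] = {}
    for c in child_ids:
        i = idx[c]
        best_parent, bp_score = None, -np.inf
        best_child_score = -np.inf
        for lab in parent_ids:
            s = scores[i, idx[lab]]
            if s > bp_score:
                best_parent, bp_score = lab, s
        for lab in child_set:
            if lab == c:
                continue
            best_child_score = max(best_child_score, scores[i, idx[lab]])
        if best_parent is not None and bp_score > best_child_score:
            out[c] = (best_parent, float(bp_score))
    return out
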