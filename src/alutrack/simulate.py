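"""Retrotransposition simulator with known amplification history.

A founder element amplifies under a master-gene model: the founder (and any
copy promoted by a subfamily event) spawns daughters as a Poisson process;
daughters may themselves become low-activity "stealth" drivers. Each copy
inherits its parent's sequence *as of the birth time* and thereafter
accumulates neutral substitutions, with CpG dinucleotide positions (tracked
on the founder consensus frame) mutating faster through C->T / G->A
deamination. Scheduled subfamily events inject a diagnostic edit into a
designated copy, founding a new labelled subfamily. The output carries a
full truth table (parentage, birth times, labels) so every downstream
stage can be scored against ground truth.

Time is in million years (My); rates in substitutions/site/My or
copies/My. All randomness flows from a single seed: identical parameters
and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ConsensusModel, DiagnosticSite, GenomicInterval, revcomp

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
# transition partner index (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)


class CapacityError(RuntimeError):
    """Raised when copies cannot be placed without overlap."""


@dataclass(frozen=True)
class SubfamilyEvent:
    """A diagnostic edit applied to one copy at a fixed time.

    ``site`` positions are on the founder consensus frame. ``target`` is
    the copy id receiving the edit (copies are numbered C0000, C0001, ...
    in birth order, founders first) or ``latest:<subfamily>`` for the most
    recently born copy of that subfamily at event time. If ``copy_rate``
    is given, the edited copy starts transposing at that rate (a mutated
    copy that "then actively transposed").
    """

    time_my: float
    site: DiagnosticSite
    target: str
    subfamily: str
    copy_rate: float | None = None


@dataclass(frozen=True)
class SimParams:
    founder: ConsensusModel
    timeline_my: float
    non_cpg_rate: float = 0.0015  # substitutions/site/My (0.15%/My)
    cpg_multiplier: float = 6.0
    master_copy_rate: float = 0.0  # births/My for the founder copy
    stealth_activation_prob: float = 0.0
    stealth_copy_rate: float = 0.0
    n_founders: int = 1
    subfamily_events: tuple[SubfamilyEvent, ...] = ()
    truncation_prob: float = 0.0
    truncation_mean: int = 60
    polya_mean: int = 12
    genome_length: int = 200_000
    seed: int = 0
    max_copies: int = 5000

    def __post_init__(self) -> None:
        if self.timeline_my <= 0:
            raise ValueError("timeline_my must be > 0")
        for name in ("non_cpg_rate", "master_copy_rate", "stealth_copy_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.stealth_activation_prob <= 1:
            raise ValueError("stealth_activation_prob must be in [0,1]")
        if not 0 <= self.truncation_prob <= 1:
            raise ValueError("truncation_prob must be in [0,1]")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")


class _Copy:
    __slots__ = (
        "id", "parent", "birth", "subfamily", "rate", "seq", "consmap", "checkpoint"
    )

    def __init__(self, cid, parent, birth, subfamily, rate, seq, consmap):
        self.id = cid
        self.parent = parent
        self.birth = birth
        self.subfamily = subfamily
        self.rate = rate
        self.seq = seq          # int8 codes
        self.consmap = consmap  # founder consensus position per base, -1 inserted
        self.checkpoint = birth


@dataclass
class SimTruth:
    """Ground truth for a simulation run."""

    table: pd.DataFrame  # id, parent_id, birth_time_my, subfamily, is_active, ...

    def members(self, subfamily: str) -> list[str]:
        return list(self.table.loc[self.table.subfamily == subfamily, "id"])

    def offspring_counts(self) -> pd.Series:
        return self.table.parent_id.value_counts()

    def mean_copy_age(self, timeline_my: float) -> float:
        return float((timeline_my - self.table.birth_time_my).mean())


def _site_rates(
    seq: np.ndarray, cpg_flags: np.ndarray, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site total substitution rate and deamination excess share.

    CpG-frame positions whose base still carries the CpG context (C or G)
    mutate at ``cpg_multiplier * non_cpg_rate`` in total, the excess over
    the neutral rate being the C->T / G->A deamination channel; once the
    context is lost the site reverts to the neutral rate.
    """
    r = params.non_cpg_rate
    hot = cpg_flags & ((seq == _ENC["C"]) | (seq == _ENC["G"]))
    total = np.where(hot, params.cpg_multiplier * r, r)
    deam_share = np.where(hot, (total - 2 * r / 3) / np.maximum(total, 1e-300), 1 / 3)
    return total, deam_share


def _advance(copy: _Copy, t: float, cpg_mask: frozenset[int], params: SimParams,
             rng: np.random.Generator) -> None:
    """Accumulate substitutions on ``copy`` from its checkpoint up to ``t``.

    Sites mutate independently; at most one substitution per site per
    advance interval is drawn, an excellent approximation at neutral-rate x
    My scales (second hits have probability ~(rate*dt)^2).
    """
    dt = t - copy.checkpoint
    copy.checkpoint = t
    if dt <= 0 or params.non_cpg_rate == 0:
        return
    cpg_flags = np.isin(copy.consmap, list(cpg_mask)) if cpg_mask else np.zeros(
        len(copy.consmap), dtype=bool
    )
    total, deam = _site_rates(copy.seq, cpg_flags, params)
    p_mut = -np.expm1(-total * dt)
    hits = np.nonzero(rng.random(len(copy.seq)) < p_mut)[0]
    for i in hits:
        base = copy.seq[i]
        if rng.random() < deam[i]:
            copy.seq[i] = _TRANSITION[base]
        else:
            # one of the two transversion alternatives, uniformly
            alts = [b for b in range(4) if b != base and b != _TRANSITION[base]]
            copy.seq[i] = alts[rng.integers(2)]


def _apply_event_edit(copy: _Copy, site: DiagnosticSite) -> None:
    pos_idx = np.nonzero(copy.consmap == site.consensus_position)[0]
    if len(pos_idx) == 0:
        raise ValueError(
            f"target copy does not cover consensus position {site.consensus_position}"
        )
    i = int(pos_idx[0])
    if site.kind == "substitution":
        copy.seq[i] = _ENC[site.alt_state]
        return
    if site.kind == "insertion":
        ins = np.array([_ENC[b] for b in site.alt_state], dtype=np.int8)
        copy.seq = np.concatenate([copy.seq[: i + 1], ins, copy.seq[i + 1 :]])
        copy.consmap = np.concatenate(
            [copy.consmap[: i + 1], np.full(len(ins), -1), copy.consmap[i + 1 :]]
        )
        return
    # duplication: repeat the block starting at the site position
    k = len(site.ref_state)
    block = copy.seq[i : i + k].copy()
    copy.seq = np.concatenate([copy.seq[: i + k], block, copy.seq[i + k :]])
    copy.consmap = np.concatenate(
        [copy.consmap[: i + k], np.full(k, -1), copy.consmap[i + k :]]
    )


def simulate_amplification(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], SimTruth]:
    """Run the amplification process; returns (sequences, truth).

    Sequences are consensus-strand, untruncated and tail-free (truncation
    and poly-A belong to genome planting). Birth events follow exponential
    waiting times over the summed per-copy rates (Gillespie); scheduled
    subfamily events interleave at their fixed times.
    """
    rng = rng or np.random.default_rng(params.seed)
    founder_seq = np.array([_ENC[b] for b in params.founder.sequence], dtype=np.int8)
    consmap = np.arange(1, len(founder_seq) + 1)
    copies: list[_Copy] = [
        _Copy(f"C{i:04d}", None, 0.0, params.founder.name, params.master_copy_rate,
              founder_seq.copy(), consmap.copy())
        for i in range(params.n_founders)
    ]
    by_id = {c.id: c for c in copies}
    events = sorted(params.subfamily_events, key=lambda e: e.time_my)
    for ev in events:
        if ev.site.kind == "substitution" and len(ev.site.alt_state) != 1:
            raise ValueError("event substitutions must be single-base")
    ev_i = 0
    t = 0.0
    while True:
        total_rate = sum(c.rate for c in copies)
        t_birth = t + rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        t_event = events[ev_i].time_my if ev_i < len(events) else np.inf
        t_next = min(t_birth, t_event)
        if t_next >= params.timeline_my:
            break
        t = t_next
        if t_event <= t_birth:
            ev = events[ev_i]
            ev_i += 1
            if ev.target.startswith("latest:"):
                want = ev.target.split(":", 1)[1]
                pool = [c for c in copies if c.subfamily == want]
                if not pool:
                    raise ValueError(
                        f"subfamily event targets empty subfamily {want!r}"
                    )
                target = max(pool, key=lambda c: (c.birth, c.id))
            elif ev.target in by_id:
                target = by_id[ev.target]
            else:
                raise ValueError(f"subfamily event targets unknown copy {ev.target!r}")
            _advance(target, t, params.founder.cpg_mask, params, rng)
            _apply_event_edit(target, ev.site)
            target.subfamily = ev.subfamily
            if ev.copy_rate is not None:
                target.rate = ev.copy_rate
            continue
        # birth
        weights = np.array([c.rate for c in copies])
        parent = copies[int(rng.choice(len(copies), p=weights / weights.sum()))]
        _advance(parent, t, params.founder.cpg_mask, params, rng)
        rate = (
            params.stealth_copy_rate
            if rng.random() < params.stealth_activation_prob
            else 0.0
        )
        child = _Copy(
            f"C{len(copies):04d}", parent.id, t, parent.subfamily, rate,
            parent.seq.copy(), parent.consmap.copy(),
        )
        copies.append(child)
        by_id[child.id] = child
        if len(copies) > params.max_copies:
            raise CapacityError(f"more than {params.max_copies} copies generated")
    for c in copies:
        _advance(c, params.timeline_my, params.founder.cpg_mask, params, rng)

    seqs = {c.id: "".join(_BASES[b] for b in c.seq) for c in copies}
    table = pd.DataFrame(
        {
            "id": [c.id for c in copies],
            "parent_id": [c.parent for c in copies],
            "birth_time_my": [c.birth for c in copies],
            "subfamily": [c.subfamily for c in copies],
            "is_active": [c.rate > 0 for c in copies],
        }
    )
    return seqs, SimTruth(table)


def plant_into_genome(
    copies: dict[str, str],
    params: SimParams,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[tuple[GenomicInterval, str]]]:
    """Write copies into a random background chromosome.

    Each copy may be 5'-truncated (probability ``truncation_prob``,
    geometric length around ``truncation_mean``) and receives a 3' poly-A
    tail. Placements are uniform, non-overlapping, on a random strand; the
    copy (with tail) overwrites the background so the emitted annotation
    locates it exactly. Raises CapacityError if placement fails after
    bounded retries.
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    total = sum(len(s) for s in copies.values()) + len(copies) * (params.polya_mean + 10)
    if params.genome_length <= total:
        raise CapacityError("genome_length too small for the planted copies")
    genome = rng.integers(0, 4, params.genome_length)
    background = "".join(_BASES[b] for b in genome)
    chrom = "chrSim"
    placed: list[tuple[int, int]] = []
    annotations: list[tuple[GenomicInterval, str]] = []
    out = list(background)
    full_flags: dict[str, bool] = {}
    for cid in sorted(copies):
        seq = copies[cid]
        truncated = rng.random() < params.truncation_prob
        if truncated:
            cut = int(min(rng.geometric(1.0 / params.truncation_mean), len(seq) - 50))
            seq = seq[cut:]
        tail = "A" * int(max(5, rng.poisson(params.polya_mean)))
        planted = seq + tail
        full_flags[cid] = not truncated
        strand = "+" if rng.random() < 0.5 else "-"
        insert = planted if strand == "+" else revcomp(planted)
        for _ in range(1000):
            start = int(rng.integers(0, params.genome_length - len(insert)))
            end = start + len(insert)
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise CapacityError(f"could not place copy {cid} without overlap")
        placed.append((start, end))
        out[start:end] = insert
        iv = GenomicInterval(chrom, start, end, strand)
        annotations.append((iv, cid))
    if truth is not None:
        tbl = truth.table.set_index("id")
        for iv, cid in annotations:
            tbl.loc[cid, ["chrom", "start", "end", "strand"]] = [
                iv.chrom, iv.start, iv.end, iv.strand,
            ]
            tbl.loc[cid, "full_length"] = full_flags[cid]
        truth.table = tbl.reset_index()
    annotations.sort(key=lambda x: x[0].start)
    return {chrom: "".join(out)}, annotations


# ---------------------------------------------------------------------------
# tree/sequence simulation utilities (clock-test calibration, oracles)
# ---------------------------------------------------------------------------

def random_clock_tree(n_leaves: int, rng: np.random.Generator, height: float = 0.05):
    """Random ultrametric tree by Kingman-style sequential coalescence.

    Pair-merge times are exponential with rate k(k-1)/2, rescaled so the
    expected root height equals ``height`` (substitutions/site).
    """
    from .phylo import LineageTree

    tree = LineageTree()
    lineages = [
        (tree.add_node(None, 0.0, f"t{i}"), 0.0) for i in range(n_leaves)
    ]
    # E[sum of waiting times] = sum 2/(k(k-1)) = 2(1 - 1/n)
    scale = height / (2.0 * (1.0 - 1.0 / n_leaves))
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1))) * scale
        i, j = sorted(rng.choice(k, 2, replace=False))
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        parent = tree.add_node(None, 0.0)
        for child, h in ((ni, hi), (nj, hj)):
            tree.parent[child] = parent
            tree.children[parent].append(child)
            tree.lengths[child] = t - h
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append((parent, t))
    tree.root = lineages[0][0]
    tree.rooted = True
    return tree


def evolve_jc(tree, n_sites: int, rng: np.random.Generator) -> dict[str, str]:
    """Evolve sequences down a tree under JC69; returns leaf label -> string."""
    seqs: dict[int, np.ndarray] = {}
    for n in reversed(tree.postorder()):  # preorder
        if tree.parent[n] is None:
            seqs[n] = rng.integers(0, 4, n_sites).astype(np.int8)
            continue
        t = tree.lengths[n]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        seq = seqs[tree.parent[n]].copy()
        hits = np.nonzero(rng.random(n_sites) < p_change)[0]
        for i in hits:
            seq[i] = (seq[i] + 1 + rng.integers(3)) % 4
        seqs[n] = seq
    return {
        tree.labels[n]: "".join(_BASES[b] for b in seqs[n]) for n in tree.leaves()
    }


def random_additive_matrix(
    n_leaves: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], "object"]:
    """Random binary tree with positive branch lengths and its path-length
    (additive) distance matrix; used to exercise NJ's consistency."""
    from .phylo import LineageTree

    tree = LineageTree()
    nodes = [tree.add_node(None, 0.0, f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = tree.add_node(None, 0.0)
        for idx in (j, i):  # j first so pops keep indices valid
            child = nodes.pop(idx)
            tree.parent[child] = parent
            tree.children[parent].append(child)
            tree.lengths[child] = 0.05 + rng.random()
        nodes.append(parent)
    center = tree.add_node(None, 0.0)
    for child in nodes:
        tree.parent[child] = center
        tree.children[center].append(child)
        tree.lengths[child] = 0.05 + rng.random()
    tree.root = center
    tree.rooted = False
    labels, D = tree.leaf_distances()
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    D = D[np.ix_(order, order)]
    return (D + D.T) / 2, labels, tree  # symmetrize float round-off
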