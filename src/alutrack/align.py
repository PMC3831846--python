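"""Pairwise global alignment and consensus anchoring.

Every element is placed into a shared column frame by aligning it to its
subfamily consensus: column *i* of the frame is consensus position *i*
(1-based), element bases that fall between consensus positions are kept as
keyed insertions. All downstream statistics (diagnostic-site detection,
distances, mutation densities) are computed on this frame, which replaces a
progressive multiple alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core_io import ConsensusModel

NEG = -1e30

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
_PURINE = {0, 2}


class SaturationError(ValueError):
    """Distance undefined: observed divergence beyond the model's domain."""


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for global alignment.

    The first base of a gap costs ``gap_open``, each further base
    ``gap_extend`` (both negative). ``min_report_score`` is the reporting
    threshold standing in for an aligner e-value cutoff: elements scoring
    below it against their consensus are flagged unalignable.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    min_report_score: float = 25.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= 0 and self.gap_extend <= 0 < self.match):
            raise ValueError("need gap penalties <= 0 < match")


def global_align(
    a: str, b: str, params: AlignParams | None = None
) -> tuple[float, tuple[str, str]]:
    """Optimal affine-gap global alignment of two DNA strings.

    Returns ``(score, (aligned_a, aligned_b))``. Ties are broken
    deterministically, preferring diagonal over up (gap in ``b``) over left
    (gap in ``a``) moves during traceback.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    if not re.fullmatch(r"[ACGTNacgtn]+", a) or not re.fullmatch(r"[ACGTNacgtn]+", b):
        raise ValueError("sequences must be DNA over {A,C,G,T,N}")
    params = params or AlignParams()
    a = a.upper()
    b = b.upper()
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend

    # substitution score a[i] vs b[j]; N matches nothing and mismatches nothing
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], params.match, params.mismatch)
    is_n = (av[:, None] == ord("N")) | (bv[None, :] == ord("N"))
    sub = np.where(is_n, 0.0, sub)

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b ("up")
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a ("left")
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Iy[0, 1:] = go + (j - 1) * ge
    i_idx = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        Ix[i, 0] = go + (i - 1) * ge
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + go, Ix[i - 1, 1:] + ge
        )
        # horizontal gaps solved in closed form via a running maximum:
        # Iy[i, j] = go + ge*(j-1) + max_{k<j} (best(M,Ix)[i,k] - ge*k)
        B = np.maximum(M[i], Ix[i]) - ge * i_idx
        run = np.maximum.accumulate(B)
        Iy[i, 1:] = go + ge * (j - 1) + run[:-1]

    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    score = max(end_scores)

    # traceback; state preference M (diagonal) > Ix (up) > Iy (left)
    eps = 1e-9
    state = int(np.argmax(np.array(end_scores) + np.array([2 * eps, eps, 0.0])))
    i, jj = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or jj > 0:
        if state == 0:  # M
            out_a.append(a[i - 1])
            out_b.append(b[jj - 1])
            target = M[i, jj] - sub[i - 1, jj - 1]
            i, jj = i - 1, jj - 1
            if i == 0 and jj == 0:
                break
            if abs(M[i, jj] - target) < eps:
                state = 0
            elif abs(Ix[i, jj] - target) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:  # Ix: a[i-1] over gap
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Ix[i, jj]
            i -= 1
            if abs(M[i, jj] + go - val) < eps:
                state = 0
            elif abs(Ix[i, jj] + ge - val) < eps:
                state = 1
            else:
                state = 2
        else:  # Iy: gap over b[jj-1]
            out_a.append("-")
            out_b.append(b[jj - 1])
            val = Iy[i, jj]
            jj -= 1
            if abs(M[i, jj] + go - val) < eps:
                state = 0
            elif abs(Ix[i, jj] + go - val) < eps:
                state = 1
            else:
                state = 2
    return float(score), ("".join(reversed(out_a)), "".join(reversed(out_b)))


# ---------------------------------------------------------------------------
# poly-A handling
# ---------------------------------------------------------------------------

def _frac_a(s: str) -> float:
    return s.count("A") / len(s) if s else 0.0


def trim_polya(
    seq: str, window: int = 10, purity: float = 0.8, middle_min: int = 8
) -> tuple[str, list[tuple[int, int, str]]]:
    """Remove the 3' poly-A tail and the longest internal A-rich linker.

    The tail is found by scanning ``window``-nt windows from the 3' end and
    extending while each window is at least ``purity`` A; the removed tail
    always starts on an A. The internal linker is the longest merged run of
    ``middle_min``-nt windows at the same purity. Returns the trimmed
    sequence and the removed segments as (start, end, segment) in 0-based
    half-open coordinates of the input. A-free sequences pass unchanged.
    """
    seq = seq.upper()
    removed: list[tuple[int, int, str]] = []
    pos = len(seq)
    while pos > 0:
        w = seq[max(0, pos - window) : pos]
        if _frac_a(w) >= purity:
            pos = max(0, pos - window)
        else:
            break
    while pos > 0 and seq[pos - 1] == "A":
        pos -= 1
    while pos < len(seq) and seq[pos] != "A":
        pos += 1
    if pos < len(seq):
        removed.append((pos, len(seq), seq[pos:]))
        seq_body = seq[:pos]
    else:
        seq_body = seq

    # longest internal A-rich region (window merge, trimmed to A boundaries)
    best: tuple[int, int] | None = None
    i = 0
    L = len(seq_body)
    regions: list[tuple[int, int]] = []
    hits = [
        i
        for i in range(0, L - middle_min + 1)
        if _frac_a(seq_body[i : i + middle_min]) >= purity
    ]
    for start in hits:
        end = start + middle_min
        if regions and start <= regions[-1][1]:
            regions[-1] = (regions[-1][0], end)
        else:
            regions.append((start, end))
    for start, end in regions:
        while start < end and seq_body[start] != "A":
            start += 1
        while end > start and seq_body[end - 1] != "A":
            end -= 1
        if end - start >= middle_min and (best is None or end - start > best[1] - best[0]):
            best = (start, end)
    if best is not None:
        start, end = best
        removed.insert(0, (start, end, seq_body[start:end]))
        seq_body = seq_body[:start] + seq_body[end:]
    return seq_body, removed


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

@dataclass
class AnchoredElement:
    """One element expressed in the consensus column frame.

    ``states`` maps each covered consensus position (1-based) to the
    observed base or ``-`` for a deleted column; ``insertions`` maps
    ``(consensus_position, offset)`` (offset 1-based within the run) to the
    base inserted after that consensus position.
    """

    element_id: str
    states: dict[int, str]
    insertions: dict[tuple[int, int], str]
    coverage: tuple[int, int]
    full_length: bool
    alignable: bool = True
    score: float = 0.0
    subfamily: str | None = None
    interval: object = None  # optional GenomicInterval provenance

    def inserted_string(self, position: int) -> str:
        run = []
        k = 1
        while (position, k) in self.insertions:
            run.append(self.insertions[(position, k)])
            k += 1
        return "".join(run)

    def state_array(self, length: int) -> np.ndarray:
        """Codes per consensus position 1..length: ACGT=0..3, '-'=4, absent=-1."""
        arr = np.full(length, -1, dtype=np.int8)
        for pos, st in self.states.items():
            if 1 <= pos <= length:
                arr[pos - 1] = _CODE.get(st, -1)
        return arr


def states_matrix(elements: list[AnchoredElement], length: int) -> np.ndarray:
    return np.vstack([e.state_array(length) for e in elements])


def _canonicalize_insertions(
    states: dict[int, str],
    insertions: dict[tuple[int, int], str],
    consensus: str,
    last: int,
) -> None:
    """Right-shift insertions through identical flanking bases, in place.

    An inserted base next to an identical consensus base has two equivalent
    gap placements; the rightmost is canonical, matching the convention of
    reporting an insertion of T *after* a consensus T (e.g. "200+T").
    """
    runs = sorted({p for (p, _k) in insertions})
    for p in runs:
        bases = []
        k = 1
        while (p, k) in insertions:
            bases.append(insertions.pop((p, k)))
            k += 1
        q = p
        while (
            q + 1 <= last
            and bases
            and consensus[q] == bases[0]
            and states.get(q + 1) == bases[0]
            and (q + 1) not in {r for (r, _k) in insertions}
        ):
            bases = bases[1:] + [bases[0]]
            q += 1
        for i, b in enumerate(bases, start=1):
            insertions[(q, i)] = b


def anchor_to_consensus(
    seq: str,
    model: ConsensusModel,
    params: AlignParams | None = None,
    element_id: str = "",
    max_internal_deletion: int = 30,
) -> AnchoredElement:
    """Anchor a poly-A-trimmed element into the consensus column frame.

    ``full_length`` requires coverage starting by consensus position 5,
    ending within 5 positions of the consensus end, and at most
    ``max_internal_deletion`` deleted columns in between. Elements scoring
    below ``params.min_report_score`` are flagged unalignable and should be
    excluded downstream.
    """
    params = params or AlignParams()
    score, (ac, ae) = global_align(model.sequence, seq, params)
    states: dict[int, str] = {}
    insertions: dict[tuple[int, int], str] = {}
    cpos = 0
    ins_offset = 0
    first = last = None
    for x, y in zip(ac, ae):
        if x != "-":
            cpos += 1
            ins_offset = 0
            states[cpos] = y
            if y != "-":
                if first is None:
                    first = cpos
                last = cpos
        else:
            ins_offset += 1
            insertions[(cpos, ins_offset)] = y
    if first is None:  # no base aligned at all
        return AnchoredElement(element_id, {}, {}, (0, 0), False, False, score)
    # restrict to coverage; drop insertions outside it (5' / 3' overhangs)
    states = {p: s for p, s in states.items() if first <= p <= last}
    insertions = {
        (p, k): b for (p, k), b in insertions.items() if first <= p < last and b != "-"
    }
    _canonicalize_insertions(states, insertions, model.sequence, last)
    n_deleted = sum(1 for s in states.values() if s == "-")
    full = (
        first <= 5
        and last >= len(model.sequence) - 5
        and n_deleted <= max_internal_deletion
    )
    return AnchoredElement(
        element_id=element_id,
        states=states,
        insertions=insertions,
        coverage=(first, last),
        full_length=full,
        alignable=score >= params.min_report_score,
        score=score,
    )


def anchor_identity(
    seq: str, model: ConsensusModel, element_id: str = ""
) -> AnchoredElement:
    """Fast anchoring for sequences already in the consensus frame.

    Valid only when ``seq`` has the same length as the consensus (pure
    substitution divergence); used by the simulator-facing pipeline stages
    where this holds by construction.
    """
    if len(seq) != len(model.sequence):
        raise ValueError("anchor_identity requires equal-length sequences")
    L = len(seq)
    return AnchoredElement(
        element_id=element_id,
        states={i + 1: seq[i] for i in range(L)},
        insertions={},
        coverage=(1, L),
        full_length=True,
    )


# ---------------------------------------------------------------------------
# serialization: one row per element, states as a string over its coverage
# ---------------------------------------------------------------------------

def write_elements_tsv(path, elements: list[AnchoredElement]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "element_id\tsubfamily\tlocus\tscore\talignable\tfull_length\t"
            "first\tlast\tstates\tinsertions\n"
        )
        for e in elements:
            first, last = e.coverage
            states = "".join(e.states.get(p, "-") for p in range(first, last + 1))
            ins = ";".join(
                f"{p}+{e.inserted_string(p)}"
                for p in sorted({q for (q, _k) in e.insertions})
            )
            locus = e.interval.display() if e.interval is not None else "."
            fh.write(
                f"{e.element_id}\t{e.subfamily or '.'}\t{locus}\t{e.score:g}\t"
                f"{int(e.alignable)}\t{int(e.full_length)}\t{first}\t{last}\t"
                f"{states or '.'}\t{ins or '.'}\n"
            )


def read_elements_tsv(path) -> list[AnchoredElement]:
    from .core_io import parse_locus

    out: list[AnchoredElement] = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("element_id"), "not an elements TSV"
        for line in fh:
            (eid, sub, locus, score, alignable, full, first, last, states,
             ins) = line.rstrip("\n").split("\t")
            first, last = int(first), int(last)
            st = {} if states == "." else {
                first + i: c for i, c in enumerate(states)
            }
            insertions: dict[tuple[int, int], str] = {}
            if ins != ".":
                for run in ins.split(";"):
                    pos, bases = run.split("+")
                    for k, b in enumerate(bases, start=1):
                        insertions[(int(pos), k)] = b
            out.append(
                AnchoredElement(
                    element_id=eid,
                    states=st,
                    insertions=insertions,
                    coverage=(first, last),
                    full_length=bool(int(full)),
                    alignable=bool(int(alignable)),
                    score=float(score),
                    subfamily=None if sub == "." else sub,
                    interval=None if locus == "." else parse_locus(locus),
                )
            )
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _shared_counts(
    sa: np.ndarray, sb: np.ndarray
) -> tuple[int, int, int]:
    """(shared sites, transitions, transversions) over gap-free overlap."""
    ok = (sa >= 0) & (sa < 4) & (sb >= 0) & (sb < 4)
    n = int(ok.sum())
    diff = ok & (sa != sb)
    pur_a = np.isin(sa, (0, 2))
    pur_b = np.isin(sb, (0, 2))
    ts = int((diff & (pur_a == pur_b)).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _jc69(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"p-distance {p:.3f} >= 3/4: JC69 undefined")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _k2p(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2P distance undefined (saturated)")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def pairwise_distance(
    a: AnchoredElement,
    b: AnchoredElement,
    model: str = "p",
    consensus_length: int | None = None,
    min_overlap: int = 50,
) -> float:
    """Evolutionary distance over shared gap-free covered positions.

    ``model`` is ``p`` (mismatch fraction), ``jc69`` or ``k2p``. Insertions
    are excluded by construction of the column frame.
    """
    L = consensus_length or max(a.coverage[1], b.coverage[1])
    sa, sb = a.state_array(L), b.state_array(L)
    n, ts, tv = _shared_counts(sa, sb)
    if n < min_overlap:
        raise ValueError(f"only {n} shared positions (< {min_overlap})")
    p = (ts + tv) / n
    if model == "p":
        return p
    if model == "jc69":
        return float(_jc69(p))
    if model == "k2p":
        return float(_k2p(ts / n, tv / n))
    raise ValueError(f"unknown distance model {model!r}")


def distance_matrix(
    elements: list[AnchoredElement],
    consensus_length: int,
    model: str = "p",
) -> np.ndarray:
    """Square distance matrix over all element pairs (vectorized)."""
    S = states_matrix(elements, consensus_length)
    valid = (S >= 0) & (S < 4)
    n_el = len(elements)
    D = np.zeros((n_el, n_el))
    pur = np.isin(S, (0, 2))
    for i in range(n_el):
        ok = valid[i] & valid
        n = ok.sum(axis=1)
        diff = ok & (S[i] != S)
        ts = (diff & (pur[i] == pur)).sum(axis=1)
        tot = diff.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, tot / np.maximum(n, 1), np.nan)
            if model == "p":
                D[i] = p
            elif model == "jc69":
                D[i] = -0.75 * np.log1p(-4.0 * p / 3.0)
            elif model == "k2p":
                P = ts / np.maximum(n, 1)
                Q = (tot - ts) / np.maximum(n, 1)
                D[i] = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
            else:
                raise ValueError(f"unknown distance model {model!r}")
    np.fill_diagonal(D, 0.0)
    return D


def score_matrix(elements: list[AnchoredElement], consensus_length: int) -> np.ndarray:
    """Pairwise similarity scores (shared matching positions) in the frame.

    Serves as the all-against-all match score for best-hit clustering; in
    the shared column frame the number of identically matching positions is
    the natural alignment score.
    """
    S = states_matrix(elements, consensus_length)
    valid = (S >= 0) & (S < 4)
    n_el = len(elements)
    M = np.zeros((n_el, n_el))
    for i in range(n_el):
        ok = valid[i] & valid
        M[i] = (ok & (S[i] == S)).sum(axis=1)
    np.fill_diagonal(M, 0.0)
    return M
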