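"""Diagnostic-site detection, subfamily calling, signatures, genome scans.

A new subfamily announces itself as a specific mutation shared by two or
more elements at the same consensus position. Candidate sites are read off
the per-column state profile of the anchored elements; elements are then
partitioned by their combination of candidate-site states, the groups are
organized into a hierarchy by diagnostic-set inclusion, and each group
receives a short "signatory sequence" (a conserved window around its
newest diagnostic) that can be matched against whole genomes to find
further members.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .align import AnchoredElement
from .core_io import ConsensusModel, GenomicInterval, revcomp

logger = logging.getLogger(__name__)

SiteKey = tuple[int, str, str]  # (consensus_position, kind, shared_state)


@dataclass
class ColumnProfile:
    """Per-consensus-position state counts over a set of anchored elements."""

    n_elements: int
    covering: dict[int, int]  # position -> number of covering elements
    counts: dict[int, Counter]  # position -> state -> count
    carrier_ids: dict[tuple[int, str], list[str]]  # (pos, state) -> element ids
    ins_counts: dict[tuple[int, str], list[str]]  # (pos, inserted string) -> ids


@dataclass(frozen=True)
class CandidateSite:
    """A non-consensus state shared by multiple elements at one position."""

    consensus_position: int
    kind: str  # substitution | insertion
    consensus_state: str
    shared_state: str
    carrier_count: int
    carrier_ids: tuple[str, ...]
    is_cpg: bool = False

    @property
    def key(self) -> SiteKey:
        return (self.consensus_position, self.kind, self.shared_state)


@dataclass
class SubfamilyCall:
    name: str
    diagnostic_set: frozenset[SiteKey]
    members: tuple[str, ...]
    parent: str | None


@dataclass(frozen=True)
class Signature:
    """Short conserved window around a diagnostic site.

    ``diagnostic_offset`` is the 0-based index within ``sequence`` of the
    diagnostic alt base (or the inserted base); a genome hit must match it
    exactly, whatever the mismatch budget elsewhere.
    """

    sequence: str
    diagnostic_offset: int
    window_length: int
    subfamily: str

    def __post_init__(self) -> None:
        if self.window_length != len(self.sequence):
            raise ValueError("window_length must equal len(sequence)")
        if not 0 <= self.diagnostic_offset < len(self.sequence):
            raise ValueError("diagnostic_offset outside the window")


def profile_columns(
    elements: list[AnchoredElement], model: ConsensusModel
) -> ColumnProfile:
    """Tally observed states per consensus position and insertion key.

    Denominators vary per position: only elements whose coverage spans the
    position contribute.
    """
    if len(elements) < 2:
        raise ValueError("profile needs >= 2 anchored elements")
    covering: dict[int, int] = defaultdict(int)
    counts: dict[int, Counter] = defaultdict(Counter)
    carriers: dict[tuple[int, str], list[str]] = defaultdict(list)
    ins: dict[tuple[int, str], list[str]] = defaultdict(list)
    for el in elements:
        first, last = el.coverage
        for pos in range(first, last + 1):
            st = el.states.get(pos)
            if st is None:
                continue
            covering[pos] += 1
            counts[pos][st] += 1
            carriers[(pos, st)].append(el.element_id)
        seen_runs = {p for (p, _k) in el.insertions}
        for p in seen_runs:
            ins[(p, el.inserted_string(p))].append(el.element_id)
    return ColumnProfile(
        n_elements=len(elements),
        covering=dict(covering),
        counts={k: v for k, v in counts.items()},
        carrier_ids={k: v for k, v in carriers.items()},
        ins_counts={k: v for k, v in ins.items()},
    )


def call_diagnostic_sites(
    profile: ColumnProfile,
    model: ConsensusModel,
    min_carriers: int = 2,
    exclude_positions: frozenset[int] = frozenset(),
) -> list[CandidateSite]:
    """Candidate diagnostic sites: non-consensus states with enough carriers.

    CpG positions are flagged but kept (a diagnostic may sit in a CpG);
    A-rich linker columns and ``exclude_positions`` are skipped. Sites are
    sorted by carrier count descending, then position.
    """
    if min_carriers < 2:
        raise ValueError("min_carriers must be >= 2")
    skip = set(exclude_positions) | set(model.a_rich_positions())
    sites: list[CandidateSite] = []
    for pos, counter in profile.counts.items():
        if pos in skip:
            continue
        cons_state = model.sequence[pos - 1]
        for state, cnt in counter.items():
            if state == cons_state or state == "-":
                continue
            if cnt >= min_carriers:
                sites.append(
                    CandidateSite(
                        consensus_position=pos,
                        kind="substitution",
                        consensus_state=cons_state,
                        shared_state=state,
                        carrier_count=cnt,
                        carrier_ids=tuple(profile.carrier_ids[(pos, state)]),
                        is_cpg=pos in model.cpg_mask,
                    )
                )
    for (pos, inserted), ids in profile.ins_counts.items():
        if pos in skip or not inserted:
            continue
        if len(ids) >= min_carriers:
            sites.append(
                CandidateSite(
                    consensus_position=pos,
                    kind="insertion",
                    consensus_state="",
                    shared_state=inserted,
                    carrier_count=len(ids),
                    carrier_ids=tuple(ids),
                    is_cpg=False,
                )
            )
    sites.sort(key=lambda s: (-s.carrier_count, s.consensus_position, s.kind))
    return sites


def _carries(el: AnchoredElement, site: CandidateSite) -> bool | None:
    """True/False if the element covers the site; None when uncovered."""
    first, last = el.coverage
    if not (first <= site.consensus_position <= last):
        return None
    if site.kind == "substitution":
        return el.states.get(site.consensus_position) == site.shared_state
    return el.inserted_string(site.consensus_position) == site.shared_state


def _increment_trunk(name: str) -> str:
    m = re.match(r"^(.*?)(\d+)$", name)
    if m:
        return f"{m.group(1)}{int(m.group(2)) + 1}"
    return name + "2"


@dataclass
class NestingViolation:
    element_id: str
    site: SiteKey
    missing: tuple[SiteKey, ...]


def assign_subfamilies(
    elements: list[AnchoredElement],
    sites: list[CandidateSite],
    base_name: str,
    known: dict[str, frozenset[SiteKey]] | None = None,
    prerequisite_frac: float = 0.9,
) -> tuple[list[SubfamilyCall], list[NestingViolation]]:
    """Partition elements by candidate-site state combination and name them.

    Naming follows young-Alu convention: a diagnostic set extending the
    current deepest trunk subfamily by one increments the trunk numeral
    (Yb9 -> Yb10 -> Yb11); any other set is named parent + 'a' + number of
    extra diagnostics (Yb8 + 1 -> Yb8a1). ``known`` seeds pre-existing
    subfamily names keyed by their diagnostic sets (the empty set is always
    ``base_name``).

    Elements carrying a site without its prerequisites (sites co-carried by
    >= ``prerequisite_frac`` of that site's carriers) are reported as
    nesting violations - the signature of reverse mutation or gene
    conversion - but still assigned by their literal state combination.
    """
    known = dict(known or {})
    named: dict[frozenset[SiteKey], str] = {frozenset(): base_name}
    for nm, s in known.items():
        named[frozenset(s)] = nm

    combos: dict[frozenset[SiteKey], list[str]] = defaultdict(list)
    carried_by: dict[str, set[SiteKey]] = {}
    for el in elements:
        combo = frozenset(
            s.key for s in sites if _carries(el, s) is True
        )
        combos[combo].append(el.element_id)
        carried_by[el.element_id] = set(combo)

    # the trunk is the chain of numeral-named subfamilies (Yb8, Yb9, ...);
    # its deepest member is where single-site extensions increment the numeral
    m = re.match(r"^(.*?)(\d+)$", base_name)
    trunk_prefix = m.group(1) if m else base_name

    def trunk_numeral(name: str) -> int:
        tm = re.match(rf"^{re.escape(trunk_prefix)}(\d+)$", name)
        return int(tm.group(1)) if tm else -1

    trunk_set = max(named, key=lambda s: (trunk_numeral(named[s]), len(s)))
    calls: list[SubfamilyCall] = []
    sibling_letter: dict[tuple[str, int], int] = {}
    for combo in sorted(combos, key=lambda c: (len(c), sorted(c))):
        if combo in named:
            name = named[combo]
            parent_set = max(
                (s for s in named if s < combo), key=len, default=None
            )
        else:
            parent_set = max(
                (s for s in named if s < combo),
                key=lambda s: (len(s), named[s]),
            )
            if parent_set == trunk_set and len(combo) == len(trunk_set) + 1:
                name = _increment_trunk(named[trunk_set])
                trunk_set = combo
            else:
                # sibling lineages under one parent take successive letters
                k = len(combo) - len(parent_set)
                key = (named[parent_set], k)
                letter = chr(ord("a") + sibling_letter.get(key, 0))
                sibling_letter[key] = sibling_letter.get(key, 0) + 1
                name = f"{named[parent_set]}{letter}{k}"
            named[combo] = name
        calls.append(
            SubfamilyCall(
                name=name,
                diagnostic_set=combo,
                members=tuple(sorted(combos[combo])),
                parent=named.get(parent_set) if parent_set is not None else None,
            )
        )

    # prerequisite analysis for nesting violations
    site_by_key = {s.key: s for s in sites}
    violations: list[NestingViolation] = []
    for key, site in site_by_key.items():
        carriers = [e for e in elements if _carries(e, site) is True]
        if not carriers:
            continue
        prereqs = []
        for other_key, other in site_by_key.items():
            if other_key == key:
                continue
            co = sum(1 for e in carriers if _carries(e, other) is True)
            considered = sum(1 for e in carriers if _carries(e, other) is not None)
            if considered and co / considered >= prerequisite_frac and co >= 2:
                prereqs.append(other_key)
        for e in carriers:
            missing = tuple(
                p for p in prereqs
                if _carries(e, site_by_key[p]) is False
            )
            if missing:
                violations.append(NestingViolation(e.element_id, key, missing))
    if violations:
        logger.warning(
            "%d nesting violations (reverse mutation/gene conversion candidates)",
            len(violations),
        )
    return calls, violations


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

def build_signature(
    call: SubfamilyCall,
    sites: list[CandidateSite],
    model: ConsensusModel,
    profile: ColumnProfile | None = None,
    window: int | None = None,
    parent_set: frozenset[SiteKey] = frozenset(),
    min_window: int = 12,
    conservation: float = 0.99,
) -> Signature:
    """Signatory sequence for the newest diagnostic of a subfamily call.

    The window (default 30 nt for substitutions, 24 nt for insertions) is
    centered on the diagnostic, clamped at consensus ends, and shrunk away
    from A-rich linker columns and (when a profile is given) columns whose
    majority-state frequency falls below ``conservation``. The sequence is
    consensus everywhere except the diagnostic alt state.
    """
    new_keys = call.diagnostic_set - parent_set
    if not new_keys:
        raise ValueError("call has no diagnostic beyond its parent")
    focal_key = sorted(new_keys)[-1]
    site = next(s for s in sites if s.key == focal_key)
    is_insertion = site.kind == "insertion"
    w = window or (24 if is_insertion else 30)
    pos = site.consensus_position
    L = len(model.sequence)

    def ok_col(p: int) -> bool:
        if p < 1 or p > L or p in model.a_rich_positions():
            return False
        if profile is not None and profile.covering.get(p, 0) >= 2:
            cnt = profile.counts[p]
            if max(cnt.values()) / sum(cnt.values()) < conservation:
                return False
        return True

    if is_insertion:
        n_ins = len(site.shared_state)
        left_budget = (w - n_ins + 1) // 2
        right_budget = w - n_ins - left_budget
    else:
        left_budget = w // 2
        right_budget = w - 1 - left_budget

    left = []
    p = pos if is_insertion else pos - 1
    while len(left) < left_budget and ok_col(p):
        left.append(model.sequence[p - 1])
        p -= 1
    left.reverse()
    right = []
    p = pos + 1
    while len(right) < right_budget and ok_col(p):
        right.append(model.sequence[p - 1])
        p += 1

    if is_insertion:
        core = site.shared_state
        offset = len(left)
    else:
        core = site.shared_state
        offset = len(left)
    seq = "".join(left) + core + "".join(right)
    if len(seq) < min_window:
        raise ValueError(
            f"signature window shrank below {min_window} nt "
            f"(low conservation or A-rich flanks around position {pos})"
        )
    if len(seq) < w:
        logger.warning(
            "signature for %s shrunk to %d nt (requested %d)",
            call.name, len(seq), w,
        )
    return Signature(
        sequence=seq,
        diagnostic_offset=offset,
        window_length=len(seq),
        subfamily=call.name,
    )


# ---------------------------------------------------------------------------
# genome scanning
# ---------------------------------------------------------------------------

def _scan_strand(
    seq_arr: np.ndarray, pattern: str, diag_offset: int, max_mismatch: int
) -> list[int]:
    w = len(pattern)
    if len(seq_arr) < w:
        return []
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, w)
    mism = (windows != pat).sum(axis=1)
    exact_diag = windows[:, diag_offset] == pat[diag_offset]
    hits = np.nonzero((mism <= max_mismatch) & exact_diag)[0]
    return [int(h) for h in hits]


def scan_genome(
    genome: dict[str, str],
    sig: Signature,
    max_mismatch: int = 1,
) -> list[GenomicInterval]:
    """Find signature occurrences on both strands of a genome.

    A hit tolerates up to ``max_mismatch`` mismatches but must match the
    diagnostic base exactly. Overlapping hits are deduplicated keeping the
    leftmost plus-strand representative.
    """
    if max_mismatch >= sig.window_length / 4:
        raise ValueError("max_mismatch must stay below window_length/4")
    w = sig.window_length
    rc = revcomp(sig.sequence)
    rc_offset = w - 1 - sig.diagnostic_offset
    raw: list[GenomicInterval] = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for start in _scan_strand(arr, sig.sequence, sig.diagnostic_offset, max_mismatch):
            raw.append(GenomicInterval(chrom, start, start + w, "+"))
        for start in _scan_strand(arr, rc, rc_offset, max_mismatch):
            raw.append(GenomicInterval(chrom, start, start + w, "-"))
    raw.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    dedup: list[GenomicInterval] = []
    for iv in raw:
        if dedup and dedup[-1].overlaps(iv):
            continue
        dedup.append(iv)
    return dedup
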