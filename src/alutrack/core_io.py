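"""Coordinates, consensus models, diagnostic sites and file formats.

Internal coordinates are 0-based half-open (BED convention); everything a
human reads (logs, report tables, ``display()``) is 1-based inclusive, the
convention used in locus notation such as ``chr10:10493416-10493732``.

Minus-strand elements are reverse-complemented at load time so that all
downstream analysis works on the consensus strand; consensus positions are
always 1-based on the relevant subfamily consensus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_STRANDS = ("+", "-")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N passed through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared dialect."""


class ConsistencyError(ValueError):
    """Raised when a diagnostic edit does not match the consensus it edits."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with strand.

    ``start`` is 0-based inclusive, ``end`` exclusive. ``display()`` renders
    the 1-based inclusive form used in genome-browser locus notation.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def display(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}({self.strand})"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_LOCUS_RE = re.compile(r"^([^:]+):(\d+)-(\d+)(?:\(([+-])\))?$")


def parse_locus(text: str) -> GenomicInterval:
    """Parse 1-based inclusive locus notation back into a GenomicInterval."""
    m = _LOCUS_RE.match(text.strip())
    if m is None:
        raise FormatError(f"cannot parse locus {text!r}")
    chrom, start1, end1, strand = m.groups()
    return GenomicInterval(chrom, int(start1) - 1, int(end1), strand or "+")


@dataclass(frozen=True)
class DiagnosticSite:
    """A subfamily-defining edit at a fixed 1-based consensus position.

    ``kind`` is one of ``substitution`` (alt replaces ref at the position),
    ``insertion`` (alt inserted *after* the position, e.g. the 200+T event),
    or ``duplication`` (tandem duplication of ``ref_state`` starting at the
    position, e.g. the 7-bp duplication at 246-252 that defines Yb8).
    """

    consensus_position: int
    kind: str
    ref_state: str
    alt_state: str
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "duplication"):
            raise ValueError(f"unknown diagnostic kind {self.kind!r}")
        if self.consensus_position < 1:
            raise ValueError("consensus_position is 1-based and must be >= 1")
        if self.kind == "substitution" and len(self.ref_state) != len(self.alt_state):
            raise ValueError("substitution must preserve length")
        if self.kind == "duplication":
            if len(self.ref_state) < 1 or self.alt_state != self.ref_state * 2:
                raise ValueError("duplication alt_state must be ref_state doubled")
        if self.kind == "insertion" and not self.alt_state:
            raise ValueError("insertion needs a non-empty alt_state")


def compute_cpg_mask(sequence: str) -> frozenset[int]:
    """1-based positions covered by any CG dinucleotide in ``sequence``."""
    mask: set[int] = set()
    for i in range(len(sequence) - 1):
        if sequence[i] == "C" and sequence[i + 1] == "G":
            mask.add(i + 1)
            mask.add(i + 2)
    return frozenset(mask)


@dataclass(frozen=True)
class ConsensusModel:
    """A subfamily consensus: sequence, diagnostic registry and masks.

    ``sequence`` carries no 3' poly-A tail. ``a_rich_regions`` are 1-based
    inclusive (start, end) spans of internal A-rich linker excluded from
    mutation counting. ``cpg_mask`` is derived from the sequence and never
    set by hand. ``diagnostics`` lists every diagnostic accumulated along
    the lineage from the base consensus, in application order, at positions
    valid on *this* model's coordinate frame.
    """

    name: str
    sequence: str
    diagnostics: tuple[DiagnosticSite, ...] = ()
    a_rich_regions: tuple[tuple[int, int], ...] = ()
    cpg_mask: frozenset[int] = field(default=frozenset(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "cpg_mask", compute_cpg_mask(self.sequence))
        seen: set[tuple[int, str]] = set()
        for d in self.diagnostics:
            if d.consensus_position > len(self.sequence) + 1:
                raise ValueError(
                    f"diagnostic {d.label} at {d.consensus_position} beyond "
                    f"consensus length {len(self.sequence)}"
                )
            key = (d.consensus_position, d.kind)
            if key in seen:
                raise ValueError(f"duplicate diagnostic at {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    def a_rich_positions(self) -> frozenset[int]:
        pos: set[int] = set()
        for start, end in self.a_rich_regions:
            pos.update(range(start, end + 1))
        return frozenset(pos)


def _apply_one(sequence: str, site: DiagnosticSite) -> str:
    p = site.consensus_position  # 1-based
    if site.kind == "substitution":
        ref = sequence[p - 1 : p - 1 + len(site.ref_state)]
        if ref != site.ref_state:
            raise ConsistencyError(
                f"site {site.label}: expected {site.ref_state!r} at position "
                f"{p}, found {ref!r}"
            )
        return sequence[: p - 1] + site.alt_state + sequence[p - 1 + len(ref) :]
    if site.kind == "insertion":
        if p > len(sequence):
            raise ConsistencyError(f"site {site.label}: position {p} beyond sequence")
        return sequence[:p] + site.alt_state + sequence[p:]
    # duplication
    ref = sequence[p - 1 : p - 1 + len(site.ref_state)]
    if ref != site.ref_state:
        raise ConsistencyError(
            f"site {site.label}: expected block {site.ref_state!r} at position "
            f"{p}, found {ref!r}"
        )
    cut = p - 1 + len(ref)
    return sequence[:cut] + ref + sequence[cut:]


def _inserted_length(site: DiagnosticSite) -> int:
    if site.kind == "insertion":
        return len(site.alt_state)
    if site.kind == "duplication":
        return len(site.ref_state)
    return 0


def _insert_point(site: DiagnosticSite) -> int:
    """1-based position after which the frame gains bases (inclusive shifts)."""
    if site.kind == "insertion":
        return site.consensus_position
    if site.kind == "duplication":
        return site.consensus_position + len(site.ref_state) - 1
    return site.consensus_position  # substitution: no frame shift


def apply_diagnostics(
    base: ConsensusModel,
    edits: Sequence[DiagnosticSite],
    new_name: str,
) -> ConsensusModel:
    """Derive a child consensus by applying ``edits`` to ``base``.

    Edit positions are given on the *base* frame; they are applied in
    descending position order so earlier indices stay valid. Inherited
    diagnostics, A-rich regions and the positions of the edits themselves
    are re-expressed on the derived frame; the CpG mask is recomputed.
    """
    ordered = sorted(edits, key=lambda s: s.consensus_position, reverse=True)
    seq = base.sequence
    for site in ordered:
        seq = _apply_one(seq, site)

    def shift(pos: int) -> int:
        delta = 0
        for site in edits:
            if site.kind == "substitution":
                continue
            if pos > _insert_point(site):
                delta += _inserted_length(site)
        return pos + delta

    new_diags = [
        replace(d, consensus_position=shift(d.consensus_position))
        for d in base.diagnostics
    ]
    for site in sorted(edits, key=lambda s: s.consensus_position):
        delta = 0
        for other in edits:
            if other is site or other.kind == "substitution":
                continue
            if site.consensus_position > _insert_point(other):
                delta += _inserted_length(other)
        shifted = replace(site, consensus_position=site.consensus_position + delta)
        prior = next(
            (
                d for d in new_diags
                if (d.consensus_position, d.kind)
                == (shifted.consensus_position, shifted.kind)
            ),
            None,
        )
        if prior is not None:
            # an edit at an already-diagnostic position supersedes it; an
            # exact reverse mutation cancels it outright
            new_diags.remove(prior)
            if (prior.ref_state, prior.alt_state) == (
                shifted.alt_state, shifted.ref_state,
            ):
                continue
        new_diags.append(shifted)
    new_regions = tuple(
        (shift(start), shift(end)) for start, end in base.a_rich_regions
    )
    return ConsensusModel(
        name=new_name,
        sequence=seq,
        diagnostics=tuple(new_diags),
        a_rich_regions=new_regions,
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path, dialect: str
) -> list[tuple[GenomicInterval, str]]:
    """Read repeat annotations as (interval, repeat_name) records.

    ``dialect`` is ``repeatmasker_out`` (whitespace-delimited, 3 header
    lines, 'C' meaning minus strand) or ``bed_tsv`` (BED6). Malformed rows
    are skipped with a logged warning naming the line number.
    """
    if dialect not in ("repeatmasker_out", "bed_tsv"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    path = Path(path)
    records: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        logger.warning("annotation file %s is empty", path)
        return records
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        try:
            if dialect == "repeatmasker_out":
                fields = line.split()
                if fields[0] in ("SW", "score") or not fields[0][0].isdigit():
                    continue  # header lines
                chrom = fields[4]
                start = int(fields[5]) - 1  # .out begin is 1-based
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                name = fields[9]
            else:
                fields = line.split("\t")
                if fields[0] in ("track", "browser") or fields[0].startswith("#"):
                    continue
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "+"
            records.append((GenomicInterval(chrom, start, end, strand), name))
        except (IndexError, ValueError) as exc:
            logger.warning("%s line %d: skipping malformed row (%s)", path, lineno, exc)
    return records


def write_annotations_bed(
    path: str | Path, records: Iterable[tuple[GenomicInterval, str]]
) -> None:
    with open(path, "w") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def extract_sequence(genome: dict[str, str], interval: GenomicInterval) -> str:
    """Extract the consensus-strand sequence for an annotated interval."""
    seq = genome[interval.chrom][interval.start : interval.end]
    return revcomp(seq) if interval.strand == "-" else seq


# ---------------------------------------------------------------------------
# diagnostic-site registry (YAML)
# ---------------------------------------------------------------------------

@dataclass
class Registry:
    """Bundle of consensus models linked by diagnostic edits.

    ``models`` maps name -> ConsensusModel (base consensus first);
    ``own_edits`` maps name -> the edits that define that subfamily relative
    to its parent (positions on the parent frame, as configured);
    ``parents`` maps name -> parent name (base maps to None).
    """

    models: dict[str, ConsensusModel]
    own_edits: dict[str, tuple[DiagnosticSite, ...]]
    parents: dict[str, str | None]

    def base_name(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)


def _site_from_yaml(d: dict, parent_seq: str) -> DiagnosticSite:
    kind = d["kind"]
    pos = int(d["position"])
    ref = d.get("ref")
    alt = d.get("alt", "")
    if kind == "duplication":
        if ref is None:
            length = int(d["length"])
            ref = parent_seq[pos - 1 : pos - 1 + length]
        alt = ref * 2
    elif kind == "substitution" and ref is None:
        ref = parent_seq[pos - 1 : pos - 1 + max(1, len(alt))]
    return DiagnosticSite(pos, kind, ref or "", alt, d["label"])


def load_registry(path: str | Path) -> Registry:
    """Load a YAML consensus + diagnostic-site registry.

    Schema::

        consensus:
          name: AluY_toy
          sequence: ACGT...
          a_rich_regions: [[55, 66]]     # 1-based inclusive
        subfamilies:
          - name: Yb8_toy
            parent: AluY_toy
            edits:
              - {position: 80, kind: duplication, length: 7, label: ...}

    Edit positions are interpreted on the parent consensus frame; set
    them on whichever frame your numbering convention uses (see docs on
    the 259/274 frame ambiguity) before loading.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cons = doc["consensus"]
    base = ConsensusModel(
        name=cons["name"],
        sequence=cons["sequence"].replace("\n", "").replace(" ", ""),
        a_rich_regions=tuple(tuple(r) for r in cons.get("a_rich_regions", [])),
    )
    models: dict[str, ConsensusModel] = {base.name: base}
    own_edits: dict[str, tuple[DiagnosticSite, ...]] = {base.name: ()}
    parents: dict[str, str | None] = {base.name: None}
    for sub in doc.get("subfamilies", []):
        parent = models[sub["parent"]]
        edits = tuple(_site_from_yaml(e, parent.sequence) for e in sub["edits"])
        models[sub["name"]] = apply_diagnostics(parent, edits, sub["name"])
        own_edits[sub["name"]] = edits
        parents[sub["name"]] = sub["parent"]
    return Registry(models=models, own_edits=own_edits, parents=parents)


def default_registry() -> Registry:
    """The bundled synthetic Alu-like registry (Yb8/Yb9/Yb8a1/Yb10/Yb11)."""
    from importlib.resources import files

    return load_registry(str(files("alutrack.data") / "yb_registry.yaml"))


def toy_registry() -> Registry:
    """The bundled 120-nt toy registry used throughout the test-suite."""
    from importlib.resources import files

    return load_registry(str(files("alutrack.data") / "toy_registry.yaml"))


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a rooted LineageTree to newick with 6-decimal branch lengths.

    Raises if the tree is unrooted or leaf labels are duplicated.
    """
    if not getattr(tree, "rooted", False):
        raise ValueError("write_newick requires a rooted tree")
    labels = [tree.labels[n] for n in tree.leaves()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    with open(path, "w") as fh:
        fh.write(tree.newick())
        fh.write("\n")


def read_newick(path: str | Path):
    """Parse a newick file into a LineageTree (via dendropy)."""
    import dendropy

    from .phylo import LineageTree

    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    tree = LineageTree()

    def convert(dnode, parent_id):
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        nid = tree.add_node(
            parent=parent_id,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            label=label,
        )
        for child in dnode.child_nodes():
            convert(child, nid)
        return nid

    root = convert(dtree.seed_node, None)
    tree.root = root
    tree.lengths[root] = 0.0
    tree.rooted = len(tree.children[root]) == 2
    return tree
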