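"""Subfamily age from non-CpG mutation density.

Under neutral divergence, the fraction of non-CpG consensus positions at
which members differ from their subfamily consensus grows linearly with
time at the neutral rate (0.15% per My for primate intervening DNA), so

    age [My] = non-CpG mutation density / neutral rate.

CpG dinucleotide positions are excluded because deamination makes them
hypermutable; A-rich linker columns and the subfamily's own diagnostic
positions (definitional, not post-founding mutations) are excluded from
both numerator and denominator. Because reported densities are often
quoted rounded to two decimals of a percent, estimates are carried both
unrounded and as implied by the rounded density.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AnchoredElement
from .core_io import ConsensusModel, DiagnosticSite


@dataclass(frozen=True)
class AgeParams:
    neutral_rate: float = 0.0015  # substitutions/site/My, i.e. 0.15%/My
    full_length_only: bool = True
    count_indels: bool = False

    def __post_init__(self) -> None:
        if self.neutral_rate <= 0:
            raise ValueError("neutral_rate must be > 0")


@dataclass
class AgeEstimate:
    subfamily: str
    n_elements: int
    mutations: int
    non_cpg_bases: int
    density: float
    age_my: float
    age_my_rounded_density: float  # age implied by the 2-d.p. percent density


def diagnostic_exclusion_positions(
    model: ConsensusModel, own_sites: tuple[DiagnosticSite, ...]
) -> frozenset[int]:
    """Consensus positions occupied by a subfamily's own diagnostics.

    Substitutions exclude their position; duplications exclude the
    duplicated block; insertions occupy inserted columns which are never
    part of the consensus frame and need no exclusion.
    """
    pos: set[int] = set()
    for site in own_sites:
        if site.kind == "substitution":
            pos.update(
                range(site.consensus_position,
                      site.consensus_position + len(site.ref_state))
            )
        elif site.kind == "duplication":
            pos.update(
                range(site.consensus_position,
                      site.consensus_position + 2 * len(site.ref_state))
            )
    return frozenset(p for p in pos if 1 <= p <= len(model.sequence))


def non_cpg_mutation_density(
    members: list[AnchoredElement],
    model: ConsensusModel,
    params: AgeParams | None = None,
    exclude_positions: frozenset[int] = frozenset(),
) -> tuple[int, int, float]:
    """(mutations, non_cpg_bases, density) over all members' covered columns.

    Each member contributes its covered, non-gap, non-CpG, non-A-rich,
    non-excluded positions to the denominator, and its mismatches with the
    subfamily consensus there to the numerator. Indel columns (gaps and
    insertions) are not counted unless ``count_indels`` (then each gapped
    column or insertion run adds one mutation and one base).
    """
    params = params or AgeParams()
    use = [m for m in members if m.full_length] if params.full_length_only else members
    skip = set(model.cpg_mask) | set(model.a_rich_positions()) | set(exclude_positions)
    mutations = 0
    bases = 0
    for el in use:
        first, last = el.coverage
        for pos in range(first, last + 1):
            if pos in skip:
                continue
            st = el.states.get(pos)
            if st is None:
                continue
            if st == "-":
                if params.count_indels:
                    bases += 1
                    mutations += 1
                continue
            bases += 1
            if st != model.sequence[pos - 1]:
                mutations += 1
        if params.count_indels:
            runs = {p for (p, _k) in el.insertions if p not in skip}
            bases += len(runs)
            mutations += len(runs)
    if bases == 0:
        raise ValueError("no countable non-CpG bases")
    return mutations, bases, mutations / bases


def estimate_age(density: float, params: AgeParams | None = None) -> float:
    """Age in My implied by a non-CpG mutation density."""
    if density < 0:
        raise ValueError("density must be >= 0")
    params = params or AgeParams()
    return density / params.neutral_rate


def age_from_counts(
    mutations: int, non_cpg_bases: int, params: AgeParams | None = None
) -> tuple[float, float, float]:
    """(density, unrounded age, age from 2-d.p.-percent density)."""
    params = params or AgeParams()
    density = mutations / non_cpg_bases
    rounded = round(100.0 * density, 2) / 100.0
    return density, estimate_age(density, params), estimate_age(rounded, params)


def subfamily_age(
    name: str,
    members: list[AnchoredElement],
    model: ConsensusModel,
    own_sites: tuple[DiagnosticSite, ...] = (),
    params: AgeParams | None = None,
) -> AgeEstimate:
    """Full age estimate for one subfamily against its consensus model."""
    params = params or AgeParams()
    excl = diagnostic_exclusion_positions(model, own_sites)
    used = [m for m in members if m.full_length] if params.full_length_only else members
    muts, bases, density = non_cpg_mutation_density(
        members, model, params, exclude_positions=excl
    )
    _d, age, age_r = age_from_counts(muts, bases, params)
    return AgeEstimate(
        subfamily=name,
        n_elements=len(used),
        mutations=muts,
        non_cpg_bases=bases,
        density=density,
        age_my=age,
        age_my_rounded_density=age_r,
    )
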