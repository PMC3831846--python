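"""Insertion polymorphism: variant-set overlap and population tallies.

An insertion is called polymorphic (dimorphic) when its breakpoints lie
within a tolerance of an entry in any supplied variant interval set
(structural-variation calls, mobile-element-insertion calls, known
retrotransposon insertion polymorphism databases); otherwise it is treated
as fixed. A presence/absence matrix over populations is tallied into
per-population counts, with 'unascertained' cells handled conservatively:
an insertion is population-specific only if it is present in exactly one
population and ascertainably absent in all others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomicInterval

logger = logging.getLogger(__name__)

PRESENT, ABSENT, UNASCERTAINED = 1.0, 0.0, np.nan


@dataclass
class VariantSet:
    name: str
    intervals: list[GenomicInterval]


@dataclass
class OverlapCall:
    insertion_id: str
    status: str  # polymorphic | fixed
    matched_sets: tuple[str, ...]


def overlap_classify(
    insertions: dict[str, GenomicInterval],
    sets: list[VariantSet],
    tolerance_bp: int = 100,
) -> list[OverlapCall]:
    """Classify insertions by breakpoint proximity to variant intervals.

    A match requires both breakpoints of the insertion to fall within
    ``tolerance_bp`` of the corresponding variant breakpoints on the same
    chromosome; every matching set name is recorded. Classification is
    monotone in the tolerance: enlarging it can only add matches.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    calls: list[OverlapCall] = []
    for ins_id, iv in insertions.items():
        matched = []
        for vset in sets:
            for var in vset.intervals:
                if (
                    var.chrom == iv.chrom
                    and abs(var.start - iv.start) <= tolerance_bp
                    and abs(var.end - iv.end) <= tolerance_bp
                ):
                    matched.append(vset.name)
                    break
        calls.append(
            OverlapCall(
                insertion_id=ins_id,
                status="polymorphic" if matched else "fixed",
                matched_sets=tuple(matched),
            )
        )
    return calls


def polymorphic_fraction(calls: list[OverlapCall]) -> float:
    if not calls:
        return float("nan")
    return sum(c.status == "polymorphic" for c in calls) / len(calls)


def load_presence_matrix(path) -> pd.DataFrame:
    """Read a TSV presence matrix ({1,0,NA}; rows insertions, cols populations)."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def population_tally(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-population counts from a presence/absence matrix.

    Cells are 1 (present), 0 (ascertained absent) or NaN (unascertained).
    Columns of the result: present, absent_elsewhere (present in some other
    population but not here), unascertained, population_specific (present
    only here, absent - not unascertained - everywhere else), and
    pct_present over ascertainable insertions. Rows that are entirely
    unascertained are dropped with a warning.
    """
    m = matrix.astype(float)
    all_na = m.isna().all(axis=1)
    if all_na.any():
        logger.warning(
            "%d insertions unascertained in every population; excluded",
            int(all_na.sum()),
        )
        m = m.loc[~all_na]
    pops = list(m.columns)
    rows = []
    for pop in pops:
        col = m[pop]
        present = int((col == PRESENT).sum())
        unasc = int(col.isna().sum())
        present_any_other = (m.drop(columns=[pop]) == PRESENT).any(axis=1)
        absent_elsewhere = int(((col == ABSENT) & present_any_other).sum())
        specific = int(
            (
                (col == PRESENT)
                & (m.drop(columns=[pop]) == ABSENT).all(axis=1)
            ).sum()
        )
        ascertainable = int((~col.isna()).sum())
        rows.append(
            {
                "population": pop,
                "present": present,
                "absent_elsewhere": absent_elsewhere,
                "unascertained": unasc,
                "population_specific": specific,
                "pct_present": 100.0 * present / ascertainable if ascertainable else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("population")
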