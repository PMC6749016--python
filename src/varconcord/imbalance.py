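"""Allelic-expression imbalance from paired DNA/RNA VAFs.

When the wild-type allele of a locus is preferentially transcribed, a
variant seen clearly in DNA can be depleted or absent in RNA.  This module
pairs DNA-panel and RNA-panel observations of the same variant, computes
the DNA:RNA VAF ratio (with a floor on the RNA VAF so silenced alleles do
not divide by zero), and classifies records as imbalanced when the DNA VAF
exceeds 10% while the RNA VAF stays under 5%.  Records whose variant locus
has inadequate RNA coverage are excluded before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .callset import CallSet, VariantKey

logger = logging.getLogger(__name__)

DEFAULT_RNA_VAF_FLOOR = 0.005
DEFAULT_MIN_RNA_DEPTH = 50
DNA_VAF_IMBALANCE_THRESHOLD = 0.10  # strict >
RNA_VAF_IMBALANCE_THRESHOLD = 0.05  # strict <


def vaf_ratio(dna_vaf: float, rna_vaf: float, floor: float = DEFAULT_RNA_VAF_FLOOR) -> float:
    """DNA:RNA VAF ratio with the RNA VAF floored at ``floor``.

    Defined only for DNA-positive variants (``dna_vaf > 0``).
    """
    if dna_vaf <= 0:
        raise ValueError("vaf_ratio defined only for DNA-positive variants (dna_vaf > 0)")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return dna_vaf / max(rna_vaf, floor)


def classify_imbalanced(dna_vaf: float, rna_vaf: float) -> bool:
    """True iff DNA VAF > 10% while RNA VAF < 5% (both strict)."""
    if not (0.0 <= dna_vaf <= 1.0 and 0.0 <= rna_vaf <= 1.0):
        raise ValueError("VAFs must lie in [0, 1]")
    return dna_vaf > DNA_VAF_IMBALANCE_THRESHOLD and rna_vaf < RNA_VAF_IMBALANCE_THRESHOLD


@dataclass(frozen=True)
class ImbalanceRecord:
    """One DNA-positive variant with its paired RNA observation."""

    sample_id: str
    key: VariantKey
    dna_vaf: float
    rna_vaf: float
    rna_depth: Optional[int]
    ratio: Optional[float]
    imbalanced: bool
    excluded_low_coverage: bool

    def __post_init__(self) -> None:
        if self.imbalanced and self.excluded_low_coverage:
            raise ValueError("an excluded record cannot be classified imbalanced")


def pair_dna_rna(
    dna: CallSet,
    rna: CallSet,
    min_rna_depth: int = DEFAULT_MIN_RNA_DEPTH,
    floor: float = DEFAULT_RNA_VAF_FLOOR,
) -> list:
    """Build :class:`ImbalanceRecord`s for every DNA-positive expressed variant.

    A variant with no RNA-platform record, or with RNA depth below
    ``min_rna_depth``, is excluded as low-coverage (no ratio, no
    classification).  Non-expressed loci (e.g. promoter variants) are
    skipped outright: an RNA assay cannot observe them.
    """
    rna_by_event = {c.event: c for c in rna.variant_calls}
    records = []
    for call in dna.variant_calls:
        if not call.key.is_expressed_locus or call.vaf <= 0:
            continue
        rna_call = rna_by_event.get(call.event)
        rna_depth = rna_call.total_depth if rna_call is not None else None
        excluded = rna_call is None or (rna_depth is not None and rna_depth < min_rna_depth)
        rna_vaf = rna_call.vaf if rna_call is not None else 0.0
        records.append(
            ImbalanceRecord(
                sample_id=call.sample_id,
                key=call.key,
                dna_vaf=call.vaf,
                rna_vaf=rna_vaf,
                rna_depth=rna_depth,
                ratio=None if excluded else vaf_ratio(call.vaf, rna_vaf, floor),
                imbalanced=False if excluded else classify_imbalanced(call.vaf, rna_vaf),
                excluded_low_coverage=excluded,
            )
        )
    return records


def imbalance_summary(records: Iterable[ImbalanceRecord], ratio_cutoff: float = 10.0) -> dict:
    """Summarize an imbalance analysis after low-coverage exclusion.

    Ratio statistics (min/max, count above ``ratio_cutoff``) are taken over
    the *imbalanced* records, mirroring how the extreme wild-type-biased
    samples are characterized.
    """
    records = list(records)
    if not records:
        raise ValueError("imbalance_summary requires at least one record")
    considered = [r for r in records if not r.excluded_low_coverage]
    excluded = len(records) - len(considered)
    if not considered:
        logger.warning("all %d records excluded for low RNA coverage", excluded)
    imbalanced = [r for r in considered if r.imbalanced]
    ratios = [r.ratio for r in imbalanced]
    return {
        "n_considered": len(considered),
        "n_excluded_low_coverage": excluded,
        "n_imbalanced": len(imbalanced),
        "ratio_min": min(ratios) if ratios else None,
        "ratio_max": max(ratios) if ratios else None,
        "n_ratio_above_cutoff": sum(1 for r in ratios if r > ratio_cutoff),
        "ratio_cutoff": ratio_cutoff,
    }


def records_to_rows(records: Iterable[ImbalanceRecord]) -> list:
    """Scatter-ready rows (one per non-excluded record plus excluded flagged)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "gene": r.key.gene,
                "protein_change": r.key.protein_change,
                "dna_vaf": r.dna_vaf,
                "rna_vaf": r.rna_vaf,
                "rna_depth": "" if r.rna_depth is None else r.rna_depth,
                "ratio": "" if r.ratio is None else r.ratio,
                "category": (
                    "excluded_low_coverage"
                    if r.excluded_low_coverage
                    else ("imbalanced" if r.imbalanced else "balanced")
                ),
            }
        )
    return rows
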