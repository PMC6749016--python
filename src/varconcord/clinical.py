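"""Histology-anchored clinical performance of alteration positivity.

A sample is *alteration positive* when at least one reported variant or
fusion is attributed to it; truth is the histopathological benign/malignant
class.  Performance (sensitivity, specificity, PPV, NPV, prevalence, each
with exact binomial CIs) can be computed overall or stratified by the
expression classifier call or by Bethesda cytology category.  Companion
co-occurrence summaries (e.g. TERT promoter variants alongside RAS/BRAF
partners) and per-category alteration prevalence round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from scipy.stats import chi2_contingency

from .callset import CallSet, RNA_PLATFORMS, SampleRecord
from .concordance import ProportionWithCI, proportion_with_ci

logger = logging.getLogger(__name__)

RAS_GENES = frozenset({"NRAS", "HRAS", "KRAS"})

#: Default partner families for companion co-occurrence tables.
DEFAULT_PARTNER_FAMILIES = {"RAS": RAS_GENES, "BRAF": frozenset({"BRAF"})}


@dataclass(frozen=True)
class Confusion2x2:
    """Positivity-vs-malignancy confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Diagnostic performance; a metric whose denominator is zero is None."""

    sensitivity: Optional[ProportionWithCI]
    specificity: Optional[ProportionWithCI]
    ppv: Optional[ProportionWithCI]
    npv: Optional[ProportionWithCI]
    prevalence: Optional[ProportionWithCI]
    confusion: Confusion2x2


def sample_positivity(
    sample_id: str,
    callset: CallSet,
    reporting_rule: str = "all_calls",
    metadata: Optional[Dict[str, SampleRecord]] = None,
) -> bool:
    """Whether a sample carries >=1 reportable variant or fusion.

    ``reporting_rule="suppress_gsc_benign"`` mirrors clinical reporting,
    where alterations in classifier-benign nodules are not reported;
    validation analyses use ``"all_calls"``.  Non-expressed loci (promoter
    variants) never contribute to positivity on RNA platforms.
    """
    if metadata is not None and sample_id not in metadata:
        raise KeyError(f"unknown sample {sample_id!r}")
    if reporting_rule not in ("all_calls", "suppress_gsc_benign"):
        raise ValueError(f"unknown reporting_rule {reporting_rule!r}")
    if reporting_rule == "suppress_gsc_benign":
        if metadata is None:
            raise ValueError("suppress_gsc_benign requires sample metadata")
        if metadata[sample_id].gsc_call == "benign":
            return False
    expressed_only = callset.platform in RNA_PLATFORMS
    has_variant = any(
        c.sample_id == sample_id and (c.key.is_expressed_locus or not expressed_only)
        for c in callset.variant_calls
    )
    has_fusion = any(c.sample_id == sample_id for c in callset.fusion_calls)
    return has_variant or has_fusion


def positivity_map(
    samples: Sequence[SampleRecord],
    callset: CallSet,
    reporting_rule: str = "all_calls",
) -> Dict[str, bool]:
    meta = {s.sample_id: s for s in samples}
    return {
        s.sample_id: sample_positivity(s.sample_id, callset, reporting_rule, meta)
        for s in samples
    }


def build_confusion(
    samples: Sequence[SampleRecord], positivity: Dict[str, bool]
) -> Confusion2x2:
    """Tally positivity against histology class; unknown-histology samples
    are excluded with a logged count."""
    tp = fp = fn = tn = skipped = 0
    for s in samples:
        cls = s.histology_class
        if cls == "unknown":
            skipped += 1
            continue
        pos = positivity[s.sample_id]
        if cls == "malignant":
            tp, fn = tp + pos, fn + (not pos)
        else:
            fp, tn = fp + pos, tn + (not pos)
    if skipped:
        logger.info("excluded %d samples with unknown histology", skipped)
    c = Confusion2x2(tp=tp, fp=fp, fn=fn, tn=tn)
    if c.total == 0:
        raise ValueError("no samples with usable histology")
    return c


def performance_metrics(c: Confusion2x2, conf_level: float = 0.95) -> PerformanceMetrics:
    def _safe(x: int, n: int) -> Optional[ProportionWithCI]:
        return proportion_with_ci(x, n, conf_level) if n > 0 else None

    return PerformanceMetrics(
        sensitivity=_safe(c.tp, c.tp + c.fn),
        specificity=_safe(c.tn, c.tn + c.fp),
        ppv=_safe(c.tp, c.tp + c.fp),
        npv=_safe(c.tn, c.tn + c.fn),
        prevalence=_safe(c.tp + c.fn, c.total),
        confusion=c,
    )


def stratified_performance(
    samples: Sequence[SampleRecord],
    positivity: Dict[str, bool],
    stratum: str,
    conf_level: float = 0.95,
) -> Dict[str, PerformanceMetrics]:
    """Per-stratum performance; ``stratum`` is ``gsc_call`` or ``bethesda``."""
    if stratum not in ("gsc_call", "bethesda"):
        raise ValueError(f"unknown stratum {stratum!r}")
    groups: Dict[str, list] = {}
    for s in samples:
        groups.setdefault(getattr(s, stratum), []).append(s)
    out = {}
    for value, members in sorted(groups.items()):
        try:
            out[value] = performance_metrics(build_confusion(members, positivity), conf_level)
        except ValueError:
            logger.warning("stratum %s=%s has no usable samples; omitted", stratum, value)
    return out


def chi_square_2x2(table: Sequence[Sequence[int]], continuity_correction: bool = True):
    """Pearson chi-square test of independence on a 2x2 table.

    Yates continuity correction is applied by default.  Returns
    ``(statistic, p_value)``.
    """
    import numpy as np

    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("require a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    res = chi2_contingency(t, correction=continuity_correction)
    return float(res[0]), float(res[1])


def cooccurrence_summary(
    companion_calls: CallSet,
    partner_calls: CallSet,
    samples: Sequence[SampleRecord],
    companion_keys: Iterable,
    partner_families: Optional[Dict[str, frozenset]] = None,
) -> dict:
    """Per-sample co-occurrence of companion loci with partner variants.

    ``companion_keys`` are the loci of interest (typically non-expressed
    DNA-panel loci such as the TERT promoter); partner variants are drawn
    from ``partner_calls`` and grouped into gene families (default RAS and
    BRAF).  Returns the per-sample rows and family-level counts.
    """
    families = dict(partner_families or DEFAULT_PARTNER_FAMILIES)
    meta = {s.sample_id: s for s in samples}
    companion_keys = set(companion_keys)
    companion_by_sample: Dict[str, list] = {}
    for c in companion_calls.variant_calls:
        if c.key in companion_keys:
            companion_by_sample.setdefault(c.sample_id, []).append(c.key)

    rows: List[dict] = []
    family_counts = {name: 0 for name in families}
    n_with_partner = 0
    for sample_id in sorted(companion_by_sample):
        partners = sorted(
            {
                str(c.key)
                for c in partner_calls.variant_calls
                if c.sample_id == sample_id and c.key not in companion_keys
            }
        )
        rec = meta.get(sample_id, SampleRecord(sample_id=sample_id))
        partner_genes = {p.split(":", 1)[0] for p in partners}
        sample_families = sorted(
            name for name, genes in families.items() if partner_genes & genes
        )
        for name in sample_families:
            family_counts[name] += 1
        n_with_partner += bool(partners)
        rows.append(
            {
                "sample_id": sample_id,
                "companion": ";".join(str(k) for k in sorted(companion_by_sample[sample_id], key=str)),
                "partners": ";".join(partners) if partners else "None",
                "partner_families": ";".join(sample_families) if sample_families else "None",
                "bethesda": rec.bethesda,
                "histology": rec.histology,
                "histology_class": rec.histology_class,
                "gsc_call": rec.gsc_call,
            }
        )
    return {
        "rows": rows,
        "n_companion_positive": len(rows),
        "n_with_partner": n_with_partner,
        "n_without_partner": len(rows) - n_with_partner,
        "family_counts": family_counts,
    }


def prevalence_by_category(
    callset: CallSet,
    samples: Sequence[SampleRecord],
    group_by: str = "bethesda",
) -> List[dict]:
    """Counts and fractions of variant-/fusion-positive samples per group."""
    if group_by not in ("bethesda", "gsc_call", "histology_class"):
        raise ValueError(f"unknown group_by {group_by!r}")
    variant_pos = {c.sample_id for c in callset.variant_calls
                   if c.key.is_expressed_locus or callset.platform not in RNA_PLATFORMS}
    fusion_pos = {c.sample_id for c in callset.fusion_calls}
    groups: Dict[str, list] = {}
    for s in samples:
        key = s.histology_class if group_by == "histology_class" else getattr(s, group_by)
        groups.setdefault(key, []).append(s.sample_id)
    rows = []
    for value, ids in sorted(groups.items()):
        n = len(ids)
        nv = sum(1 for i in ids if i in variant_pos)
        nf = sum(1 for i in ids if i in fusion_pos)
        na = sum(1 for i in ids if i in variant_pos or i in fusion_pos)
        rows.append(
            {
                "group": value,
                "n": n,
                "n_variant_positive": nv,
                "n_fusion_positive": nf,
                "n_alteration_positive": na,
                "frac_variant_positive": nv / n,
                "frac_fusion_positive": nf / n,
                "frac_alteration_positive": na / n,
            }
        )
    return rows
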