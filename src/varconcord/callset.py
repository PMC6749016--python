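"""Domain types and I/O for cross-platform variant and fusion call sets.

A *call set* is one platform's view of a cohort: variant observations keyed
by (gene, HGVS protein change) and fusion observations keyed by the ordered
5'/3' partner pair.  Matching calls across platforms (whole-transcriptome
RNA-seq, targeted DNA/RNA amplicon panels, qPCR) requires a canonical
identity for each event, which this module provides, together with TSV/VCF
readers and writers for the on-disk representation.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerated discrepancy between a reported VAF and alt_depth/total_depth
#: (covers rounding in exported tables).
VAF_DEPTH_TOL = 0.005

#: Non-coding loci that cannot be observed in expressed transcript sequence.
#: The TERT promoter hotspots are reported by their colloquial DNA tokens.
NON_EXPRESSED_LOCI = {("TERT", "C228T"), ("TERT", "C250T")}


class Platform(str, enum.Enum):
    """Assay platform producing a call set."""

    WTS_RNASEQ = "WTS_RNASEQ"
    DNA_PANEL = "DNA_PANEL"
    RNA_PANEL = "RNA_PANEL"
    QPCR = "QPCR"


RNA_PLATFORMS = frozenset({Platform.WTS_RNASEQ, Platform.RNA_PANEL, Platform.QPCR})

_GENE_RE = re.compile(r"^[A-Z0-9][A-Z0-9\-\.]*$")
# simple substitution such as V600E / Q61R / K601E
_SIMPLE_SUB_RE = re.compile(r"^[A-Za-z]\d+[A-Za-z\*]$")
_PCHANGE_RE = re.compile(r"^[A-Za-z0-9_\*\+\-><=\?\.]+$")


@dataclass(frozen=True)
class VariantKey:
    """Canonical cross-platform identity of a variant.

    Equality and hashing are case-insensitive on (gene, protein_change);
    ``is_expressed_locus`` is an annotation (False for promoter loci that
    are invisible to any RNA-based assay) and does not affect identity.
    """

    gene: str
    protein_change: str
    is_expressed_locus: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not self.gene or not self.protein_change:
            raise ValueError("VariantKey requires non-empty gene and protein_change")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantKey):
            return NotImplemented
        return (self.gene.casefold(), self.protein_change.casefold()) == (
            other.gene.casefold(),
            other.protein_change.casefold(),
        )

    def __hash__(self) -> int:
        return hash((self.gene.casefold(), self.protein_change.casefold()))

    def __str__(self) -> str:  # e.g. "BRAF:p.V600E"
        return f"{self.gene}:{self.protein_change}"


def normalize_variant_key(
    gene: str,
    protein_change: str,
    is_expressed_locus: Optional[bool] = None,
) -> VariantKey:
    """Build the canonical :class:`VariantKey` from raw platform output.

    The gene symbol is upper-cased; coding changes get an enforced ``p.``
    prefix and simple substitutions (``v600e``) are upper-cased.  Known
    promoter tokens (TERT C228T/C250T) are kept verbatim and flagged as
    non-expressed unless ``is_expressed_locus`` is given explicitly.

    Raises
    ------
    ValueError
        If either field is empty after trimming or the protein change
        contains characters outside the HGVS short-form alphabet.
    """
    gene = (gene or "").strip().upper()
    token = (protein_change or "").strip()
    if not gene:
        raise ValueError("gene: empty gene symbol")
    if not _GENE_RE.match(gene):
        raise ValueError(f"gene: malformed gene symbol {gene!r}")
    if not token:
        raise ValueError("protein_change: empty protein change")

    had_prefix = token[:2].lower() == "p."
    if had_prefix:
        token = token[2:]
    if not token or not _PCHANGE_RE.match(token):
        raise ValueError(f"protein_change: malformed protein change {protein_change!r}")
    if _SIMPLE_SUB_RE.match(token):
        token = token.upper()

    if is_expressed_locus is None:
        is_expressed_locus = (gene, token.upper()) not in NON_EXPRESSED_LOCI
    if is_expressed_locus:
        token = "p." + token
    # non-expressed promoter tokens are kept in their colloquial DNA form
    return VariantKey(gene=gene, protein_change=token, is_expressed_locus=is_expressed_locus)


@dataclass(frozen=True)
class FusionId:
    """Canonical identity and the two display names of a gene fusion."""

    partner5: str
    partner3: str

    @property
    def canonical_id(self) -> str:
        """Ordered 5'/3' identifier used for cross-platform matching."""
        return f"{self.partner5}::{self.partner3}"

    @property
    def name_5p3p(self) -> str:
        """Display name in 5'/3' partner order (the matching order)."""
        return f"{self.partner5}/{self.partner3}"

    @property
    def report_name(self) -> str:
        """Report-style name: alphabetical partner order, with the two
        colloquial overrides RET/PTC1 (=CCDC6/RET) and RET/PTC3 (=NCOA4/RET)."""
        override = _COLLOQUIAL.get((self.partner5, self.partner3))
        if override is not None:
            return override
        return "/".join(sorted((self.partner5, self.partner3)))

    def __str__(self) -> str:
        return self.name_5p3p


_COLLOQUIAL = {("CCDC6", "RET"): "RET/PTC1", ("NCOA4", "RET"): "RET/PTC3"}


def canonical_fusion_id(partner5: str, partner3: str) -> FusionId:
    """Canonicalize a fusion: upper-case partners, preserve 5'/3' order.

    Raises ``ValueError`` when the partners are identical (a self-fusion
    carries no harmonizable identity).
    """
    p5 = (partner5 or "").strip().upper()
    p3 = (partner3 or "").strip().upper()
    if not p5 or not p3:
        raise ValueError("fusion partners must be non-empty gene symbols")
    if p5 == p3:
        raise ValueError(f"fusion partners must differ, got {p5!r} twice")
    return FusionId(partner5=p5, partner3=p3)


_ALTERATION_COUNT_RE = re.compile(r"\((\d+)\)\s*$")


def parse_alteration_label(label: str):
    """Parse a report-style alteration label into keys/ids with multiplicity.

    Labels look like ``"BRAF:p.V600E(3)"``, ``"PAX8/PPARG(1)"`` or the
    comma-joined form ``"TSHR:p.L629F, EZH1:p.Y642F(1)"`` which denotes one
    nodule carrying two variants (the trailing count applies to the whole
    entry).  Returns ``(alterations, count)`` where each alteration is a
    :class:`VariantKey` or :class:`FusionId`.
    """
    label = label.strip()
    count = 1
    m = _ALTERATION_COUNT_RE.search(label)
    if m:
        count = int(m.group(1))
        label = label[: m.start()].strip()
    alterations = []
    for part in label.split(","):
        part = part.strip()
        if not part:
            continue
        if "/" in part:
            p5, p3 = part.split("/", 1)
            alterations.append(canonical_fusion_id(p5, p3))
        elif ":" in part:
            gene, pchange = part.split(":", 1)
            alterations.append(normalize_variant_key(gene, pchange))
        else:
            raise ValueError(f"unrecognized alteration label {part!r}")
    return alterations, count


@dataclass(frozen=True)
class VariantCall:
    """One platform's observation of one variant in one sample."""

    sample_id: str
    key: VariantKey
    vaf: float
    alt_depth: Optional[int]
    total_depth: Optional[int]
    platform: Platform

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.alt_depth is not None:
            if self.alt_depth < 0:
                raise ValueError("alt_depth must be non-negative")
            if self.total_depth is None:
                raise ValueError("alt_depth given without total_depth")
        if self.total_depth is not None:
            if self.total_depth <= 0:
                raise ValueError("total_depth must be positive")
            if self.alt_depth is not None:
                if self.alt_depth > self.total_depth:
                    raise ValueError("alt_depth exceeds total_depth")
                if abs(self.vaf - self.alt_depth / self.total_depth) > VAF_DEPTH_TOL:
                    raise ValueError(
                        f"vaf {self.vaf} inconsistent with "
                        f"{self.alt_depth}/{self.total_depth} beyond {VAF_DEPTH_TOL}"
                    )

    @property
    def event(self) -> tuple:
        return (self.sample_id, self.key)


@dataclass(frozen=True)
class FusionCall:
    """One platform's observation of a 5'/3' gene fusion in one sample."""

    sample_id: str
    partner5: str
    partner3: str
    supporting_reads: int
    total_valid_mapped_reads: int
    platform: Platform

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        # canonicalization also validates distinct partners
        fid = canonical_fusion_id(self.partner5, self.partner3)
        object.__setattr__(self, "partner5", fid.partner5)
        object.__setattr__(self, "partner3", fid.partner3)
        if self.supporting_reads < 0:
            raise ValueError("supporting_reads must be non-negative")
        if self.total_valid_mapped_reads < 0:
            raise ValueError("total_valid_mapped_reads must be non-negative")

    @property
    def fusion_id(self) -> FusionId:
        return FusionId(self.partner5, self.partner3)

    @property
    def event(self) -> tuple:
        return (self.sample_id, self.fusion_id.canonical_id)


BETHESDA_VALUES = ("II", "III", "IV", "V", "VI", "unknown")
GSC_VALUES = ("benign", "suspicious", "no_result", "not_applicable")

MALIGNANT_SUBTYPES = frozenset(
    {"FC", "FVPTC", "HCC", "PTC", "PTC-TCV", "MTC", "PDC/PDTC", "WDC-NOS"}
)
BENIGN_SUBTYPES = frozenset(
    {"BFN", "FA", "HCA", "HN", "HTA", "CLT", "FT-UMP", "WDT-UMP"}
)

#: Report aliases seen in per-nodule listings (invasion variants, micro
#: carcinomas, synonyms) mapped to the canonical subtype codes.
HISTOLOGY_ALIASES = {
    "FV-PTC": "FVPTC",
    "MFVPTC": "FVPTC",
    "HCC-C": "HCC",
    "HCC-V": "HCC",
    "FC-C": "FC",
    "FC-V": "FC",
    "MPTC": "PTC",
    "MPTC-TCV": "PTC-TCV",
    "PDTC": "PDC/PDTC",
    "PDC": "PDC/PDTC",
    "NHP": "HN",
    "LCT": "CLT",
}


def normalize_histology(subtype: str) -> str:
    """Map a raw subtype label to its canonical code (or ``unknown``)."""
    s = (subtype or "").strip().upper()
    if not s or s == "UNKNOWN":
        return "unknown"
    s = HISTOLOGY_ALIASES.get(s, s)
    if s not in MALIGNANT_SUBTYPES and s not in BENIGN_SUBTYPES:
        return "unknown"
    return s


def histology_class(subtype: str) -> str:
    """Benign/malignant grouping of a canonical histology subtype.

    Tumors of uncertain malignant potential (FT-UMP, WDT-UMP) are grouped
    with the benign subtypes.
    """
    s = normalize_histology(subtype)
    if s in MALIGNANT_SUBTYPES:
        return "malignant"
    if s in BENIGN_SUBTYPES:
        return "benign"
    return "unknown"


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata anchoring the clinical analyses."""

    sample_id: str
    bethesda: str = "unknown"
    gsc_call: str = "not_applicable"
    histology: str = "unknown"

    def __post_init__(self) -> None:
        if self.bethesda not in BETHESDA_VALUES:
            raise ValueError(f"bethesda {self.bethesda!r} not one of {BETHESDA_VALUES}")
        if self.gsc_call not in GSC_VALUES:
            raise ValueError(f"gsc_call {self.gsc_call!r} not one of {GSC_VALUES}")
        object.__setattr__(self, "histology", normalize_histology(self.histology))

    @property
    def histology_class(self) -> str:
        return histology_class(self.histology)


@dataclass
class CallSet:
    """All variant and fusion calls of one platform over a cohort.

    Duplicate observations of the same event are collapsed on construction,
    keeping the record with the greatest total depth (respectively read
    support) and logging a warning.
    """

    platform: Platform
    variant_calls: list = field(default_factory=list)
    fusion_calls: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variant_calls = _dedup(
            self.variant_calls, lambda c: c.total_depth or 0, "variant"
        )
        self.fusion_calls = _dedup(
            self.fusion_calls, lambda c: c.supporting_reads, "fusion"
        )

    def variant_events(self, expressed_only: bool = False) -> set:
        """Set of (sample_id, VariantKey) events, optionally restricted to
        loci observable in expressed transcripts."""
        return {
            c.event
            for c in self.variant_calls
            if not expressed_only or c.key.is_expressed_locus
        }

    def fusion_events(self) -> set:
        """Set of (sample_id, canonical 5'/3' fusion id) events."""
        return {c.event for c in self.fusion_calls}

    def sample_ids(self) -> set:
        return {c.sample_id for c in self.variant_calls} | {
            c.sample_id for c in self.fusion_calls
        }

    def restrict_to_samples(self, sample_ids: Iterable[str]) -> "CallSet":
        keep = set(sample_ids)
        return CallSet(
            platform=self.platform,
            variant_calls=[c for c in self.variant_calls if c.sample_id in keep],
            fusion_calls=[c for c in self.fusion_calls if c.sample_id in keep],
        )


def _dedup(calls: Sequence, depth_of, kind: str) -> list:
    best: dict = {}
    for call in calls:
        ev = call.event
        if ev in best:
            logger.warning(
                "duplicate %s record for %s on %s; keeping max-depth record",
                kind,
                ev,
                call.platform.value,
            )
            if depth_of(call) > depth_of(best[ev]):
                best[ev] = call
        else:
            best[ev] = call
    return list(best.values())


def apply_dna_vaf_threshold(callset: CallSet, cutoff: float) -> CallSet:
    """Restrict a DNA call set to variants at or above a VAF positivity cutoff.

    The cutoff defines DNA positivity (e.g. 5% or 20%); it therefore applies
    only to DNA-platform call sets, and fusion calls pass through untouched.
    """
    if callset.platform != Platform.DNA_PANEL:
        raise ValueError(
            "VAF positivity cutoff applies to DNA_PANEL call sets only, "
            f"got {callset.platform.value}"
        )
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1)")
    return CallSet(
        platform=callset.platform,
        variant_calls=[c for c in callset.variant_calls if c.vaf >= cutoff],
        fusion_calls=list(callset.fusion_calls),
    )


# --------------------------------------------------------------------------
# TSV / VCF input-output
# --------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "sample_id", "gene", "protein_change", "vaf", "alt_depth", "total_depth", "platform",
]
FUSION_COLUMNS = [
    "sample_id", "partner5", "partner3", "supporting_reads",
    "total_valid_mapped_reads", "platform",
]
METADATA_COLUMNS = ["sample_id", "bethesda", "gsc_call", "histology"]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variant_tsv(path, platform: Optional[Platform] = None) -> list:
    """Read variant calls from the tab-delimited dialect.

    Unparseable or out-of-range rows raise ``ValueError`` naming the
    offending (1-based, header-exclusive) row.
    """
    df = _read_tsv(path)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing variant columns {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            calls.append(
                VariantCall(
                    sample_id=row.sample_id,
                    key=normalize_variant_key(row.gene, row.protein_change),
                    vaf=float(row.vaf),
                    alt_depth=int(row.alt_depth) if row.alt_depth != "" else None,
                    total_depth=int(row.total_depth) if row.total_depth != "" else None,
                    platform=Platform(row.platform) if platform is None else platform,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return calls


def read_fusion_tsv(path, platform: Optional[Platform] = None) -> list:
    df = _read_tsv(path)
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fusion columns {missing}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            calls.append(
                FusionCall(
                    sample_id=row.sample_id,
                    partner5=row.partner5,
                    partner3=row.partner3,
                    supporting_reads=int(row.supporting_reads),
                    total_valid_mapped_reads=int(row.total_valid_mapped_reads),
                    platform=Platform(row.platform) if platform is None else platform,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return calls


def read_metadata_tsv(path) -> list:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    bethesda=row.bethesda,
                    gsc_call=row.gsc_call,
                    histology=row.histology,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_variant_tsv(calls: Iterable[VariantCall], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "gene": c.key.gene,
            "protein_change": c.key.protein_change,
            "vaf": repr(c.vaf),
            "alt_depth": "" if c.alt_depth is None else c.alt_depth,
            "total_depth": "" if c.total_depth is None else c.total_depth,
            "platform": c.platform.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_fusion_tsv(calls: Iterable[FusionCall], path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "partner5": c.partner5,
            "partner3": c.partner3,
            "supporting_reads": c.supporting_reads,
            "total_valid_mapped_reads": c.total_valid_mapped_reads,
            "platform": c.platform.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_metadata_tsv(records: Iterable[SampleRecord], path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "bethesda": r.bethesda,
            "gsc_call": r.gsc_call,
            "histology": r.histology,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_vcf(path, platform: Platform) -> list:
    """Read variant calls from a single-sample VCF v4.2.

    VAF comes from FORMAT/AF with an AD-derived fallback, depth from
    FORMAT/DP; the variant identity (gene and protein change) is taken from
    the INFO fields ``GENE`` and ``PCHANGE`` written by this package's own
    exporter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, got {vcf.samples}")
    sample_id = vcf.samples[0]
    calls = []
    for rec in vcf:
        gene = rec.INFO.get("GENE")
        pchange = rec.INFO.get("PCHANGE")
        if gene is None or pchange is None:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks GENE/PCHANGE")
        def fmt(field_name):
            try:
                return rec.format(field_name)
            except KeyError:
                return None

        af, dp, ad = fmt("AF"), fmt("DP"), fmt("AD")
        total = int(dp[0][0]) if dp is not None else None
        alt = None
        if ad is not None and len(ad[0]) >= 2:
            alt = int(ad[0][1])
            if total is None:
                total = int(ad[0][0]) + alt
        if af is not None:
            vaf = float(af[0][0])
        elif alt is not None and total:
            vaf = alt / total
        else:
            raise ValueError(f"{path}: record at {rec.CHROM}:{rec.POS} lacks AF and AD")
        calls.append(
            VariantCall(
                sample_id=sample_id,
                key=normalize_variant_key(gene, pchange),
                vaf=vaf,
                alt_depth=alt,
                total_depth=total,
                platform=platform,
            )
        )
    return calls


def read_callset(path, format: str, platform: Platform) -> CallSet:
    """Read a :class:`CallSet` from ``tsv`` (variant or fusion dialect,
    detected from the header) or single-sample ``vcf``."""
    if format == "vcf":
        return CallSet(platform=platform, variant_calls=read_vcf(path, platform))
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    if "partner5" in header:
        return CallSet(platform=platform, fusion_calls=read_fusion_tsv(path, platform))
    return CallSet(platform=platform, variant_calls=read_variant_tsv(path, platform))
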