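"""Seeded synthetic cohorts with matched DNA/RNA ground truth.

The validation analyses operate on proprietary clinical call sets; this
module generates cohorts with the same statistical structure so that every
pipeline stage is testable end to end.  Ground truth consists of per-sample
metadata (cytology category, histology subtype, classifier call), true
variants (DNA VAF plus an allele expression fraction ``e`` — the relative
transcription of the variant-bearing allele, 1 = balanced, 0 = silenced),
and true fusions (an expression rate scaled to valid mapped reads).

Platform call sets are then simulated read-level: sequencing depth is
Poisson, alt reads are beta-binomial around the platform-appropriate VAF
(the DNA VAF for DNA assays, the expression-adjusted RNA VAF for RNA
assays), and a call requires minimum alt reads, minimum observed VAF, and
survival of a per-call miss probability.  Fusion evidence is Poisson read
support with the standard QC gates (minimum valid mapped reads per sample,
minimum supporting reads per call).  Promoter loci flagged non-expressed
are never callable on RNA platforms.

All randomness flows through integer-seeded ``numpy`` generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .callset import (
    CallSet,
    FusionCall,
    FusionId,
    Platform,
    SampleRecord,
    VariantCall,
    VariantKey,
    canonical_fusion_id,
    normalize_variant_key,
)
from .reproducibility import ReplicateDesign

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Default alteration panel: the recurrent thyroid variants and fusions the
# validation reports, used as the synthetic truth vocabulary.
# ---------------------------------------------------------------------------

DEFAULT_VARIANT_PANEL: Tuple[VariantKey, ...] = tuple(
    normalize_variant_key(g, p)
    for g, p in [
        ("BRAF", "V600E"), ("BRAF", "K601E"),
        ("NRAS", "Q61R"), ("NRAS", "Q61K"),
        ("HRAS", "Q61R"), ("HRAS", "G13R"),
        ("KRAS", "Q61R"), ("KRAS", "Q61K"),
        ("TSHR", "M453T"), ("TSHR", "L629F"), ("TSHR", "I568T"),
        ("TSHR", "I486M"), ("TSHR", "L512R"), ("TSHR", "D633Y"),
        ("TSHR", "S425I"), ("TSHR", "S281I"),
        ("SPOP", "P94R"),
        ("EIF1AX", "G8R"), ("EIF1AX", "G9D"), ("EIF1AX", "A113_splice"),
        ("GNAS", "Q870H"), ("PTEN", "G129R"), ("EZH1", "Y642F"),
        ("RET", "M918T"), ("RET", "C634R"),
    ]
)

DEFAULT_FUSION_PANEL: Tuple[FusionId, ...] = tuple(
    canonical_fusion_id(a, b)
    for a, b in [
        ("PAX8", "PPARG"), ("ETV6", "NTRK3"), ("CCDC6", "RET"),
        ("NCOA4", "RET"), ("STRN", "ALK"), ("EML4", "ALK"),
        ("AGK", "BRAF"), ("SND1", "BRAF"), ("RBPMS", "NTRK3"),
        ("MKRN1", "BRAF"), ("PAX8", "GLIS3"),
    ]
)

TERT_PROMOTER = normalize_variant_key("TERT", "C228T")

MALIGNANT_SUBTYPE_WEIGHTS = {
    "PTC": 0.45, "FVPTC": 0.25, "HCC": 0.10, "FC": 0.10,
    "PTC-TCV": 0.03, "MTC": 0.03, "PDC/PDTC": 0.03, "WDC-NOS": 0.01,
}
BENIGN_SUBTYPE_WEIGHTS = {
    "BFN": 0.35, "FA": 0.35, "HCA": 0.10, "HN": 0.05,
    "FT-UMP": 0.05, "WDT-UMP": 0.04, "CLT": 0.05, "HTA": 0.01,
}


@dataclass(frozen=True)
class TruthVariant:
    """Ground-truth variant: true DNA VAF and allele expression fraction."""

    sample_id: str
    key: VariantKey
    dna_vaf_true: float
    expression_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.dna_vaf_true < 1.0:
            raise ValueError("dna_vaf_true must lie in (0, 1)")
        if self.expression_fraction < 0:
            raise ValueError("expression_fraction must be non-negative")


@dataclass(frozen=True)
class TruthFusion:
    """Ground-truth fusion with expected read support per 20,000 valid
    mapped reads."""

    sample_id: str
    partner5: str
    partner3: str
    expression_rate: float

    def __post_init__(self) -> None:
        if self.expression_rate <= 0:
            raise ValueError("expression_rate must be positive")

    @property
    def fusion_id(self) -> FusionId:
        return canonical_fusion_id(self.partner5, self.partner3)


@dataclass
class PlatformModel:
    """Read-sampling and calling behaviour of one platform."""

    platform: Platform
    mean_depth: float = 300.0
    overdispersion: float = 0.01  # beta-binomial rho
    min_alt_reads: int = 5
    min_vaf_call: float = 0.05
    per_call_miss_prob: float = 0.02
    # fusion-specific QC gates
    mean_valid_mapped_reads: float = 60000.0
    mapped_reads_sigma: float = 0.5
    min_supporting_reads: int = 20
    min_valid_mapped_reads: int = 20000

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_call_miss_prob <= 1.0:
            raise ValueError("per_call_miss_prob must lie in [0, 1]")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")
        if self.min_alt_reads < 0 or self.min_supporting_reads <= 0:
            raise ValueError("read thresholds must be positive")


def default_platform_models() -> Dict[Platform, PlatformModel]:
    """Per-platform defaults: a deep targeted DNA panel tuned for
    low-frequency detection, a deep targeted RNA panel, and shallower
    whole-transcriptome coverage."""
    return {
        Platform.DNA_PANEL: PlatformModel(
            Platform.DNA_PANEL, mean_depth=500, min_alt_reads=4, min_vaf_call=0.01
        ),
        Platform.RNA_PANEL: PlatformModel(
            Platform.RNA_PANEL, mean_depth=300, min_alt_reads=4, min_vaf_call=0.01
        ),
        Platform.WTS_RNASEQ: PlatformModel(
            Platform.WTS_RNASEQ, mean_depth=100, min_alt_reads=5, min_vaf_call=0.05
        ),
    }


@dataclass
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the validation setting: ~30% of samples carry a
    variant (49% of histologically malignant, 24% of benign nodules), ~5%
    carry a fusion, ~5% of true variants sit in the low-expression
    (wild-type-biased) component, and malignancy follows the Bethesda
    mixture of an indeterminate-heavy FNA stream.
    """

    n_samples: int = 500
    seed: int = 0
    bethesda_mixture: Dict[str, float] = field(
        default_factory=lambda: {"II": 0.05, "III": 0.45, "IV": 0.30, "V": 0.10, "VI": 0.10}
    )
    malignant_prob_by_bethesda: Dict[str, float] = field(
        default_factory=lambda: {"II": 0.05, "III": 0.20, "IV": 0.25, "V": 0.70, "VI": 0.95}
    )
    variant_prevalence_by_class: Dict[str, float] = field(
        default_factory=lambda: {"malignant": 0.49, "benign": 0.24}
    )
    fusion_prevalence: float = 0.05
    imbalance_fraction: float = 0.05
    imbalance_e_max: float = 0.10
    balanced_e_sigma: float = 0.35  # lognormal sigma of the balanced component
    dna_vaf_range: Tuple[float, float] = (0.05, 0.50)
    fusion_rate_median: float = 60.0
    fusion_rate_sigma: float = 0.5
    gsc_suspicious_prob: Dict[str, float] = field(
        default_factory=lambda: {"malignant": 0.91, "benign": 0.32}
    )
    gsc_no_result_prob: float = 0.005
    tert_prevalence: float = 0.015
    tert_partner_prob: float = 0.93

    def __post_init__(self) -> None:
        for name in ("bethesda_mixture",):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, sums to {total}")
        lo, hi = self.dna_vaf_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("dna_vaf_range must satisfy 0 < lo < hi < 1")
        if not 0.0 <= self.imbalance_fraction <= 1.0:
            raise ValueError("imbalance_fraction must lie in [0, 1]")

    @property
    def expected_malignant_fraction(self) -> float:
        return sum(
            w * self.malignant_prob_by_bethesda[b]
            for b, w in self.bethesda_mixture.items()
        )


def expected_rna_vaf(dna_vaf: float, e: float) -> float:
    """RNA VAF implied by a DNA VAF ``v`` and allele expression fraction ``e``.

    With the variant allele transcribed at relative rate ``e``, the variant
    share of transcripts is ``e*v / (e*v + (1 - v))``.  Monotone increasing
    in both arguments; identity at ``e = 1``.
    """
    if not 0.0 < dna_vaf < 1.0:
        raise ValueError("dna_vaf must lie in (0, 1)")
    if e < 0:
        raise ValueError("e must be non-negative")
    num = e * dna_vaf
    return num / (num + (1.0 - dna_vaf))


def estimate_expression_fraction(dna_vaf: float, rna_vaf: float) -> float:
    """Invert :func:`expected_rna_vaf`: the expression fraction implied by a
    paired (DNA VAF, RNA VAF) observation."""
    if not 0.0 < dna_vaf < 1.0:
        raise ValueError("dna_vaf must lie in (0, 1)")
    if not 0.0 <= rna_vaf <= 1.0:
        raise ValueError("rna_vaf must lie in [0, 1]")
    if rna_vaf >= 1.0:
        return float("inf")
    return rna_vaf * (1.0 - dna_vaf) / (dna_vaf * (1.0 - rna_vaf))


def _choice(rng: np.random.Generator, weights: Dict[str, float]) -> str:
    names = list(weights)
    p = np.asarray([weights[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


def generate_cohort(
    config: CohortConfig,
) -> Tuple[List[SampleRecord], List[TruthVariant], List[TruthFusion]]:
    """Draw sample metadata and ground-truth alterations for one cohort.

    Deterministic given ``config.seed``.  Each variant-positive sample
    carries one expressed panel variant; TERT promoter companions (never
    expressed) are layered on independently, usually alongside a RAS or
    BRAF partner.
    """
    rng = np.random.default_rng(config.seed)
    samples: List[SampleRecord] = []
    truth_variants: List[TruthVariant] = []
    truth_fusions: List[TruthFusion] = []
    vaf_lo, vaf_hi = config.dna_vaf_range

    def draw_variant(sample_id: str, key: VariantKey, expressed: bool = True) -> TruthVariant:
        v = rng.uniform(vaf_lo, vaf_hi)
        if not expressed:
            e = 0.0
        elif rng.random() < config.imbalance_fraction:
            e = rng.uniform(0.0, config.imbalance_e_max)
        else:
            e = float(np.exp(rng.normal(0.0, config.balanced_e_sigma)))
        return TruthVariant(
            sample_id=sample_id, key=key, dna_vaf_true=float(v), expression_fraction=e
        )

    ras_braf = [k for k in DEFAULT_VARIANT_PANEL if k.gene in ("NRAS", "HRAS", "KRAS", "BRAF")]

    for i in range(config.n_samples):
        sample_id = f"SYN{i + 1:05d}"
        bethesda = _choice(rng, config.bethesda_mixture)
        malignant = rng.random() < config.malignant_prob_by_bethesda[bethesda]
        cls = "malignant" if malignant else "benign"
        subtype = _choice(
            rng, MALIGNANT_SUBTYPE_WEIGHTS if malignant else BENIGN_SUBTYPE_WEIGHTS
        )
        if rng.random() < config.gsc_no_result_prob:
            gsc = "no_result"
        else:
            gsc = (
                "suspicious"
                if rng.random() < config.gsc_suspicious_prob[cls]
                else "benign"
            )
        samples.append(
            SampleRecord(
                sample_id=sample_id, bethesda=bethesda, gsc_call=gsc, histology=subtype
            )
        )

        has_variant = rng.random() < config.variant_prevalence_by_class[cls]
        if has_variant:
            key = DEFAULT_VARIANT_PANEL[rng.integers(len(DEFAULT_VARIANT_PANEL))]
            truth_variants.append(draw_variant(sample_id, key))
        if rng.random() < config.tert_prevalence:
            truth_variants.append(draw_variant(sample_id, TERT_PROMOTER, expressed=False))
            already = {t.key for t in truth_variants if t.sample_id == sample_id}
            if rng.random() < config.tert_partner_prob:
                partner = ras_braf[rng.integers(len(ras_braf))]
                if partner not in already:
                    truth_variants.append(draw_variant(sample_id, partner))
        if rng.random() < config.fusion_prevalence:
            fid = DEFAULT_FUSION_PANEL[rng.integers(len(DEFAULT_FUSION_PANEL))]
            rate = float(
                config.fusion_rate_median
                * np.exp(rng.normal(0.0, config.fusion_rate_sigma))
            )
            truth_fusions.append(
                TruthFusion(
                    sample_id=sample_id,
                    partner5=fid.partner5,
                    partner3=fid.partner3,
                    expression_rate=rate,
                )
            )
    return samples, truth_variants, truth_fusions


def _beta_binomial(rng: np.random.Generator, n: int, p: float, rho: float) -> int:
    """Alt-read draw: binomial when rho = 0, beta-binomial otherwise."""
    if n == 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    if rho <= 0.0:
        return int(rng.binomial(n, p))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(a, b)))


def simulate_variant_calls(
    truth: Sequence[TruthVariant],
    model: PlatformModel,
    seed: int,
    include_uncalled: bool = False,
) -> CallSet:
    """Simulate one platform's variant call set from ground truth.

    With ``include_uncalled=True`` the call set also carries measurement
    records for loci that did not reach the calling thresholds (a targeted
    panel reports coverage and VAF at known loci regardless of call
    status); this is what the allelic-imbalance pairing consumes.
    """
    if model.platform not in (Platform.DNA_PANEL, Platform.RNA_PANEL, Platform.WTS_RNASEQ):
        raise ValueError(f"no read model for platform {model.platform}")
    rng = np.random.default_rng(seed)
    is_rna = model.platform != Platform.DNA_PANEL
    calls: List[VariantCall] = []
    for tv in truth:
        depth = int(rng.poisson(model.mean_depth))
        if is_rna and not tv.key.is_expressed_locus:
            p = 0.0
        elif is_rna:
            p = expected_rna_vaf(tv.dna_vaf_true, tv.expression_fraction)
        else:
            p = tv.dna_vaf_true
        alt = _beta_binomial(rng, depth, p, model.overdispersion) if depth else 0
        vaf = alt / depth if depth else 0.0
        missed = rng.random() < model.per_call_miss_prob
        called = (
            depth > 0
            and alt >= model.min_alt_reads
            and vaf >= model.min_vaf_call
            and not missed
            and (tv.key.is_expressed_locus or not is_rna)
        )
        if called or include_uncalled:
            if depth == 0 and not called:
                continue
            calls.append(
                VariantCall(
                    sample_id=tv.sample_id,
                    key=tv.key,
                    vaf=vaf,
                    alt_depth=alt,
                    total_depth=depth,
                    platform=model.platform,
                )
            )
    return CallSet(platform=model.platform, variant_calls=calls)


def simulate_fusion_calls(
    truth: Sequence[TruthFusion], model: PlatformModel, seed: int
) -> CallSet:
    """Simulate fusion calls: Poisson read support scaled to the sample's
    valid mapped reads, gated by the sample-level and call-level QC minima."""
    rng = np.random.default_rng(seed)
    calls: List[FusionCall] = []
    for tf in truth:
        mapped = int(
            model.mean_valid_mapped_reads
            * np.exp(rng.normal(0.0, model.mapped_reads_sigma))
        )
        support = int(rng.poisson(tf.expression_rate * mapped / 20000.0))
        missed = rng.random() < model.per_call_miss_prob
        if (
            mapped >= model.min_valid_mapped_reads
            and support >= model.min_supporting_reads
            and not missed
        ):
            calls.append(
                FusionCall(
                    sample_id=tf.sample_id,
                    partner5=tf.partner5,
                    partner3=tf.partner3,
                    supporting_reads=support,
                    total_valid_mapped_reads=mapped,
                    platform=model.platform,
                )
            )
    return CallSet(platform=model.platform, fusion_calls=calls)


def simulate_replicates(
    design: ReplicateDesign,
    miss_prob: float,
    seed: int,
    lot_effect: float = 0.0,
    platform: Platform = Platform.WTS_RNASEQ,
) -> CallSet:
    """Qualitative replicate simulation for reproducibility studies.

    Each expected positive is detected independently per replicate with
    probability ``1 - miss_prob``; a ``lot_effect`` is a per-(event, plate)
    probability that the plate's reagent lot fails the event for *all*
    replicates on that plate, which degrades inter-plate but not intra-plate
    agreement.
    """
    if not 0.0 <= miss_prob <= 1.0 or not 0.0 <= lot_effect <= 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    variant_calls: List[VariantCall] = []
    fusion_calls: List[FusionCall] = []
    expected = sorted(design.expected_positive_calls, key=lambda e: (e[0], str(e[1])))
    plates = sorted(design.plates())
    for sample_id, key in expected:
        plate_fail = {p: rng.random() < lot_effect for p in plates}
        for entry in design.entries:
            if entry.sample_id != sample_id:
                continue
            detected = not plate_fail[entry.plate_id] and rng.random() >= miss_prob
            if not detected:
                continue
            uid = entry.replicate_uid
            if isinstance(key, VariantKey):
                variant_calls.append(
                    VariantCall(
                        sample_id=uid, key=key, vaf=0.3,
                        alt_depth=30, total_depth=100, platform=platform,
                    )
                )
            else:
                p5, p3 = str(key).split("::")
                fusion_calls.append(
                    FusionCall(
                        sample_id=uid, partner5=p5, partner3=p3,
                        supporting_reads=50, total_valid_mapped_reads=50000,
                        platform=platform,
                    )
                )
    return CallSet(platform=platform, variant_calls=variant_calls, fusion_calls=fusion_calls)


def simulate_lab_calls(
    expected: set, miss_prob: float, seed: int, platform: Platform = Platform.WTS_RNASEQ
) -> CallSet:
    """One laboratory's qualitative detection of a set of expected positives
    (each detected with probability ``1 - miss_prob``)."""
    rng = np.random.default_rng(seed)
    variant_calls: List[VariantCall] = []
    fusion_calls: List[FusionCall] = []
    for sample_id, key in sorted(expected, key=lambda e: (e[0], str(e[1]))):
        if rng.random() < miss_prob:
            continue
        if isinstance(key, VariantKey):
            variant_calls.append(
                VariantCall(
                    sample_id=sample_id, key=key, vaf=0.3,
                    alt_depth=30, total_depth=100, platform=platform,
                )
            )
        else:
            p5, p3 = str(key).split("::")
            fusion_calls.append(
                FusionCall(
                    sample_id=sample_id, partner5=p5, partner3=p3,
                    supporting_reads=50, total_valid_mapped_reads=50000,
                    platform=platform,
                )
            )
    return CallSet(platform=platform, variant_calls=variant_calls, fusion_calls=fusion_calls)


def write_truth_tables(samples, truth_variants, truth_fusions, out_dir) -> None:
    """Write metadata and ground-truth tables as TSV."""
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .callset import write_metadata_tsv

    write_metadata_tsv(samples, out / "metadata.tsv")
    pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "gene": t.key.gene,
                "protein_change": t.key.protein_change,
                "is_expressed_locus": t.key.is_expressed_locus,
                "dna_vaf_true": t.dna_vaf_true,
                "expression_fraction": t.expression_fraction,
            }
            for t in truth_variants
        ]
    ).to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "partner5": t.partner5,
                "partner3": t.partner3,
                "expression_rate": t.expression_rate,
            }
            for t in truth_fusions
        ]
    ).to_csv(out / "truth_fusions.tsv", sep="\t", index=False)
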