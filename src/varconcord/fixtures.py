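"""Published summary tables re-encoded as machine-readable fixtures.

The validation study's primary data are proprietary, but its report tables
are reproducible inputs: cross-platform concordance event counts, a
per-nodule reconstruction of the 190-nodule histology cohort (nodule
counts, classifier calls, and the alterations listed per subtype), and the
15-row promoter-variant co-occurrence table.  These drive the report-level
regression tests and the acceptance computations.

Per-call VAFs and read depths are not published at nodule resolution; the
call records built here carry nominal synthetic depths (VAF 0.30, 30/100
reads) that play no role in any statistic computed from these fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

from .callset import (
    CallSet,
    FusionCall,
    FusionId,
    Platform,
    SampleRecord,
    VariantCall,
    VariantKey,
    normalize_variant_key,
    parse_alteration_label,
    write_fusion_tsv,
    write_metadata_tsv,
    write_variant_tsv,
)
from .concordance import ConcordanceCounts

# --------------------------------------------------------------------------
# Cross-platform concordance event counts (test = whole-transcriptome
# RNA-seq, reference = the targeted panel named by the row).
# --------------------------------------------------------------------------

TABLE2 = {
    "dna_variants": {
        "n_samples": 501, "panel_size": 761, "unit": "variant_event",
        "n_test_only": 2, "n_ref_only": 47, "n_both": 134,
    },
    "rna_variants": {
        "n_samples": 102, "panel_size": 761, "unit": "variant_event",
        "n_test_only": 4, "n_ref_only": 9, "n_both": 72,
    },
    "fusions": {
        "n_samples": 695, "panel_size": 168, "unit": "fusion_event",
        "n_test_only": 0, "n_ref_only": 11, "n_both": 50,
    },
}


def table2_counts() -> Dict[str, ConcordanceCounts]:
    """Concordance counts per comparison, with joint negatives derived from
    the sample count and the assayable target panel size."""
    out = {}
    for name, row in TABLE2.items():
        n_positive_pairs = row["n_both"] + row["n_ref_only"] + row["n_test_only"]
        n_neither = row["n_samples"] * row["panel_size"] - n_positive_pairs
        out[name] = ConcordanceCounts(
            n_both=row["n_both"],
            n_ref_only=row["n_ref_only"],
            n_test_only=row["n_test_only"],
            n_neither=n_neither,
            unit=row["unit"],
        )
    return out


# --------------------------------------------------------------------------
# Per-nodule reconstruction of the 190-nodule Bethesda III/IV cohort.
# Each tuple: (subtype, n GSC-benign nodules, n GSC-suspicious nodules,
# alteration labels among GSC-benign, alteration labels among GSC-suspicious).
# A comma-joined label denotes one nodule carrying two variants; "(k)" is
# the nodule multiplicity.
# --------------------------------------------------------------------------

TABLE3: List[Tuple[str, int, int, List[str], List[str]]] = [
    # histologically benign subtypes
    ("BFN", 38, 11,
     ["EIF1AX:p.G8R(1)", "TSHR:p.I486M(1)", "TSHR:p.L512R(1)", "TSHR:p.M453T(1)"],
     ["HRAS:p.Q61R(2)", "NRAS:p.Q61K(1)", "NRAS:p.Q61R(1)"]),
    ("HN", 5, 0, ["TSHR:p.I568T(1)"], []),
    ("FA", 37, 17,
     ["GNAS:p.Q870H(1)", "SPOP:p.P94R(3)", "TSHR:p.D633Y(1)", "TSHR:p.L629F(1)"],
     ["HRAS:p.Q61R(1)", "NRAS:p.Q61R(3)", "PAX8/PPARG(1)"]),
    ("FT-UMP", 4, 5, [],
     ["HRAS:p.Q61R(1)", "NRAS:p.Q61R(1)", "SPOP:p.P94R(1)"]),
    ("WDT-UMP", 4, 4, [],
     ["HRAS:p.Q61R(2)", "NRAS:p.Q61R(1)", "PAX8/PPARG(1)"]),
    ("HCA", 10, 7,
     ["EIF1AX:p.G9D(1)", "PTEN:p.G129R(1)",
      "TSHR:p.L629F, EZH1:p.Y642F(1)", "TSHR:p.S425I(1)"],
     ["NRAS:p.Q61K(2)", "TSHR:p.M453T(1)", "TSHR:p.S281I(1)"]),
    ("CLT", 1, 1, [], []),
    ("HTA", 0, 1, [], ["PAX8/GLIS3(1)"]),
    # histologically malignant subtypes
    ("PTC", 2, 13, [],
     ["BRAF:p.V600E(3)", "NRAS:p.Q61R(1)", "SPOP:p.P94R(1)",
      "MKRN1/BRAF(1)", "ETV6/NTRK3(1)"]),
    ("PTC-TCV", 0, 1, [], []),
    ("FV-PTC", 1, 10, [],
     ["HRAS:p.Q61R(1)", "KRAS:p.Q61R, EIF1AX:p.A113_splice(1)",
      "NRAS:p.Q61K(1)", "NRAS:p.Q61R(4)"]),
    ("HCC-c", 1, 8, ["TSHR:p.I568T(1)"],
     ["EIF1AX:p.A113_splice(1)", "NRAS:p.Q61R(1)"]),
    ("FC", 0, 7, [],
     ["BRAF:p.K601E(1)", "HRAS:p.G13R(1)", "NRAS:p.Q61R(1)"]),
    ("PDTC", 0, 1, [], ["NRAS:p.Q61K(1)"]),
    ("MTC", 0, 1, [], ["HRAS:p.Q61R(1)"]),
]

_NOMINAL_VAF, _NOMINAL_ALT, _NOMINAL_DEPTH = 0.30, 30, 100


def _nominal_variant(sample_id: str, key: VariantKey, platform: Platform) -> VariantCall:
    return VariantCall(
        sample_id=sample_id, key=key, vaf=_NOMINAL_VAF,
        alt_depth=_NOMINAL_ALT, total_depth=_NOMINAL_DEPTH, platform=platform,
    )


def table3_cohort() -> Tuple[List[SampleRecord], CallSet]:
    """Expand the nodule table into 190 sample records plus the RNA-seq
    call set of their reported alterations."""
    samples: List[SampleRecord] = []
    variant_calls: List[VariantCall] = []
    fusion_calls: List[FusionCall] = []
    for subtype, n_benign, n_susp, alts_benign, alts_susp in TABLE3:
        for gsc_call, n_group, labels in (
            ("benign", n_benign, alts_benign),
            ("suspicious", n_susp, alts_susp),
        ):
            nodule_alterations: List[list] = []
            for label in labels:
                alterations, count = parse_alteration_label(label)
                nodule_alterations.extend([alterations] * count)
            if len(nodule_alterations) > n_group:
                raise AssertionError(f"{subtype}/{gsc_call}: more positives than nodules")
            tag = "B" if gsc_call == "benign" else "S"
            for i in range(n_group):
                sample_id = f"T3-{subtype}-{tag}{i + 1:02d}"
                samples.append(
                    SampleRecord(
                        sample_id=sample_id, bethesda="unknown",
                        gsc_call=gsc_call, histology=subtype,
                    )
                )
                if i < len(nodule_alterations):
                    for alt in nodule_alterations[i]:
                        if isinstance(alt, FusionId):
                            fusion_calls.append(
                                FusionCall(
                                    sample_id=sample_id,
                                    partner5=alt.partner5, partner3=alt.partner3,
                                    supporting_reads=50,
                                    total_valid_mapped_reads=50000,
                                    platform=Platform.WTS_RNASEQ,
                                )
                            )
                        else:
                            variant_calls.append(
                                _nominal_variant(sample_id, alt, Platform.WTS_RNASEQ)
                            )
    callset = CallSet(
        platform=Platform.WTS_RNASEQ,
        variant_calls=variant_calls,
        fusion_calls=fusion_calls,
    )
    return samples, callset


# --------------------------------------------------------------------------
# Promoter-variant co-occurrence rows: (bethesda, histology class label,
# subtype, GSC call, partner variant label or None).  All 15 samples carry
# the TERT C228T promoter variant on the DNA panel.
# --------------------------------------------------------------------------

TABLE4: List[Tuple[str, str, str, str, str]] = [
    ("II", "M", "FVPTC", "suspicious", "NRAS:p.Q61K"),
    ("IV", "B", "HCA", "suspicious", "HRAS:p.Q61R"),
    ("IV", "B", "HCA", "suspicious", "NRAS:p.Q61K"),
    ("IV", "B", "NHP", "suspicious", "NRAS:p.Q61R"),
    ("IV", "B", "FA", "suspicious", "NRAS:p.Q61R"),
    ("IV", "B", "WDT-UMP", "suspicious", "NRAS:p.Q61R"),
    ("IV", "M", "PTC", "suspicious", "KRAS:p.Q61R"),
    ("IV", "M", "FC-v", "suspicious", "NRAS:p.Q61R"),
    ("V", "M", "PTC", "suspicious", "BRAF:p.V600E"),
    ("V", "M", "PTC", "suspicious", "BRAF:p.V600E"),
    ("VI", "M", "PTC", "suspicious", "BRAF:p.V600E"),
    ("VI", "M", "PTC-TCV", "suspicious", "BRAF:p.V600E"),
    ("VI", "M", "PTC-TCV", "suspicious", "BRAF:p.V600E"),
    ("VI", "Unknown", "Unknown", "suspicious", "BRAF:p.V600E"),
    ("VI", "M", "FC-v", "suspicious", "None"),
]

TERT_C228T = normalize_variant_key("TERT", "C228T")


def table4_cohort() -> Tuple[List[SampleRecord], CallSet]:
    """The 15 promoter-variant-positive samples with their DNA-panel calls
    (the C228T companion locus plus any partner variant)."""
    samples: List[SampleRecord] = []
    variant_calls: List[VariantCall] = []
    for i, (bethesda, _cls, subtype, gsc, partner) in enumerate(TABLE4, start=1):
        sample_id = f"T4-{i:02d}"
        samples.append(
            SampleRecord(
                sample_id=sample_id, bethesda=bethesda,
                gsc_call=gsc, histology=subtype,
            )
        )
        variant_calls.append(_nominal_variant(sample_id, TERT_C228T, Platform.DNA_PANEL))
        if partner != "None":
            gene, pchange = partner.split(":", 1)
            variant_calls.append(
                _nominal_variant(
                    sample_id, normalize_variant_key(gene, pchange), Platform.DNA_PANEL
                )
            )
    return samples, CallSet(platform=Platform.DNA_PANEL, variant_calls=variant_calls)


def write_fixtures(out_dir) -> List[Path]:
    """Write all fixtures in the package's TSV dialect; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "table2_concordance_counts.tsv"
    with open(p, "w") as fh:
        fh.write("method\tn_samples\tpanel_size\tunit\tn_test_only\tn_ref_only\tn_both\n")
        for name, row in TABLE2.items():
            fh.write(
                f"{name}\t{row['n_samples']}\t{row['panel_size']}\t{row['unit']}\t"
                f"{row['n_test_only']}\t{row['n_ref_only']}\t{row['n_both']}\n"
            )
    paths.append(p)

    samples3, calls3 = table3_cohort()
    for name, writer, payload in (
        ("table3_metadata.tsv", write_metadata_tsv, samples3),
        ("table3_variants.tsv", write_variant_tsv, calls3.variant_calls),
        ("table3_fusions.tsv", write_fusion_tsv, calls3.fusion_calls),
    ):
        p = out / name
        writer(payload, p)
        paths.append(p)

    samples4, calls4 = table4_cohort()
    for name, writer, payload in (
        ("table4_metadata.tsv", write_metadata_tsv, samples4),
        ("table4_variants.tsv", write_variant_tsv, calls4.variant_calls),
    ):
        p = out / name
        writer(payload, p)
        paths.append(p)

    p = out / "fixtures_manifest.json"
    with open(p, "w") as fh:
        json.dump({"files": [q.name for q in paths]}, fh, indent=2)
    paths.append(p)
    return paths
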