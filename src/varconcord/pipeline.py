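"""End-to-end orchestration: from fixtures or a seeded synthetic cohort to
the full report bundle (concordance, imbalance, reproducibility, clinical
performance, co-occurrence), with a machine-readable manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import pandas as pd

from . import __version__
from .callset import CallSet, Platform, apply_dna_vaf_threshold
from .clinical import (
    build_confusion,
    chi_square_2x2,
    cooccurrence_summary,
    performance_metrics,
    positivity_map,
    prevalence_by_category,
    stratified_performance,
)
from .cohort import (
    CohortConfig,
    TERT_PROMOTER,
    default_platform_models,
    generate_cohort,
    simulate_fusion_calls,
    simulate_replicates,
    simulate_variant_calls,
)
from .concordance import (
    ConcordanceCounts,
    confirmation,
    cross_tabulate,
    npa,
    ppa,
    round_percent,
)
from .fixtures import table2_counts, table3_cohort, table4_cohort
from .imbalance import imbalance_summary, pair_dna_rna, records_to_rows
from .reproducibility import replicate_concordance, triplicate_design

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one validation run."""

    mode: str = "fixtures"  # "fixtures" or "simulate"
    out_dir: str = "varconcord_run"
    seed: int = 0
    dna_vaf_cutoffs: Tuple[float, ...] = (0.05, 0.20)
    conf_level: float = 0.95
    reporting_rule: str = "all_calls"
    stratify: Tuple[str, ...] = ("gsc_call",)
    min_rna_depth: int = 50
    rna_vaf_floor: float = 0.005
    cohort: Dict = field(default_factory=dict)  # CohortConfig overrides

    def __post_init__(self) -> None:
        if self.mode not in ("fixtures", "simulate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for c in self.dna_vaf_cutoffs:
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff {c} outside (0, 1)")

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (the output location
        does not influence results and is excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _metrics_row(name: str, m) -> dict:
    def cell(p, decimals=0):
        return "" if p is None else p.format_percent(decimals)

    c = m.confusion
    return {
        "stratum": name,
        "n": c.total,
        "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        "sensitivity": cell(m.sensitivity),
        "specificity": cell(m.specificity),
        "ppv": cell(m.ppv),
        "npv": cell(m.npv),
        "prevalence": cell(m.prevalence),
    }


def _concordance_row(method: str, n_samples, counts: ConcordanceCounts, conf_level: float) -> dict:
    row = {
        "method": method,
        "n": n_samples,
        "ppa": ppa(counts, conf_level).format_percent(0),
        "npa": npa(counts, conf_level).format_percent(0) if counts.n_neither is not None else "",
        "confirmation": confirmation(counts, conf_level).format_percent(1, 0),
        "test_only": counts.n_test_only,
        "ref_only": counts.n_ref_only,
        "both": counts.n_both,
    }
    return row


def run_validation(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the JSON-ready summary (also written to ``summary.json``).
    Any stage failure raises with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "mode": config.mode,
    }
    stage = "setup"
    try:
        if config.mode == "fixtures":
            stage = "concordance"
            summary["concordance"] = _fixture_concordance(config, out)
            stage = "clinical"
            summary["clinical"] = _clinical_stage(*table3_cohort(), config, out)
            stage = "cooccurrence"
            summary["cooccurrence"] = _cooccurrence_stage(*table4_cohort(), out)
        else:
            stage = "simulate"
            cc = CohortConfig(seed=config.seed, **config.cohort)
            samples, truth_variants, truth_fusions = generate_cohort(cc)
            models = default_platform_models()
            dna = simulate_variant_calls(truth_variants, models[Platform.DNA_PANEL], cc.seed + 1)
            wts = simulate_variant_calls(truth_variants, models[Platform.WTS_RNASEQ], cc.seed + 2)
            wts_fusions = simulate_fusion_calls(truth_fusions, models[Platform.WTS_RNASEQ], cc.seed + 3)
            wts = CallSet(
                platform=Platform.WTS_RNASEQ,
                variant_calls=wts.variant_calls,
                fusion_calls=wts_fusions.fusion_calls,
            )
            rna_meas = simulate_variant_calls(
                truth_variants, models[Platform.RNA_PANEL], cc.seed + 4, include_uncalled=True
            )
            scope = [s.sample_id for s in samples]

            stage = "concordance"
            rows = []
            conc = {}
            for cutoff in config.dna_vaf_cutoffs:
                counts = cross_tabulate(
                    wts, apply_dna_vaf_threshold(dna, cutoff), scope, unit="variant_event"
                )
                rows.append(
                    _concordance_row(f"dna_variants_cutoff_{cutoff}", len(scope), counts, config.conf_level)
                )
                conc[f"ppa_pct_cutoff_{cutoff}"] = round_percent(
                    ppa(counts, config.conf_level).point, 1
                )
            pd.DataFrame(rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
            summary["concordance"] = conc

            stage = "imbalance"
            dna_positive = apply_dna_vaf_threshold(dna, min(config.dna_vaf_cutoffs))
            records = pair_dna_rna(
                dna_positive, rna_meas, config.min_rna_depth, config.rna_vaf_floor
            )
            if records:
                pd.DataFrame(records_to_rows(records)).to_csv(
                    out / "imbalance.tsv", sep="\t", index=False
                )
                summary["imbalance"] = imbalance_summary(records)

            stage = "reproducibility"
            expected = {
                (t.sample_id, t.key)
                for t in truth_variants
                if t.key.is_expressed_locus and t.expression_fraction > 0.5
            }
            positive_samples = sorted({s for s, _ in expected})[:9]
            expected = {(s, k) for (s, k) in expected if s in positive_samples}
            if expected:
                design = triplicate_design(positive_samples, expected_positive_calls=expected)
                rep_calls = simulate_replicates(design, miss_prob=0.05, seed=cc.seed + 5)
                summary["reproducibility"] = {
                    mode: replicate_concordance(rep_calls, design, mode).format_percent(1)
                    for mode in ("intra_plate", "inter_plate")
                }

            stage = "clinical"
            summary["clinical"] = _clinical_stage(samples, wts, config, out)
            stage = "cooccurrence"
            summary["cooccurrence"] = _cooccurrence_stage(samples, dna, out)
            stage = "prevalence"
            pd.DataFrame(prevalence_by_category(wts, samples, "bethesda")).to_csv(
                out / "prevalence_by_bethesda.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def _fixture_concordance(config: RunConfig, out: Path) -> dict:
    counts = table2_counts()
    from .fixtures import TABLE2

    rows = [
        _concordance_row(name, TABLE2[name]["n_samples"], c, config.conf_level)
        for name, c in counts.items()
    ]
    pd.DataFrame(rows).to_csv(out / "concordance.tsv", sep="\t", index=False)
    return {
        name: {
            "ppa": ppa(c, config.conf_level).format_percent(
                1 if name == "rna_variants" else 0
            ),
            "npa": npa(c, config.conf_level).format_percent(0),
            "confirmation": confirmation(c, config.conf_level).format_percent(1, 0),
        }
        for name, c in counts.items()
    }


def _clinical_stage(samples, callset: CallSet, config: RunConfig, out: Path) -> dict:
    usable = [s for s in samples if s.gsc_call in ("benign", "suspicious")]
    pos = positivity_map(usable, callset, config.reporting_rule)
    confusion = build_confusion(usable, pos)
    overall = performance_metrics(confusion, config.conf_level)
    rows = [_metrics_row("overall", overall)]
    strat_summaries = {}
    for stratum in config.stratify:
        for value, m in stratified_performance(usable, pos, stratum, config.conf_level).items():
            rows.append(_metrics_row(f"{stratum}={value}", m))
            strat_summaries[f"{stratum}={value}"] = _metrics_row(f"{stratum}={value}", m)
    pd.DataFrame(rows).to_csv(out / "clinical_performance.tsv", sep="\t", index=False)
    c = confusion
    stat, p = chi_square_2x2([[c.tp, c.fn], [c.fp, c.tn]])
    return {
        "overall": _metrics_row("overall", overall),
        "strata": strat_summaries,
        "chi_square_positivity_vs_malignancy": {"statistic": stat, "p_value": p},
    }


def _cooccurrence_stage(samples, dna_calls: CallSet, out: Path) -> dict:
    summary = cooccurrence_summary(dna_calls, dna_calls, samples, companion_keys={TERT_PROMOTER})
    if summary["rows"]:
        pd.DataFrame(summary["rows"]).to_csv(out / "cooccurrence.tsv", sep="\t", index=False)
    return {k: v for k, v in summary.items() if k != "rows"}
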