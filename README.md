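# varconcord

Cross-platform validation of **expressed variants and gene fusions** called
from thyroid fine-needle-aspiration (FNA) samples.

When the same biological sample is assayed by whole-transcriptome RNA-seq,
a targeted DNA amplicon panel, and a targeted RNA panel, the call sets
rarely agree perfectly: a variant clearly present in DNA may be depleted in
RNA when the wild-type allele is preferentially transcribed, fusion callers
disagree on nomenclature and orientation, and each platform has its own
depth and calling thresholds. `varconcord` is a tested, reusable pipeline
for the analyses that quantify this: it harmonizes call identities across
platforms, computes agreement statistics with exact binomial confidence
intervals, classifies allelic-expression imbalance from paired DNA:RNA
VAFs, measures replicate and between-laboratory reproducibility, and
derives histology-anchored diagnostic performance stratified by cytology
(Bethesda) category and expression-classifier call. It is written for
molecular diagnostics groups validating RNA-based variant/fusion reporting
against orthogonal methods.

## The statistics

Events are (sample, variant-key) or (sample, 5′/3′ fusion) pairs. For a
*test* method compared with a *reference* method over a shared sample set:

- **PPA** (positive percent agreement) = `both / (both + reference-only)` —
  how much of what the reference sees the test also sees;
- **confirmation** = `both / (both + test-only)` — how much of what the
  test reports the reference corroborates;
- **NPA** (negative percent agreement) = jointly negative
  (sample × panel-target) pairs over reference-negative pairs, which
  requires an explicit panel of assayable targets.

All intervals are two-sided exact binomial (Clopper–Pearson) intervals
from the beta-quantile closed form,

```
low  = BetaInv(α/2;     x,     n − x + 1)        (0 at x = 0)
high = BetaInv(1 − α/2; x + 1, n − x)            (1 at x = n)
```

Allelic expression is modelled through the expression fraction *e* of the
variant-bearing allele: a DNA VAF *v* implies an RNA VAF
`e·v / (e·v + (1 − v))`. A paired observation is classified **imbalanced**
when the DNA VAF exceeds 10% while the RNA VAF stays below 5% (both
strict), and the DNA:RNA VAF ratio is reported with the RNA VAF floored at
0.5% so silenced alleles do not divide by zero.

Clinical performance treats a sample as *alteration positive* when ≥1
variant or fusion is attributed to it and anchors truth in the
histopathological benign/malignant class; sensitivity, specificity, PPV,
NPV and prevalence come with exact CIs, overall and per stratum.

Because the underlying clinical call sets are proprietary, the package
ships two kinds of inputs: the published report tables re-encoded as
machine-readable fixtures, and a seeded synthetic-cohort generator
(`varconcord.cohort`) that draws matched ground truth (true DNA VAF,
expression fraction, fusion expression rate) and simulates each platform's
calls read-level (Poisson depth, beta-binomial alt reads, per-call miss
probability, fusion QC gates at 20 supporting / 20,000 valid mapped reads).

## Worked example

```python
from varconcord import ConcordanceCounts, ppa, confirmation

# whole-transcriptome RNA-seq vs targeted DNA panel, variant events:
# 134 detected by both, 47 by the DNA panel only, 2 by RNA-seq only
counts = ConcordanceCounts(n_both=134, n_ref_only=47, n_test_only=2)
print(ppa(counts).format_percent(0))            # 74%[67-80]
print(confirmation(counts).format_percent(1, 0))  # 98.5%[95-100]
```

RNA-seq recovers 74% of DNA-detected variants (95% CI 67–80%), while
98.5% of its own positive calls are corroborated by the DNA panel — the
asymmetry that motivates the allelic-imbalance analysis.

The full report bundle from the packaged fixtures:

```
varconcord report --mode fixtures --seed 1 --out-dir run/
```

writes `concordance.tsv`, `clinical_performance.tsv`, `cooccurrence.tsv`
and `summary.json`. On the 190-nodule histology fixture the overall row is

```
stratum  n    tp fp fn tn  sensitivity  specificity  ppv         npv         prevalence
overall  190  22 36 23 109 49%[34-64]   75%[67-82]   38%[26-52]  83%[75-89]  24%[18-30]
```

i.e. roughly half of histologically malignant nodules carry a detectable
expressed alteration, and a negative result still leaves a ~17% residual
malignancy risk at 24% prevalence — why alteration positivity supplements,
rather than replaces, an expression classifier.

A synthetic end-to-end run (generation → platform simulation → all
analysis stages) uses the same entry point:

```
varconcord report --mode simulate --seed 7 --out-dir sim_run/
```

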