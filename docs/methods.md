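# Methods

## Event identity and harmonization

Cross-platform matching needs a platform-neutral identity per alteration.
Variants are keyed by `(gene symbol, HGVS protein short form)` rather than
genomic coordinate: the validation context reports variants at protein
level throughout, amplicon panels and transcriptome callers agree at that
level even when their genomic representations differ, and no
genomic↔protein conversion is attempted. Keys are case-insensitive on
input and canonical (upper-case gene, enforced `p.` prefix) on output.
Non-coding loci that cannot appear in transcript sequence — the TERT
promoter hotspots, kept in their colloquial DNA notation (`C228T`,
`C250T`) — are flagged `is_expressed_locus=False`; they are never counted
toward RNA-platform positivity and enter only the DNA-side co-occurrence
analysis.

Fusions are matched on the **ordered** 5′/3′ partner pair. A
reverse-orientation call is a different event: the 5′/3′ order is fixed by
the fusion's biology (promoter/kinase topology), and treating `STRN/ALK`
and `ALK/STRN` as equal would silently merge distinct transcripts. Display
names follow reporting convention — alphabetical partner order with exactly
two colloquial overrides, `RET/PTC1` for CCDC6/RET and `RET/PTC3` for
NCOA4/RET — while matching always uses the 5′/3′ identifier.

Two file-level policies are deliberate: a reported VAF may disagree with
`alt/total` by at most 0.005 (covers rounding in exported tables; anything
larger is a data error), and duplicate records for one event collapse to
the maximum-depth record (deterministic, favors the better-measured
observation).

## Agreement statistics

The unit of agreement is the event (sample × key), not the sample, so one
sample carrying two variants contributes two events. PPA and confirmation
are the two conditional detection rates (reference-anchored and
test-anchored). NPA needs a denominator of true negatives, which a
positive-calls-only file cannot supply; we define negatives as
(sample, panel-target) pairs where the reference is negative, requiring an
explicit panel of assayable keys. With hundreds of targets per sample this
denominator is large, which is why NPA prints as 100% with a degenerate CI
even when a handful of test-only events exist.

Confidence intervals are two-sided Clopper–Pearson, computed from the beta
quantile function (scipy); at the boundaries the closed forms
`high = 1 − (α/2)^{1/n}` at x=0 and `low = (α/2)^{1/n}` at x=n hold
exactly. The test suite verifies the implementation against an independent
implementation (statsmodels `proportion_confint(method="beta")`) and
checks exact coverage ≥ 95% over all n ≤ 30 by summing the binomial pmf —
no Monte-Carlo noise.

Report tables round half away from zero: whole percent for PPA/NPA and
performance metrics, one decimal for confirmation, mirroring how such
tables are printed. Discordant events can be adjudicated against a third
(arbiter) method, typically qPCR: each discordant event is labelled
`test_correct` / `reference_correct` by whether the arbiter agrees with
the side that called it, and `unresolved` when the arbiter did not assay
that sample.

## Allelic-expression imbalance

If the variant-bearing allele is transcribed at relative rate *e* (1 =
balanced, 0 = silenced), a DNA VAF *v* implies an expected RNA VAF
`r = e·v / (e·v + (1 − v))` — monotone in both arguments, identity at
e = 1. The classification rule for an imbalanced record is threshold-based
(DNA VAF > 10% and RNA VAF < 5%, both strict), applied only to records
with adequate RNA coverage. Three numerical choices are configurable:

- **minimum RNA depth 50 reads** — below this the RNA VAF is too noisy to
  distinguish low expression from sampling zeros, so the record is
  excluded before classification (the exclusion threshold is not stated in
  the validation context; 50 gives a VAF standard error ≲ 3 percentage
  points at the 5% boundary);
- **RNA VAF floor 0.005** for the DNA:RNA ratio — prevents division by
  zero for silenced alleles and caps the ratio at `v/0.005`;
- the ratio cutoff **10** used when summarizing how many imbalanced
  records show strong bias.

For parameter recovery the package also inverts the model:
`ê = r(1 − v) / (v(1 − r))` estimates the expression fraction of each
paired record directly, which separates the generator's low-expression
component (e ≤ 0.1) from balanced records far more cleanly than the
threshold rule and is what the acceptance computation uses to recover the
planted imbalance fraction.

## Reproducibility metrics

Reproducibility is qualitative: agreement requires identity of the
canonical key, never VAF closeness. Because the denominators of published
reproducibility percentages for this kind of assay are typically not
defined precisely, we adopt the standard symmetric definitions and
document them:

- **between-lab accuracy** — fraction of expected positives detected in
  *both* labs; under independent per-call miss probability *m* this equals
  (1 − m)² in expectation (a sample-level tally is also available);
- **replicate concordance** — pooled pairwise agreement over expected
  positives: within-plate pairs (intra) or cross-plate pairs (inter),
  where a pair agrees when both replicates call the event or both miss it;
  under independent misses this equals m² + (1 − m)².

The printed values from the original validation (86–94%) are therefore
calibration context rather than exact targets: they cannot be recomputed
without the proprietary plated samples, but the closed forms above are
verified by simulation, and a planted reagent-lot effect (a per-event,
per-plate failure shared by all replicates on the plate) strictly lowers
inter-plate relative to intra-plate concordance, as it must.

## Clinical performance

Truth is the histopathological class; follicular and well-differentiated
tumors of uncertain malignant potential (FT-UMP, WDT-UMP) are grouped with
the benign subtypes, matching how the per-nodule table organizes them (a
config switch can reassign them). Samples without a definitive benign or
suspicious classifier call (no-result) are excluded from performance sets.
Positivity uses all calls by default; the `suppress_gsc_benign` reporting
rule reproduces clinical reporting, where alterations in classifier-benign
nodules are not released. The 2×2 test of independence is Pearson
chi-square with Yates continuity correction on by default — the convention
of the R environment such analyses are usually run in, and the choice that
reproduces the printed p = 0.003 for the positivity-by-malignancy table;
without correction the value differs.

One documented inconsistency: the per-nodule enumeration of the 190-nodule
cohort implies 36 alteration-positive benign nodules (specificity
109/145 = 75.2%), while the accompanying prose implies 35 (76%).
Sensitivity, PPV, NPV and prevalence are unaffected; specificity is
reported but pinned only to the 74–77% range in tests.

## The synthetic cohort generator

The generator defines the study conditions under which all simulation
tests run; its defaults are fixed, not tuned per test:

| parameter | default | rationale |
|---|---|---|
| cohort size | 500 | order of the validation's primary evaluation sets |
| Bethesda mixture | II/III/IV/V/VI = .05/.45/.30/.10/.10 | indeterminate-heavy FNA stream |
| malignancy by Bethesda | .05/.20/.25/.70/.95 | canonical malignancy risk gradient |
| variant prevalence | 49% malignant / 24% benign | alteration-positive fractions of the histology cohort |
| fusion prevalence | 5% | observed fusion rate in the large consecutive series |
| imbalance fraction | 5% | ~6 strongly biased samples among ~100 DNA-positive pairs |
| imbalanced component | e ~ U(0, 0.1) | strong wild-type bias; the phenomenon, not a fitted distribution |
| balanced component | e ~ LogNormal(0, 0.35) | biological + technical spread around balanced expression |
| true DNA VAF | U(0.05, 0.50) | somatic VAFs in heterogeneous FNA material |
| beta-binomial ρ | 0.01 | avoids unrealistically tight binomial VAFs |
| depths | DNA 500×, targeted RNA 300×, transcriptome 100× | order-of-magnitude platform defaults, config-exposed |
| per-call miss | 2% | residual pipeline/handling losses |
| fusion QC gates | ≥20 supporting reads, ≥20,000 valid mapped reads | the fusion caller's stated thresholds |

Platform simulation is read-level (Poisson depth, beta-binomial alt
reads), so detection near thresholds is genuinely stochastic: DNA variants
just above a 5% VAF cutoff are sometimes missed on 100× transcriptome
coverage, which is what makes PPA at a 20% DNA cutoff exceed PPA at 5% in
expectation — the qualitative behaviour the analysis is designed to
measure. Targeted panels can emit *measurement* records for loci below the
calling threshold (`include_uncalled=True`), reflecting that an amplicon
panel reports coverage and VAF at known loci regardless of call status;
the imbalance pairing consumes these.

What the generator does **not** emulate: read-level sequence content and
sequencer error profiles, locus-specific expression levels (one expression
fraction per variant, no gene effects), batch/RIN quality covariates, and
multi-variant clonal structure (at most one panel variant per sample plus
an optional promoter companion). Passing tests therefore demonstrate the
correctness of the statistics and the detection model's qualitative
behaviour, not calibration against any particular sequencing chemistry.

Replicate simulation is deliberately simpler — per-replicate Bernoulli
detection with an optional lot effect — because the reproducibility
metrics are qualitative and their closed forms make exact verification
possible at that level.

## Determinism and problem sizes

All randomness flows through integer-seeded numpy generators; re-running
any pipeline or CLI entry point with the same configuration and seed is
byte-identical (the config digest excludes the output directory). Test and
acceptance problem sizes — cohorts of 250–800 samples, 10–20 seed
replicates, 1,500–2,000 events for closed-form checks — were chosen so
that Monte-Carlo standard errors are small relative to the tolerances
being asserted while the full suite completes in seconds.

## Known limitations

- NPA depends entirely on the declared panel size; without a panel file it
  is undefined rather than silently approximated.
- The threshold rule for imbalance is insensitive to imbalanced variants
  whose DNA VAF is ≤ 10%, and mildly biased at high VAFs; the model-based
  estimator `ê` is preferred for recovery, the threshold rule for
  comparability with the published analysis.
- Replicate-concordance CIs treat pooled pairs as independent, which they
  are not (pairs share replicates); the point estimates are unaffected.
- Whether the original six-sample imbalance classification used exactly
  the >10%/<5% rule or also the ratio is not stated; both the rule outcome
  and the ratio summary are reported.
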