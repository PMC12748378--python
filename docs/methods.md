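# Methods

This note records the statistical conventions the package implements, the
design choices made where the analysis recipe is genuinely underdetermined,
what the synthetic generators do and do not emulate, and the problem sizes
the test suite and `scripts/acceptance.py` run at.

## Cohort copy-number profiling

An alteration table holds one row per patient (unique `patient_id`; one
representative sample per patient) with stratum labels (`site`,
`histology`, `sample_type`) and per-gene integer copy-number calls in
GISTIC convention (−2..+2) plus boolean pathogenic-mutation flags.

* **Amplification call.** A gene is amplified iff its call is ≥ +2.
  Patients with a missing call for the anchor gene are excluded from both
  numerator and denominator; the exclusion count is logged.
* **Rates.** `amplification_rate(k, n)` reports the exact percentage
  100·k/n and a two-decimal value rounded **half-to-even** via exact
  decimal arithmetic (so 0.125 % → 0.12, 0.375 % → 0.38). Half-to-even at
  two decimals reproduces all the conventional printed rate presentations
  the test suite pins (e.g. 463/4703 → 9.84).
* **Between-stratum test.** Chi-square without continuity correction on
  the strata × {amplified, not} table. For 2×2 tables with any expected
  cell < 5, Fisher's exact test is substituted; larger tables with small
  expected cells keep the chi-square p but log a warning. A single stratum
  yields rates only (p = None). A table whose amplified column is entirely
  zero is trivially homogeneous (p = 1, logged).
* **Co-alterations.** Among anchor-amplified cases, the frequency of
  co-amplification (call ≥ +2) per copy-number gene and of pathogenic
  mutation per flagged gene, sorted by descending frequency with
  lexicographic tie-break. The anchor is excluded from its own table.

## Single-cell stratification and differential expression

* **QC.** Keep cells with 50 ≤ detected genes ≤ 9,000 and mitochondrial
  fraction ≤ 0.15 (strictly greater removed). Idempotent; removal counts
  logged per criterion.
* **Normalization.** Counts per cell scaled to 10,000 and log1p-transformed.
  A zero-total cell is an error naming the cell, never a silent NaN row.
* **Quartile stratification.** Within each sample, the log-normalized
  anchor expression of that sample's epithelial cells is z-scored
  ("scaled"), and cells at or above the 75th percentile are labeled high,
  at or below the 25th percentile low, everything else excluded.
  Percentiles use linear interpolation (numpy default, the "type 7"
  convention): eight cells valued 1..8 give q25 = 2.75, q75 = 6.25, so the
  top two and bottom two cells form the groups. Closed bounds mean ties at
  a percentile fall **into** the high/low groups, which can inflate group
  sizes above n/4 on discrete data. Samples with fewer than 4 epithelial
  cells or a degenerate (constant, or q25 = q75) anchor distribution are
  skipped with a warning. The scaling mode is configurable
  (`zscore` | `none`), as is global rather than per-sample stratification;
  per-sample z-scoring is the default because quartiles must be comparable
  within sample.
* **Differential expression.** For each gene detected (nonzero) in ≥ 3
  cells across the pooled groups: `avg_log2FC` is the log2 ratio of
  pseudocounted (pseudocount 1) group means of the **linear-scale**
  normalized expression (expm1 of the log-normalized values) — the
  convention of standard marker tests. Computing the fold change on the
  logged values instead would bound it near ~1 for realistic shifts and
  make the |avg_log2FC| > 2 threshold unreachable even for a planted
  8-fold gene, so the linear-scale reading is used and recorded here.
  The p-value is a two-sided Wilcoxon rank-sum test: exact enumeration of
  the permutation null (average ranks for ties) when both groups have ≤ 10
  cells, otherwise a tie-corrected normal approximation with continuity
  correction (agrees with the exact p within 0.02 on tie-free samples at
  those sizes; heavy ties at tiny n can widen the gap — an intrinsic
  property of doubling an asymmetric exact tail). BH adjustment runs
  across tested genes; a gene passes iff |avg_log2FC| > 2 and q < 0.05.
  The |avg_log2FC| > 2 cutoff is unusually strict for scRNA-seq; it is
  implemented verbatim and exposed in configuration.
* **BH.** `bh_adjust` is the step-up procedure
  q₍ᵢ₎ = min_{j ≥ i} p₍ⱼ₎·m/j capped at 1, returned in input order
  (delegated to statsmodels; the test suite checks it against a
  from-definition oracle).

## Spatial proximity framework

Sections carry spot-by-gene values (raw counts or pre-normalized — every
statistic is threshold- or rank-based) and continuous x,y coordinates;
grid row/col indices are reporting metadata only.

* **High-expression region.** Threshold = the (1 − top_fraction) linear
  interpolation quantile of a gene's values over all spots (top_fraction
  0.25 by default); members are spots at or above it. If the threshold
  equals the gene's minimum the mask would be all spots and carries no
  localization signal; the gene is skipped with reason
  `uninformative-distribution` rather than given p = 1. This also skips
  genes expressed in too few spots for a top-quartile mask to separate.
* **Proximity statistic.** D_obs = mean over the test gene's high spots of
  the Euclidean distance to the nearest anchor-high spot (directional;
  a spot in both masks contributes 0). The directional mean-NN form is a
  design choice made for interpretability and monotone response to planted
  colocalization; the underlying recipe names only "Euclidean
  distance"-based analysis, so this form must not be attributed beyond
  this package.
* **Permutation null.** The anchor mask is held fixed; the test gene's
  values are shuffled across spots B times (preserving the value multiset
  and hence the mask size) and D recomputed. Shuffling *expression values*
  rather than permuting coordinates jointly is deliberate: a joint
  coordinate permutation preserves spot-level coupling between the two
  genes and can never reject a gene co-expressed in the very spots that
  are anchor-high. The joint mode is retained behind
  `null_mode="coordinates"` for comparison. Empirical
  p = (1 + #{D_b ≤ D_obs})/(1 + B) — never zero. For sections of ≤ 8
  spots, `exhaustive=True` enumerates all n! value permutations (the
  4-spot worked example gives p = 19/25 = 0.76). A secondary one-sided
  Mann–Whitney U test compares observed per-spot distances against
  per-spot distances pooled from the first 50 permutations (capping the
  pooled control keeps the rank test linear in the mask size; the
  empirical p always uses all B permutations). The Mann–Whitney p is
  exact by enumeration when both samples have ≤ 8 values, otherwise a
  tie-corrected normal approximation.
* **Genome screen.** Per section, every non-anchor gene with a valid mask
  gets a permutation null; empirical p-values are BH-adjusted across genes
  within the section. A gene is *consistent* iff it was testable in every
  section and q ≤ α (0.05) in all of them — a gene skipped anywhere is
  never consistent. Consistent genes are ranked by mean D_obs ascending,
  ties lexicographic. "Consistently close" has no quantitative definition
  in the underlying recipe; this conjunction-over-sections rule is the
  package's own.
* **Determinism.** One seed per screen; per-(section, gene) RNG
  sub-streams derive from a stable 64-bit hash, so results are independent
  of gene iteration order and of adding other genes.
* **Invariances.** All statistics are invariant to rigid motions of the
  coordinates; distances scale linearly and p-values are invariant under
  coordinate scaling (property-tested).
* **Spearman colocalization** uses average ranks for ties and returns NaN
  (an explicit undefined flag) when either gene has zero variance.

## Overrepresentation

Hypergeometric upper tail P(X ≥ k) for overlap k between the deduplicated
query (intersected with the universe) and each set, BH across all sets in
the collection, significance at q < 0.05. The universe defaults to the
union of set members — the background any collection carries implicitly —
and the choice ("declared" vs "union-of-sets") is recorded on the
collection and echoed in CLI output. Only enrichment (one-sided) is
tested. Any "top 10" truncation is display-layer only; stored tables are
complete.

## Synthetic-data generators

The generators define the study conditions for every test; they are
deliberately simple and their limitations are stated here.

* **Noise model.** Negative binomial via a gamma–Poisson mixture
  (variance = μ + μ²/θ, dispersion θ = 2 by default), the standard
  overdispersion convention for droplet counts. No distributional
  description of the emulated data exists, so the NB choice (and every
  other noise parameter) is a stand-in: downstream tests are rank- and
  threshold-based and need only ordinal structure.
* **Cohort.** One row per patient; the anchor call is +2 with the
  stratum's probability, 0 otherwise; co-amplifications and co-mutations
  are drawn from probabilities conditional on the anchor state. The
  default calibration emulates a 12,845-patient multi-institution
  gynecologic registry with the stratum rates such registries report
  (e.g. uterine carcinosarcoma 122/795 ≈ 15.3%, HGSOC 463/4703 ≈ 9.8%,
  cervical subtypes < 1%). Note the printed overall figure usually quoted
  for such cohorts (≈ 8.4%) is *not* the pooled expectation of these
  strata (≈ 6.3%); the stratum-level calibration is authoritative here and
  the pooled rate is whatever the strata imply.
* **Cells.** Per sample: epithelial cells drawn at `epithelial_fraction`;
  a `high_subpop_fraction` subset of them carries the anchor shifted by
  `anchor_log2_shift` (default +3) and each planted DEG shifted by its
  stated log2 fold change, acting multiplicatively on the NB mean. The
  anchor's baseline mean is fixed (default 2.0) rather than drawn from the
  lognormal spread used for background genes, because quartile
  stratification presupposes an expressed anchor — a mostly-zero anchor
  makes the within-sample quartiles degenerate, which the pipeline then
  rightly skips. Planted fold changes are diluted downstream by the
  imperfect overlap between the anchor-high quartile and the true high
  subpopulation; at default noise a +3 planted gene measures ≈ 2–2.5 in
  `avg_log2FC`, at near-Poisson noise (dispersion 20) ≈ 2.8.
* **Spatial.** Spots on a rows × cols unit grid (or explicit coordinates);
  a circular niche (default radius covering ≈ 30% of spots — comfortably
  above the 25% mask fraction so a strong partner's high region can
  coincide with the niche) multiplies the NB mean of the anchor
  (strength 3 → 8-fold) and each partner gene (2^strength) inside the
  niche; background genes are spatially exchangeable. `noise="none"`
  emits the mean surface exactly for geometric edge-case tests.
* **Determinism.** Identical config + seed ⇒ byte-identical output; RNG
  sub-streams per stratum / sample / section derive from stable label
  hashes, so adding a unit never perturbs existing ones.
* **Not emulated.** Ligand–receptor signaling, immune composition, batch
  effects, segmentation/annotation error, histology, spot deconvolution,
  inter-panel calling variability. Passing tests demonstrate correctness
  of the statistical machinery under the planted model, not performance on
  real tissue.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so the
planted effects sit well inside the power of the tests: null-calibration
sections of 20×20 = 400 spots with 50 exchangeable genes at B = 200 over
20 seeds; planted-partner screens with two sections, 61 test genes,
partner strength 2, B = 2,000 over 20 seeds (B is set so the smallest
attainable empirical p, 1/(B+1), survives BH across 61 genes at α = 0.05);
DE null runs with 500 genes and 200 cells per group; exhaustive
permutation checks on ≤ 6-spot sections against B = 10,000 Monte-Carlo
draws. Floating point in tables is written at 6 significant digits; rates
additionally at the half-even 2-decimal convention described above.

## Known limitations

* The directional proximity statistic is asymmetric; a symmetric variant
  (max of both directions) exists but is not the default.
* The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and is capped at
  group sizes 10 (cells) / 8 (distances); above that the normal
  approximation's accuracy degrades gracefully but is not exact.
* Empirical p-values are discrete at resolution 1/(B+1); BH on them is
  conservative.
* Co-alteration output is format-complete but its frequencies depend
  entirely on the configured conditional probabilities; no external
  denominators exist to validate against.
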