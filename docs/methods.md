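# Methods

This note records the model behind `pamcross`, the choices made where the
procedure was genuinely open, and what the synthetic study conditions do and
do not establish about real data.

## Expression model and the synthetic study conditions

The generator emulates log-scale expression of a subtype classifier panel.
Each subtype s has a centroid μ_s ∈ R^G with entries drawn as
`separation × N(0, 1)` (seeded), so the mean pairwise centroid distance is
exactly proportional to the `separation` parameter and `separation = 0`
collapses all classes. A sample of latent subtype s is μ_s + ε,
ε ~ N(0, noise_sd² I) i.i.d. across genes, optionally followed by an affine
per-platform distortion x ↦ scale·x + offset. Gaussian noise on the log
scale is the standard microarray assumption; within-subtype covariance
across genes is **not** modeled (independence), and no probe-level
artifacts, batch trends beyond the affine shift, or tumor-purity effects
exist in the simulation. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the stated noise model, not robustness to
every distortion of real array data.

Standard conditions used throughout the tests and the acceptance script,
chosen once as field-realistic values:

| parameter | default | rationale |
|---|---|---|
| panel | 50 genes, 42 retained | working panel after 1:1 ortholog filtering (6% ambiguous + 10% unmapped) |
| subtypes | LumA, LumB, Her2, Basal, Normal | the five intrinsic classes |
| base prior | .35/.20/.10/.15/.20 | approximate human cohort subtype frequencies |
| separation / noise_sd | 2.0 / 1.0 | per-gene signal-to-noise 2; classes separable but single genes uninformative |
| reference | 12 per subtype (60) | small labeled cohort |
| marker map | 500 markers, 19 chromosomes × 100 Mb | medium-density linkage panel |
| recombination | 0.01 per Mb, capped at 0.5 | ~1 cM/Mb genome average |
| platform shift | offset 2.0, scale 1.5 | exercises the normalization stage |
| metastasis incidence | 76/166 (backcross-like), 72/124 (outbred-like) | observed cross incidences |

## Normalization

The merged matrix is unitized with zero mean: per group, subtract the mean
and divide by the maximum absolute deviation, giving values in [−1, 1] with
group mean 0 and max |value| exactly 1. This is the member of the
unitization family whose output range is [−1, 1]. Two scopes exist; the
default normalizes each gene **within each dataset block**, because that
scope removes any affine per-platform transform exactly (proved as a
property test). `per_gene_global` is available for sensitivity analyses.
Numerical guards: a group whose spread is below 1e-12 relative to its
magnitude is treated as constant and mapped to zeros (otherwise float
rounding of the mean of equal values can blow up to ±1).

## Label transfer

Distances are 1 − Pearson correlation over the panel (the convention of the
clustering/heatmap tools used for this kind of data); Euclidean distance is
a config option. Trees are complete-linkage; cutting at k undoes the last
k−1 merges. Three aspects of the procedure were open and are fixed as
follows, all config-exposed:

- **Qualification threshold**: a cluster contributes only if it has strictly
  more than `min_ref = 4` reference members ("more than 4" read literally as
  ≥ 5).
- **Aggregation across cuts**: the per-cut qualifying proportion vectors are
  combined by unweighted mean. This is the simplest estimator consistent
  with treating cluster proportions as probabilities; the per-sample count
  of contributing cuts is recorded so alternative weightings can be audited.
- **Ties**: argmax ties are broken lexicographically by label name (flagged
  per sample), or the sample can be left unassigned (`tie_rule="unassign"`).
  Equal-distance merge ties are resolved by scipy's deterministic linkage
  order; with continuous expression values exact ties have probability zero,
  and the brute-force oracle test covers the generic case.

Query cohorts are co-clustered with the reference one dataset at a time in
the pipeline (a joint mode is possible by merging more blocks). The
comparator is a generic nearest-centroid classifier trained on the labeled
reference (per-label mean profile, correlation similarity) — not a
re-implementation of any published centroid set.

## Planted-locus model

A planted locus tilts the latent subtype prior as a mixture:
p′ = (1 − w·e)·p + w·e·δ_target, where w is the carrier weight (1 for a
heterozygote in a backcross; dosage/2 of the risk founder in an outbred
design) and e ∈ [0, 1] the effect. Equivalently: with probability w·e the
carrier's subtype is forced to the target. This makes effect 1 fully
penetrant, keeps probabilities normalized, and gives carriers a target
frequency of b + e(1 − b) from base frequency b — the simplest mechanism
that yields a detectable categorical association. For a target *set*, the
forced mass is spread proportionally to the base probabilities within the
set.

## Association tests

- **Backcross**: two-sided exact conditional (hypergeometric) test on the
  2×2 genotype × phenotype table. The two-sided p sums all tables with the
  observed margins whose point probability is ≤ the observed one, compared
  with relative tolerance 1e-12; when every table qualifies the p-value is
  exactly 1. Monomorphic markers get p = 1 and a flag. A chi-square variant
  (`backcross_test="chisq"`) exists; note the exact test's null p-values are
  discrete and conservative (point mass at 1 from the modal table), so
  uniformity diagnostics should use the chi-square variant.
- **Outbred**: ordinary least squares of the binary phenotype on founder
  dosages. The dosage sum-to-2 constraint absorbs one founder column;
  further collinear columns are dropped (flagged). The p-value is the
  overall F-test against the intercept-only model; attribution is the
  founder with the largest coefficient after centring effects to mean zero
  (which makes the attribution invariant to the dropped baseline). A perfect
  fit is floored at p = 1e-300 to stay inside (0, 1].
- **FDR**: Benjamini–Hochberg step-up within each scan (not across
  phenotypes), the field default when an FDR is printed without a named
  procedure. Scans are reported in natural chromosome order ("2" < "10").
- **Metastasis independence**: chi-square statistic Σ(O−E)²/E on the
  subtype × metastasis table over assigned samples; if any expected cell is
  below 5 the p-value comes instead from 10,000 seeded permutations of the
  metastasis labels (same statistic, margins fixed, computed vectorized).
  The permutation p uses the add-one estimator (1+#≥)/(1+B) and is slightly
  conservative.

Unassigned samples are excluded listwise from phenotype vectors, with the
count logged; whether ambiguous tumors should instead be modeled is left
open.

## Problem sizes

The test suite and acceptance script use 60-sample reference cohorts,
60–200-animal query cohorts, 500-marker scans with 20 replicates, and
200-cohort calibration loops — sizes at which every statistical property
under test (normalization bounds, ≥ 0.90 macro accuracy, ≥ 0.85 comparator
concordance, null-scan cleanliness, planted-locus recovery, p-value
uniformity) is comfortably resolvable while the whole suite runs in well
under a minute of compute per module.

## Known limitations

- Independence of genes within subtype; no correlated noise module yet.
- The founder mosaic is a first-order Markov chain per strand, not a
  pedigree-accurate outbred model; dosages are taken as known rather than
  reconstructed from SNP intensities.
- No kinship/structure correction in the scans and no interval mapping; the
  per-marker tests assume exchangeable animals.
- The nearest-centroid comparator is trained on the synthetic reference, so
  concordance measures internal consistency, not agreement with any
  published classifier's centroids.
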