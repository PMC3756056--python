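# pamcross

Cross-species intrinsic-subtype label transfer and subtype-susceptibility
mapping for transcriptomic tumor cohorts.

## The problem

Breast tumors are stratified into five intrinsic subtypes (luminal A,
luminal B, HER2-enriched, basal-like, normal-like) from the expression of a
~50-gene classifier panel. Mouse mammary tumor models driven by a single
oncogenic event can nonetheless distribute across all five human subtypes,
which suggests that inherited genetic background — not only cell of origin
and somatic mutation — shapes the subtype signature. Testing that idea
requires two things this package provides:

1. **Label transfer across species and platforms.** Mouse tumors carry no
   subtype labels. `pamcross` assigns them probabilistically by clustering
   them *jointly* with a labeled human reference cohort over the orthologous
   classifier genes, then reading labels off the clusters.
2. **Susceptibility mapping.** Given per-animal subtype calls and genotypes
   from a genetic mapping cross, `pamcross` scans the genome for loci whose
   inheritance predicts subtype assignment, with false-discovery-rate
   control.

A synthetic-data module generates reference cohorts, genotype-driven query
cohorts, ortholog tables and metastasis phenotypes with the statistical
structure the analysis assumes, so every stage is testable end to end
without any downloads.

## The method

**Panel harmonization.** The classifier panel is restricted to genes with an
unambiguous 1:1 ortholog in both directions between the two gene namespaces.
Cohorts are column-merged into one matrix and each gene is unitized with
zero mean within each dataset block:

```
x'_gij = (x_gij − mean_j(x_gij)) / max_j |x_gij − mean_j(x_gij)|   ∈ [−1, 1]
```

Per-gene-per-block unitization removes any affine per-platform distortion
exactly, which is why it is the default scope.

**Label transfer by multi-resolution co-clustering.** Samples are clustered
with complete linkage on d(i,j) = 1 − r(i,j) (Pearson correlation over the
panel). The tree is cut into k clusters for every k = 2..20. Within a cut, a
cluster *qualifies* if it holds more than 4 (i.e. ≥ 5) labeled reference
samples; its reference-label distribution is then evidence for its query
members. A query sample's probability vector over subtypes is the unweighted
mean of the qualifying distributions it collects across all cuts:

```
P(subtype = s | query i) = (1 / |K_i|) Σ_{k ∈ K_i} prop_s(cluster_k(i))
```

where K_i is the set of cuts at which sample i's cluster qualifies. Samples
with K_i = ∅ stay unassigned. The argmax gives categorical calls; a generic
nearest-centroid classifier (most-correlated per-label mean reference
profile) serves as the comparator for performance analysis.

**Association mapping.** For an N2 backcross (genotypes hom/het at 1:1),
each marker is tested with a two-sided exact conditional test on the 2×2
table genotype × subtype-membership. For a multi-founder outbred design, the
binary phenotype is regressed on the founder-dosage matrix (dosages sum to 2;
one column dropped) and the overall F-test against the intercept-only model
is reported, with the founder carrying the largest centred coefficient as
the attribution. Benjamini–Hochberg step-up q-values control the FDR across
markers within each scan. A chi-square (or, for sparse tables, permutation)
test checks that subtype calls are independent of metastasis status.

## Worked example

```python
from pamcross.simulate import (make_subtype_centroids, generate_reference_cohort,
                               generate_backcross_genotypes, generate_query_cohort,
                               PlantedLocus)
from pamcross.expression import merge_matrices, normalize_unitization
from pamcross.transfer import SubtypeTransfer
from pamcross.mapping import GenomeScan

base = {"LumA": 0.35, "LumB": 0.20, "Her2": 0.10, "Basal": 0.15, "Normal": 0.20}
centroids = make_subtype_centroids(42, separation=2.0, seed=7)
reference = generate_reference_cohort(centroids, 12, noise_sd=1.0, platform_id="ref", seed=11)
genotypes = generate_backcross_genotypes(200, 500, seed=12)
locus = PlantedLocus(marker_index=249, target_subtype="Basal", effect=0.4)
query = generate_query_cohort(genotypes, [locus], centroids, base,
                              platform_shift=(2.0, 1.5), noise_sd=1.0, seed=13)

merged = normalize_unitization(merge_matrices([reference.expression, query.expression]))
res = SubtypeTransfer(merged, reference.true_labels).fit()
print(res.summary())
print("macro accuracy vs latent truth:", round(res.accuracy(query.true_labels), 3))
scan = GenomeScan.from_calls(genotypes, res.calls, {"Basal"}).fit()
print(scan.summary())
```

prints

```
Subtype label transfer (joint co-clustering)
  metric: one_minus_pearson   linkage: complete
  cuts: k = 2..20   min_ref > 4
  query samples: 200   assigned: 200

  call distribution:
           Basal: 68
            Her2: 13
            LumA: 50
            LumB: 40
          Normal: 29
  median contributing cuts: 16.0
macro accuracy vs latent truth: 1.0
Genome scan (backcross, 500 markers, 200 samples)
  cases: 68   FDR level: 0.05
  significant markers (q <= 0.05): 20
  top marker: m0250 chr10:36.5 Mb p=9.32e-10 q=3.04e-07 (het)
```

All 200 query tumors are assigned, the calls recover the latent subtype
exactly at these noise settings (the query cohort's affine platform shift is
removed by the per-block normalization), and the genome scan's strongest
association is the planted susceptibility marker (m0250 is marker index 249)
together with its linked neighbors on chromosome 10 — the heterozygous
(risk) genotype is enriched among basal-called animals.

The same run is available as a shell pipeline:

```sh
pamcross run-all --out-dir myrun          # simulate → merge → classify → scan → report
pamcross simulate --out-dir myrun         # or stage by stage
```

All stage outputs are plain TSV plus a JSON report; re-running with the same
config and seed reproduces every file byte for byte.

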