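"""Synthetic cohorts with the statistical structure the pipeline assumes.

Emulates, at desk scale, the study design of a transgene-driven mouse mammary
tumor cross profiled alongside labeled human breast-cancer cohorts:

* five intrinsic-subtype classes with distinct expression centroids over a
  ~42-gene panel (i.i.d. Gaussian noise per gene on the log scale),
* per-platform affine location/scale shifts,
* backcross genotypes (hom/het, 1:1) or eight-founder outbred mosaics with
  Markov linkage along each chromosome,
* planted susceptibility loci that tilt a sample's latent subtype prior,
* metastasis phenotypes drawn independently of subtype (the null the
  metastasis-independence test should recover).

Every generator is a pure function of (arguments, seed); there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, OrthologTable

__all__ = [
    "PAM50_SUBTYPES",
    "CentroidSet",
    "SimulatedCohort",
    "PlantedLocus",
    "GenotypeData",
    "uniform_marker_map",
    "make_subtype_centroids",
    "generate_reference_cohort",
    "generate_backcross_genotypes",
    "generate_outbred_genotypes",
    "generate_query_cohort",
    "generate_metastasis_status",
    "build_ortholog_table",
]

#: The five intrinsic breast-cancer subtype names used as the default vocabulary.
PAM50_SUBTYPES: tuple[str, ...] = ("LumA", "LumB", "Her2", "Basal", "Normal")

HOM, HET = 0, 1  # backcross genotype codes


@dataclass
class CentroidSet:
    """Per-subtype mean log-expression vectors over the gene panel.

    ``centroids`` is genes × labels; ``separation`` scales all centroids so the
    mean pairwise Euclidean distance is exactly proportional to it.
    """

    labels: tuple[str, ...]
    centroids: pd.DataFrame
    separation: float

    def __post_init__(self) -> None:
        if list(self.centroids.columns) != list(self.labels):
            raise ValueError("centroid columns must match labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.centroids.index)


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    true_labels: pd.Series  # sample id -> latent subtype
    platform_id: str
    metastasis: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.true_labels.index) != list(self.expression.values.columns):
            raise ValueError("true_labels must be indexed by the expression samples")


@dataclass
class PlantedLocus:
    """A marker whose risk genotype tilts the latent subtype prior.

    ``effect`` in [0, 1] is the mixture weight moved onto ``target_subtype``
    for a full carrier (heterozygote in a backcross; two copies of
    ``risk_founder`` in an outbred design; one copy counts half).
    """

    marker_index: int
    target_subtype: str | tuple[str, ...]
    effect: float
    risk_founder: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"effect must be in [0, 1], got {self.effect}")

    @property
    def targets(self) -> tuple[str, ...]:
        if isinstance(self.target_subtype, str):
            return (self.target_subtype,)
        return tuple(self.target_subtype)


@dataclass
class GenotypeData:
    """Marker genotypes for a backcross or a multi-founder outbred design.

    Backcross: ``codes`` is markers × samples with 0 = homozygous, 1 =
    heterozygous.  Outbred: ``dosages`` is markers × samples × founders and
    sums to 2 over founders at every (marker, sample).
    """

    marker_ids: list[str]
    chrom: np.ndarray
    pos_mb: np.ndarray
    design: str  # "backcross" | "outbred"
    sample_ids: list[str]
    codes: np.ndarray | None = None
    dosages: np.ndarray | None = None
    founder_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.design not in ("backcross", "outbred"):
            raise ValueError(f"unknown design {self.design!r}")
        n_m = len(self.marker_ids)
        if len(self.chrom) != n_m or len(self.pos_mb) != n_m:
            raise ValueError("chrom/pos_mb must match marker_ids")
        for c in pd.unique(np.asarray(self.chrom)):
            p = np.asarray(self.pos_mb)[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not nondecreasing on chromosome {c!r}")
        if self.design == "backcross":
            if self.codes is None or self.codes.shape != (n_m, len(self.sample_ids)):
                raise ValueError("backcross design requires codes of shape (markers, samples)")
        else:
            if self.dosages is None or self.founder_ids is None:
                raise ValueError("outbred design requires dosages and founder_ids")
            if self.dosages.shape != (n_m, len(self.sample_ids), len(self.founder_ids)):
                raise ValueError("dosages must be (markers, samples, founders)")
            if not np.all(self.dosages.sum(axis=2) == 2):
                raise ValueError("founder dosages must sum to 2 at every (marker, sample)")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def uniform_marker_map(
    n_markers: int, n_chromosomes: int = 19, chrom_length_mb: float = 100.0
) -> pd.DataFrame:
    """Evenly spaced marker map over autosome-like chromosomes.

    Markers are split as evenly as possible across chromosomes named
    "1".."n_chromosomes", each of length ``chrom_length_mb``, and placed at
    midpoints of equal intervals.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    base, extra = divmod(n_markers, n_chromosomes)
    rows = []
    for c in range(n_chromosomes):
        m = base + (1 if c < extra else 0)
        if m == 0:
            continue
        spacing = chrom_length_mb / m
        for i in range(m):
            rows.append((str(c + 1), (i + 0.5) * spacing))
    return pd.DataFrame(rows, columns=["chrom", "pos_mb"])


def make_subtype_centroids(
    n_genes: int,
    labels: tuple[str, ...] = PAM50_SUBTYPES,
    separation: float = 2.0,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> CentroidSet:
    """Draw one centroid per subtype, scaled so distances ∝ ``separation``.

    Each centroid entry is ``separation`` × a standard normal draw, so doubling
    ``separation`` (same seed) exactly doubles every pairwise distance, and
    ``separation = 0`` collapses all centroids to the origin.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    labels = tuple(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 subtype labels")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate subtype labels")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_genes, len(labels)))
    if gene_ids is None:
        gene_ids = [f"G{i + 1:03d}" for i in range(n_genes)]
    cent = pd.DataFrame(separation * raw, index=gene_ids, columns=list(labels))
    return CentroidSet(labels=labels, centroids=cent, separation=float(separation))


def _apply_shift(values: np.ndarray, platform_shift: tuple[float, float]) -> np.ndarray:
    offset, scale = platform_shift
    return values * scale + offset


def generate_reference_cohort(
    centroids: CentroidSet,
    n_per_subtype: int,
    noise_sd: float = 1.0,
    platform_id: str = "ref",
    seed: int = 0,
    platform_shift: tuple[float, float] = (0.0, 1.0),
) -> SimulatedCohort:
    """Labeled cohort: each sample is its subtype centroid plus Gaussian noise."""
    if n_per_subtype < 1:
        raise ValueError("n_per_subtype must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    cols, labels = [], []
    n_genes = len(centroids.gene_ids)
    for lab in centroids.labels:
        mu = centroids.centroids[lab].to_numpy()
        for _ in range(n_per_subtype):
            cols.append(mu + noise_sd * rng.standard_normal(n_genes))
            labels.append(lab)
    values = _apply_shift(np.column_stack(cols), platform_shift)
    sample_ids = [f"{platform_id}_s{i + 1:03d}" for i in range(len(labels))]
    df = pd.DataFrame(values, index=centroids.gene_ids, columns=sample_ids)
    expr = ExpressionMatrix(df, species="a", platform_id=platform_id, dataset_id=platform_id)
    truth = pd.Series(labels, index=sample_ids, name="subtype")
    return SimulatedCohort(expression=expr, true_labels=truth, platform_id=platform_id)


def generate_backcross_genotypes(
    n_samples: int,
    n_markers: int | None = None,
    chrom_map: pd.DataFrame | None = None,
    seed: int = 0,
    recomb_rate_per_mb: float = 0.01,
) -> GenotypeData:
    """N2-backcross genotypes: hom/het at 1:1, Markov linkage within chromosomes.

    Along each chromosome the genotype switches between consecutive markers
    with probability min(0.5, rate × distance).  Different chromosomes are
    independent.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if chrom_map is None:
        if n_markers is None or n_markers < 1:
            raise ValueError("provide n_markers >= 1 or a chrom_map")
        chrom_map = uniform_marker_map(n_markers)
    chrom = chrom_map["chrom"].to_numpy(dtype=object)
    pos = chrom_map["pos_mb"].to_numpy(dtype=float)
    n_m = len(chrom)
    rng = np.random.default_rng(seed)
    codes = np.empty((n_m, n_samples), dtype=np.int8)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        codes[idx[0]] = rng.integers(0, 2, size=n_samples)
        for prev, cur in zip(idx[:-1], idx[1:]):
            r = min(0.5, recomb_rate_per_mb * (pos[cur] - pos[prev]))
            flip = rng.random(n_samples) < r
            codes[cur] = np.where(flip, 1 - codes[prev], codes[prev])
    marker_ids = [f"m{i + 1:04d}" for i in range(n_m)]
    sample_ids = [f"bc_s{i + 1:04d}" for i in range(n_samples)]
    return GenotypeData(
        marker_ids=marker_ids, chrom=chrom, pos_mb=pos, design="backcross",
        sample_ids=sample_ids, codes=codes,
    )


def generate_outbred_genotypes(
    n_samples: int,
    n_markers: int | None = None,
    n_founders: int = 8,
    chrom_map: pd.DataFrame | None = None,
    seed: int = 0,
    switch_rate_per_mb: float = 0.01,
) -> GenotypeData:
    """Outbred founder mosaics: two haplotype strands per sample and chromosome.

    Each strand starts from a uniform founder and, between consecutive markers,
    is redrawn uniformly with probability min(0.5, rate × distance) — so a
    switch rate of 0 leaves each chromosome a single-founder-pair block.
    Founder dosages (counts over the two strands) sum to 2 everywhere.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if chrom_map is None:
        if n_markers is None or n_markers < 1:
            raise ValueError("provide n_markers >= 1 or a chrom_map")
        chrom_map = uniform_marker_map(n_markers)
    chrom = chrom_map["chrom"].to_numpy(dtype=object)
    pos = chrom_map["pos_mb"].to_numpy(dtype=float)
    n_m = len(chrom)
    rng = np.random.default_rng(seed)
    strands = np.empty((2, n_m, n_samples), dtype=np.int8)
    for h in range(2):
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            strands[h, idx[0]] = rng.integers(0, n_founders, size=n_samples)
            for prev, cur in zip(idx[:-1], idx[1:]):
                r = min(0.5, switch_rate_per_mb * (pos[cur] - pos[prev]))
                redraw = rng.random(n_samples) < r
                fresh = rng.integers(0, n_founders, size=n_samples)
                strands[h, cur] = np.where(redraw, fresh, strands[h, prev])
    dosages = np.zeros((n_m, n_samples, n_founders), dtype=np.int8)
    for h in range(2):
        np.add.at(dosages, (np.arange(n_m)[:, None], np.arange(n_samples)[None, :], strands[h]), 1)
    marker_ids = [f"m{i + 1:04d}" for i in range(n_m)]
    sample_ids = [f"do_s{i + 1:04d}" for i in range(n_samples)]
    founder_ids = [f"F{j + 1}" for j in range(n_founders)]
    return GenotypeData(
        marker_ids=marker_ids, chrom=chrom, pos_mb=pos, design="outbred",
        sample_ids=sample_ids, dosages=dosages, founder_ids=founder_ids,
    )


def _locus_carrier_weight(genotypes: GenotypeData, locus: PlantedLocus, sample: int) -> float:
    if not 0 <= locus.marker_index < genotypes.n_markers:
        raise ValueError(f"marker_index {locus.marker_index} outside the marker map")
    if genotypes.design == "backcross":
        return float(genotypes.codes[locus.marker_index, sample] == HET)
    if locus.risk_founder is None:
        raise ValueError("outbred planted locus requires a risk_founder")
    return float(genotypes.dosages[locus.marker_index, sample, locus.risk_founder]) / 2.0


def tilt_probabilities(
    base: np.ndarray, labels: tuple[str, ...], locus: PlantedLocus, weight: float
) -> np.ndarray:
    """Mix a fraction ``weight × effect`` of probability mass onto the targets.

    p' = (1 - w·e)·p + w·e·t where t is the base distribution restricted and
    renormalized to the target set (a point mass for a single target).  A full
    carrier with effect 1 is therefore deterministically in the target set.
    """
    e = weight * locus.effect
    if e == 0.0:
        return base
    targets = locus.targets
    t_idx = [labels.index(t) for t in targets]
    t_mass = base[t_idx].sum()
    t = np.zeros_like(base)
    if t_mass > 0:
        t[t_idx] = base[t_idx] / t_mass
    else:
        t[t_idx] = 1.0 / len(t_idx)
    return (1.0 - e) * base + e * t


def generate_query_cohort(
    genotypes: GenotypeData,
    loci: list[PlantedLocus],
    centroids: CentroidSet,
    base_probs,
    platform_shift: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 1.0,
    platform_id: str = "query",
    seed: int = 0,
    gene_id_map: dict[str, str] | None = None,
) -> SimulatedCohort:
    """Unlabeled cohort whose latent subtype is tilted by planted loci.

    Per sample, the latent subtype is drawn from ``base_probs`` after mixing in
    each carried locus's effect (see :func:`tilt_probabilities`); expression is
    the latent centroid plus Gaussian noise, then the affine platform shift.
    ``gene_id_map`` optionally renames panel genes into the query namespace.
    """
    labels = centroids.labels
    if isinstance(base_probs, dict):
        base = np.array([base_probs[lab] for lab in labels], dtype=float)
    else:
        base = np.asarray(base_probs, dtype=float)
    if base.shape != (len(labels),):
        raise ValueError("base_probs must give one probability per subtype label")
    if np.any(base < 0) or abs(base.sum() - 1.0) > 1e-8:
        raise ValueError("base_probs must be nonnegative and sum to 1 (tolerance 1e-8)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    n_genes = len(centroids.gene_ids)
    cent = centroids.centroids.to_numpy()
    values = np.empty((n_genes, n))
    latent = []
    for s in range(n):
        probs = base.copy()
        for locus in loci:
            w = _locus_carrier_weight(genotypes, locus, s)
            probs = tilt_probabilities(probs, labels, locus, w)
        lab_idx = rng.choice(len(labels), p=probs)
        latent.append(labels[lab_idx])
        values[:, s] = cent[:, lab_idx] + noise_sd * rng.standard_normal(n_genes)
    values = _apply_shift(values, platform_shift)
    gene_ids = centroids.gene_ids
    if gene_id_map is not None:
        gene_ids = [gene_id_map.get(g, g) for g in gene_ids]
    df = pd.DataFrame(values, index=gene_ids, columns=genotypes.sample_ids)
    expr = ExpressionMatrix(df, species="b", platform_id=platform_id, dataset_id=platform_id)
    truth = pd.Series(latent, index=genotypes.sample_ids, name="subtype")
    return SimulatedCohort(expression=expr, true_labels=truth, platform_id=platform_id)


def generate_metastasis_status(n: int, incidence: float, seed: int = 0) -> pd.Series:
    """I.i.d. Bernoulli metastasis indicators, independent of subtype."""
    if not 0.0 <= incidence <= 1.0:
        raise ValueError(f"incidence must be in [0, 1], got {incidence}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    status = (rng.random(n) < incidence).astype(int)
    return pd.Series(status, name="metastasis")


def build_ortholog_table(
    panel: list[str],
    frac_ambiguous: float = 0.0,
    frac_missing: float = 0.0,
    seed: int = 0,
) -> OrthologTable:
    """Ortholog table over the panel with controlled ambiguity and loss.

    Retained genes get a single partner ``<gene>_m``; an ``frac_ambiguous``
    fraction additionally maps to a second partner (multi-mapping); a
    ``frac_missing`` fraction gets no pair at all.
    """
    for f in (frac_ambiguous, frac_missing):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    if frac_ambiguous + frac_missing > 1.0:
        raise ValueError("frac_ambiguous + frac_missing must be <= 1")
    n = len(panel)
    if n == 0:
        raise ValueError("panel must be non-empty")
    n_missing = int(round(frac_missing * n))
    n_amb = int(round(frac_ambiguous * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    missing = set(perm[:n_missing].tolist())
    ambiguous = set(perm[n_missing : n_missing + n_amb].tolist())
    pairs: list[tuple[str, str]] = []
    for i, g in enumerate(panel):
        if i in missing:
            continue
        pairs.append((g, f"{g}_m"))
        if i in ambiguous:
            pairs.append((g, f"{g}_m2"))
    return OrthologTable(pairs)
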