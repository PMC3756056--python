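"""End-to-end orchestration: simulate → merge/normalize → classify → scan → report.

A single :class:`RunConfig` (YAML-serializable) governs a run; every stage
writes its outputs before the next begins, and identical config + seeds give
byte-identical files.  Stage functions are importable individually and are
what the CLI subcommands call.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .expression import (
    ExpressionMatrix,
    filter_unambiguous_orthologs,
    merge_matrices,
    normalize_unitization,
    restrict_and_align,
)
from .mapping import GenomeScan, binarize_subtype, subtype_metastasis_test
from .simulate import (
    PAM50_SUBTYPES,
    PlantedLocus,
    build_ortholog_table,
    generate_backcross_genotypes,
    generate_metastasis_status,
    generate_outbred_genotypes,
    generate_query_cohort,
    generate_reference_cohort,
    make_subtype_centroids,
)
from .transfer import (
    UNASSIGNED,
    SubtypeTransfer,
    classification_agreement,
    macro_accuracy,
    nearest_centroid_classify,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_full_pipeline",
           "stage_simulate", "stage_merge", "stage_classify", "stage_scan", "stage_report"]

_SEED_MOD = 2**31


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run.

    Defaults are the package's standard study conditions: a 50-gene panel
    losing 8 genes to missing/ambiguous orthology (42 used), five subtypes at
    human-like base frequencies, centroid separation 2.0 with unit Gaussian
    noise, 60 labeled reference samples, a backcross query cohort with one
    planted basal-susceptibility locus of effect 0.4, and a metastasis
    incidence matching the corresponding mouse cross.
    """

    # subtype vocabulary and expression model
    labels: tuple[str, ...] = PAM50_SUBTYPES
    panel_size: int = 50
    separation: float = 2.0
    noise_sd: float = 1.0
    n_reference_per_subtype: int = 12
    # ortholog table
    frac_ambiguous: float = 0.06
    frac_missing: float = 0.10
    # query cohort and genotypes
    design: str = "backcross"
    n_query: int = 60
    n_markers: int = 500
    n_founders: int = 8
    recomb_rate_per_mb: float = 0.01
    base_probs: dict = field(
        default_factory=lambda: {
            "LumA": 0.35, "LumB": 0.20, "Her2": 0.10, "Basal": 0.15, "Normal": 0.20,
        }
    )
    planted_loci: list = field(
        default_factory=lambda: [
            {"marker_index": 249, "target_subtype": "Basal", "effect": 0.4}
        ]
    )
    platform_offset: float = 2.0
    platform_scale: float = 1.5
    metastasis_incidence: float = 76 / 166
    # merge / normalize
    normalization_scope: str = "per_gene_per_block"
    # transfer
    metric: str = "one_minus_pearson"
    k_min: int = 2
    k_max: int = 20
    min_ref: int = 4
    tie_rule: str = "lexicographic"
    # scans
    scan_targets: list = field(default_factory=lambda: [["Basal"], ["LumB", "Her2"]])
    fdr_level: float = 0.05
    # randomness
    seed: int = 1

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.design not in ("backcross", "outbred"):
            raise ValueError(f"unknown design {self.design!r}")
        total = sum(self.base_probs.get(lab, 0.0) for lab in self.labels)
        if abs(total - 1.0) > 1e-8:
            raise ValueError("base_probs must sum to 1 over the subtype labels")
        if self.normalization_scope not in ("per_gene_per_block", "per_gene_global"):
            raise ValueError(f"unknown normalization scope {self.normalization_scope!r}")
        self.labels = tuple(self.labels)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        offsets = {
            "centroids": 1, "reference": 2, "genotypes": 3, "query": 4,
            "metastasis": 5, "orthologs": 6, "permutation": 7,
        }
        return (self.seed * 1_000_003 + offsets[stage]) % _SEED_MOD

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["labels"] = list(data["labels"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage record counts and headline numbers of a run."""

    n_reference: int = 0
    n_query: int = 0
    n_panel: int = 0
    n_orthologs_retained: int = 0
    n_genes_merged: int = 0
    n_samples_merged: int = 0
    normalized_min: float = float("nan")
    normalized_max: float = float("nan")
    n_assigned: int = 0
    n_unassigned: int = 0
    macro_accuracy: float = float("nan")
    centroid_concordance: float = float("nan")
    scans: dict = field(default_factory=dict)
    metastasis_p: float = float("nan")
    metastasis_method: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _loci_from_config(cfg: RunConfig) -> list[PlantedLocus]:
    out = []
    for d in cfg.planted_loci:
        t = d["target_subtype"]
        out.append(
            PlantedLocus(
                marker_index=int(d["marker_index"]),
                target_subtype=tuple(t) if isinstance(t, (list, tuple)) else str(t),
                effect=float(d["effect"]),
                risk_founder=d.get("risk_founder"),
            )
        )
    return out


def stage_simulate(cfg: RunConfig, out_dir: Path) -> None:
    """Generate and write all synthetic inputs (cohorts, genotypes, orthologs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    centroids = make_subtype_centroids(
        cfg.panel_size, cfg.labels, cfg.separation, seed=cfg.stage_seed("centroids")
    )
    reference = generate_reference_cohort(
        centroids, cfg.n_reference_per_subtype, cfg.noise_sd,
        platform_id="ref", seed=cfg.stage_seed("reference"),
    )
    table = build_ortholog_table(
        centroids.gene_ids, cfg.frac_ambiguous, cfg.frac_missing,
        seed=cfg.stage_seed("orthologs"),
    )
    if cfg.design == "backcross":
        genotypes = generate_backcross_genotypes(
            cfg.n_query, cfg.n_markers, seed=cfg.stage_seed("genotypes"),
            recomb_rate_per_mb=cfg.recomb_rate_per_mb,
        )
    else:
        genotypes = generate_outbred_genotypes(
            cfg.n_query, cfg.n_markers, cfg.n_founders,
            seed=cfg.stage_seed("genotypes"), switch_rate_per_mb=cfg.recomb_rate_per_mb,
        )
    shared = filter_unambiguous_orthologs(centroids.gene_ids, table)
    gene_map = dict(shared)  # query cohort lives in the species-b namespace
    query = generate_query_cohort(
        genotypes, _loci_from_config(cfg), centroids,
        base_probs=cfg.base_probs,
        platform_shift=(cfg.platform_offset, cfg.platform_scale),
        noise_sd=cfg.noise_sd, platform_id="query",
        seed=cfg.stage_seed("query"), gene_id_map=gene_map,
    )
    metastasis = generate_metastasis_status(
        cfg.n_query, cfg.metastasis_incidence, seed=cfg.stage_seed("metastasis")
    )
    metastasis.index = pd.Index(genotypes.sample_ids)

    pio.write_expression_tsv(reference.expression, out_dir / "reference_expression.tsv")
    pio.write_expression_tsv(query.expression, out_dir / "query_expression.tsv")
    pio.write_ortholog_tsv(table, out_dir / "orthologs.tsv")
    if cfg.design == "backcross":
        pio.write_backcross_genotype_tsv(genotypes, out_dir / "genotypes.tsv")
    else:
        pio.write_founder_dosage_tsv(genotypes, out_dir / "founder_dosages.tsv")

    ann_rows = []
    for s in reference.expression.sample_ids:
        ann_rows.append((s, "ref", "a", "ref", reference.true_labels[s], np.nan))
    for s in query.expression.sample_ids:
        ann_rows.append((s, "query", "b", "query", np.nan, metastasis[s]))
    ann = pd.DataFrame(
        ann_rows, columns=["sample_id", "cohort", "species", "platform", "subtype", "metastasis"]
    )
    pio.write_annotation_tsv(ann, out_dir / "annotations.tsv")
    # latent truth is withheld from the classifier; kept for evaluation only
    truth = query.true_labels.rename("subtype").reset_index()
    truth.columns = ["sample_id", "subtype"]
    truth.to_csv(out_dir / "query_truth.tsv", sep="\t", index=False, lineterminator="\n")
    log.info("simulate: %d reference, %d query samples, %d ortholog pairs retained",
             len(reference.expression.sample_ids), cfg.n_query, len(shared))


def stage_merge(cfg: RunConfig, out_dir: Path) -> None:
    """Ortholog-restrict, merge and normalize the simulated cohorts."""
    out_dir = Path(out_dir)
    reference = pio.read_expression_tsv(
        out_dir / "reference_expression.tsv", species="a", dataset_id="ref"
    )
    query = pio.read_expression_tsv(
        out_dir / "query_expression.tsv", species="b", dataset_id="query"
    )
    table = pio.read_ortholog_tsv(out_dir / "orthologs.tsv")
    shared = filter_unambiguous_orthologs(reference.gene_ids, table)
    if not shared:
        raise ValueError("ortholog filtering retained no genes")
    aligned = restrict_and_align([reference, query], shared)
    merged = merge_matrices(aligned)
    normalized = normalize_unitization(merged, scope=cfg.normalization_scope)
    pio.write_merged_tsv(normalized, out_dir / "merged.tsv")
    log.info("merge: %d genes × %d samples, normalized (%s)",
             *normalized.values.shape, cfg.normalization_scope)


def stage_classify(cfg: RunConfig, out_dir: Path) -> None:
    """Co-clustering label transfer plus the nearest-centroid comparator."""
    out_dir = Path(out_dir)
    merged = pio.read_merged_tsv(out_dir / "merged.tsv")
    ann = pio.read_annotation_tsv(out_dir / "annotations.tsv", allowed_labels=list(cfg.labels))
    model = SubtypeTransfer.from_cohorts(
        merged, ann, metric=cfg.metric, k_min=cfg.k_min, k_max=cfg.k_max,
        min_ref=cfg.min_ref, tie_rule=cfg.tie_rule, labels=sorted(cfg.labels),
    )
    res = model.fit()
    probs = res.probabilities.probs.copy()
    probs["n_contributing_cuts"] = res.probabilities.n_contributing_cuts
    probs.index.name = "sample_id"
    probs.to_csv(out_dir / "probabilities.tsv", sep="\t", float_format="%.10g",
                 na_rep="NA", lineterminator="\n")
    calls = pd.DataFrame(
        {
            "subtype": res.calls.labels,
            "tie_broken": res.calls.tie_broken,
            "n_contributing_cuts": res.probabilities.n_contributing_cuts,
        }
    )
    calls.index.name = "sample_id"
    calls.to_csv(out_dir / "calls.tsv", sep="\t", lineterminator="\n")

    ref_ids = model.reference_labels.index
    centroid_calls = nearest_centroid_classify(
        merged.values[list(ref_ids)], model.reference_labels, merged.values[model.query_ids]
    )
    cc = pd.DataFrame({"subtype": centroid_calls.labels, "tie_broken": centroid_calls.tie_broken})
    cc.index.name = "sample_id"
    cc.to_csv(out_dir / "calls_centroid.tsv", sep="\t", lineterminator="\n")
    log.info("classify: %d/%d query samples assigned", res.n_assigned, res.n_query)


def stage_scan(cfg: RunConfig, out_dir: Path) -> None:
    """Genome scans for each configured target subtype set."""
    out_dir = Path(out_dir)
    calls = pd.read_csv(out_dir / "calls.tsv", sep="\t", index_col=0)
    if cfg.design == "backcross":
        genotypes = pio.read_backcross_genotype_tsv(out_dir / "genotypes.tsv")
    else:
        genotypes = pio.read_founder_dosage_tsv(out_dir / "founder_dosages.tsv")
    for target in cfg.scan_targets:
        target = [target] if isinstance(target, str) else list(target)
        name = "_".join(t.lower() for t in target)
        try:
            y = binarize_subtype(calls["subtype"], target)
        except ValueError as err:
            log.warning("scan %s skipped: %s", name, err)
            continue
        if y.min() == y.max():
            log.warning("scan %s skipped: phenotype is constant", name)
            continue
        res = GenomeScan(genotypes, y, fdr_level=cfg.fdr_level).fit()
        res.table.to_csv(out_dir / f"scan_{name}.tsv", sep="\t", index=False,
                         float_format="%.10g", lineterminator="\n")
        log.info("scan %s: %d significant markers", name, len(res.significant))


def stage_report(cfg: RunConfig, out_dir: Path) -> RunReport:
    """Assemble the run report from the stage outputs."""
    out_dir = Path(out_dir)
    report = RunReport()
    ann = pio.read_annotation_tsv(out_dir / "annotations.tsv", allowed_labels=list(cfg.labels))
    report.n_reference = int(ann["subtype"].notna().sum())
    report.n_query = int(ann["subtype"].isna().sum())
    report.n_panel = cfg.panel_size
    merged = pio.read_merged_tsv(out_dir / "merged.tsv")
    report.n_orthologs_retained = len(merged.gene_ids)
    report.n_genes_merged, report.n_samples_merged = merged.values.shape
    report.normalized_min = float(merged.values.to_numpy().min())
    report.normalized_max = float(merged.values.to_numpy().max())

    calls = pd.read_csv(out_dir / "calls.tsv", sep="\t", index_col=0)
    report.n_assigned = int((calls["subtype"] != UNASSIGNED).sum())
    report.n_unassigned = int((calls["subtype"] == UNASSIGNED).sum())

    truth = pd.read_csv(out_dir / "query_truth.tsv", sep="\t", index_col=0)["subtype"]
    from .transfer import SubtypeCalls  # local import to avoid cycle at module load

    call_obj = SubtypeCalls(
        labels=calls["subtype"], tie_broken=calls["tie_broken"].astype(bool)
    )
    report.macro_accuracy = macro_accuracy(call_obj, truth)
    cc = pd.read_csv(out_dir / "calls_centroid.tsv", sep="\t", index_col=0)
    cc_obj = SubtypeCalls(labels=cc["subtype"], tie_broken=cc["tie_broken"].astype(bool))
    concordance, _ = classification_agreement(call_obj, cc_obj)
    report.centroid_concordance = concordance

    for target in cfg.scan_targets:
        target = [target] if isinstance(target, str) else list(target)
        name = "_".join(t.lower() for t in target)
        path = out_dir / f"scan_{name}.tsv"
        if not path.exists():
            continue
        tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        top = tab.loc[tab["p"].idxmin()]
        report.scans[name] = {
            "n_markers": len(tab),
            "n_significant": int(tab["significant"].sum()),
            "top_marker": str(top["marker_id"]),
            "top_chrom": str(top["chrom"]),
            "top_pos_mb": float(top["pos_mb"]),
            "top_p": float(top["p"]),
            "top_q": float(top["q"]),
        }

    met = ann.loc[ann["metastasis"].notna(), "metastasis"].astype(int)
    if len(met) and calls.loc[calls.index.intersection(met.index), "subtype"].nunique() >= 2:
        test = subtype_metastasis_test(
            call_obj.labels, met, seed=cfg.stage_seed("permutation")
        )
        report.metastasis_p = test.p_value
        report.metastasis_method = test.method
    else:
        log.warning("metastasis test skipped (missing status or <2 subtype levels)")
    report.to_json(out_dir / "report.json")
    return report


def run_full_pipeline(cfg: RunConfig, out_dir) -> RunReport:
    """Execute every stage in order; identical config + seed ⇒ identical files."""
    out_dir = Path(out_dir)
    for stage in (stage_simulate, stage_merge, stage_classify, stage_scan):
        try:
            stage(cfg, out_dir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage.__name__} failed: {err}") from err
    return stage_report(cfg, out_dir)
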