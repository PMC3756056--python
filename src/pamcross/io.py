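"""TSV dialects and JSON sidecars for every pipeline artifact.

All tables are plain tab-separated text with a single header row; numbers are
serialized with 10 significant digits so that re-runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, MergedMatrix, OrthologTable
from .simulate import GenotypeData

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
    "read_backcross_genotype_tsv",
    "write_backcross_genotype_tsv",
    "read_founder_dosage_tsv",
    "write_founder_dosage_tsv",
    "read_merged_tsv",
    "write_merged_tsv",
]

_FLOAT_FMT = "%.10g"

ANNOTATION_COLUMNS = ["sample_id", "cohort", "species", "platform", "subtype", "metastasis"]


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_expression_tsv(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


def read_expression_tsv(
    path, species: str = "", platform_id: str = "", dataset_id: str = ""
) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {header[0]!r}")
    samples = header[1:]
    dupes = pd.Index(samples)[pd.Index(samples).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated sample column(s) {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        positions = np.flatnonzero(df.index.duplicated()) + 2  # header is line 1
        raise ValueError(f"{path}: duplicate gene id(s) at line(s) {positions.tolist()}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[:1].tolist()
            raise ValueError(f"{path}: non-numeric cell in column {col!r} (gene {bad})")
    return ExpressionMatrix(
        df.astype(float), species=species, platform_id=platform_id, dataset_id=dataset_id
    )


def write_annotation_tsv(annotations: pd.DataFrame, path) -> None:
    df = annotations.reset_index() if annotations.index.name == "sample_id" else annotations
    df = df.reindex(columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def read_annotation_tsv(path, allowed_labels: list[str] | None = None) -> pd.DataFrame:
    """Sample annotations; missing subtype = unlabeled query, metastasis may be NA.

    Subtype strings are compared case-sensitively against ``allowed_labels``
    when given; an unknown label is a hard error listing the vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dupes}")
    if allowed_labels is not None:
        seen = set(df["subtype"].dropna().unique())
        unknown = sorted(seen - set(allowed_labels))
        if unknown:
            raise ValueError(
                f"{path}: unknown subtype label(s) {unknown}; allowed: {sorted(allowed_labels)}"
            )
    return df.set_index("sample_id")


def write_ortholog_tsv(table: OrthologTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_tsv(path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene_a", "gene_b"]:
        raise ValueError(f"{path}: ortholog table must have columns gene_a, gene_b")
    return OrthologTable.from_frame(df)


def write_backcross_genotype_tsv(g: GenotypeData, path) -> None:
    if g.design != "backcross":
        raise ValueError("not a backcross genotype set")
    codes = np.where(g.codes == 1, "H", "A")
    df = pd.DataFrame(codes, index=g.marker_ids, columns=g.sample_ids)
    df.insert(0, "chrom", [str(c) for c in g.chrom])
    df.insert(1, "pos_mb", [_fmt(p) for p in g.pos_mb])
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_backcross_genotype_tsv(path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"chrom": str})
    sample_cols = [c for c in df.columns if c not in ("chrom", "pos_mb")]
    codes_str = df[sample_cols].to_numpy(dtype=str)
    bad = set(codes_str.ravel()) - {"A", "H"}
    if bad:
        raise ValueError(f"{path}: invalid genotype code(s) {sorted(bad)} (expected A or H)")
    codes = (codes_str == "H").astype(np.int8)
    return GenotypeData(
        marker_ids=list(df.index.astype(str)),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_mb=df["pos_mb"].to_numpy(dtype=float),
        design="backcross",
        sample_ids=sample_cols,
        codes=codes,
    )


def write_founder_dosage_tsv(g: GenotypeData, path) -> None:
    if g.design != "outbred":
        raise ValueError("not an outbred genotype set")
    rows = []
    for m, marker in enumerate(g.marker_ids):
        for s, sample in enumerate(g.sample_ids):
            for f, founder in enumerate(g.founder_ids):
                d = int(g.dosages[m, s, f])
                if d:
                    rows.append((marker, str(g.chrom[m]), _fmt(g.pos_mb[m]), sample, founder, d))
    pd.DataFrame(
        rows, columns=["marker_id", "chrom", "pos_mb", "sample_id", "founder_id", "dosage"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_founder_dosage_tsv(path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str, "founder_id": str})
    markers = list(dict.fromkeys(df["marker_id"]))
    samples = sorted(df["sample_id"].unique())
    founders = sorted(df["founder_id"].unique())
    m_idx = {m: i for i, m in enumerate(markers)}
    s_idx = {s: i for i, s in enumerate(samples)}
    f_idx = {f: i for i, f in enumerate(founders)}
    dosages = np.zeros((len(markers), len(samples), len(founders)), dtype=np.int8)
    for row in df.itertuples(index=False):
        dosages[m_idx[row.marker_id], s_idx[row.sample_id], f_idx[row.founder_id]] = row.dosage
    meta = df.drop_duplicates("marker_id").set_index("marker_id")
    return GenotypeData(
        marker_ids=markers,
        chrom=meta.loc[markers, "chrom"].to_numpy(dtype=object),
        pos_mb=meta.loc[markers, "pos_mb"].to_numpy(dtype=float),
        design="outbred",
        sample_ids=samples,
        dosages=dosages,
        founder_ids=founders,
    )


def write_merged_tsv(merged: MergedMatrix, path) -> None:
    """Merged matrix TSV plus a ``<path>.meta.json`` sidecar with block metadata."""
    path = Path(path)
    write_expression_tsv(merged.values, path)
    meta = {
        "block_of_sample": merged.block_of_sample.to_dict(),
        "normalized": merged.normalized,
        "normalization_scope": merged.normalization_scope,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_merged_tsv(path) -> MergedMatrix:
    path = Path(path)
    expr = read_expression_tsv(path)
    with open(path.with_suffix(path.suffix + ".meta.json")) as fh:
        meta = json.load(fh)
    block = pd.Series(meta["block_of_sample"]).reindex(expr.values.columns)
    return MergedMatrix(
        values=expr.values,
        block_of_sample=block,
        normalized=bool(meta["normalized"]),
        normalization_scope=meta.get("normalization_scope"),
    )
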