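"""Ortholog panel filtering, cross-cohort merging and unit-range normalization.

The classifier panel lives in two gene namespaces (a human-like reference
species and a mouse-like query species).  Before any joint clustering the
cohorts are restricted to the genes that map one-to-one in *both* directions
between the namespaces, merged column-wise into a single matrix tagged with
the dataset of origin, and normalized so every value falls in [-1, 1]
(mean-centering followed by division by the maximum absolute deviation —
"unitization with zero mean").  Per-gene-per-dataset normalization removes
any affine per-platform distortion exactly, which is why it is the default
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "OrthologTable",
    "ExpressionMatrix",
    "MergedMatrix",
    "filter_unambiguous_orthologs",
    "restrict_and_align",
    "merge_matrices",
    "normalize_unitization",
]


@dataclass
class OrthologTable:
    """Gene pairs linking the reference namespace (a) to the query namespace (b).

    Duplicate identical pairs are dropped on construction; a gene may appear
    in several *distinct* pairs (that is what makes it ambiguous).
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for p in self.pairs:
            p = (str(p[0]), str(p[1]))
            if p not in seen:
                seen.add(p)
                deduped.append(p)
        self.pairs = deduped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologTable":
        return cls(list(zip(df["gene_a"].astype(str), df["gene_b"].astype(str))))


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with provenance tags.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    """

    values: pd.DataFrame
    species: str = ""
    platform_id: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError(f"non-finite values in expression matrix {self.dataset_id!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MergedMatrix:
    """Column-concatenation of aligned cohorts, with per-sample dataset blocks."""

    values: pd.DataFrame
    block_of_sample: pd.Series  # sample id -> dataset id
    normalized: bool = False
    normalization_scope: str | None = None

    def __post_init__(self) -> None:
        if list(self.block_of_sample.index) != list(self.values.columns):
            self.block_of_sample = self.block_of_sample.reindex(self.values.columns)
        if self.block_of_sample.isna().any():
            missing = self.block_of_sample.index[self.block_of_sample.isna()].tolist()
            raise ValueError(f"samples without block annotation: {missing}")
        if self.normalized:
            arr = self.values.to_numpy(dtype=float)
            if arr.size and (arr.min() < -1 - 1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError("normalized matrix has entries outside [-1, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_block(self, dataset_id: str) -> list[str]:
        return list(self.block_of_sample.index[self.block_of_sample == dataset_id])


def filter_unambiguous_orthologs(
    panel: list[str], table: OrthologTable
) -> list[tuple[str, str]]:
    """Return the (gene_a, gene_b) pairs of panel genes mapping 1:1 both ways.

    A panel gene is kept iff it has exactly one partner in the table and that
    partner maps back only to it.  Output order follows the panel order.
    An empty result is allowed (warned, not raised): downstream stages check.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    fwd: dict[str, set[str]] = {}
    rev: dict[str, set[str]] = {}
    for a, b in table.pairs:
        fwd.setdefault(a, set()).add(b)
        rev.setdefault(b, set()).add(a)
    kept: list[tuple[str, str]] = []
    for g in panel:
        partners = fwd.get(g, set())
        if len(partners) != 1:
            continue
        (b,) = partners
        if rev[b] == {g}:
            kept.append((g, b))
    if not kept:
        log.warning("no unambiguous 1:1 ortholog pairs retained from panel of %d", len(panel))
    return kept


def restrict_and_align(
    matrices: list[ExpressionMatrix], shared: list[tuple[str, str]]
) -> list[ExpressionMatrix]:
    """Restrict every matrix to the shared ortholog pairs, in identical order.

    Each matrix may carry either namespace; rows are renamed to the reference
    (species-a) identifiers.  A shared gene absent from any one matrix is
    dropped from all (intersection semantics, with a warning); a matrix that
    contains none of the shared genes is a hard error.
    """
    if not shared:
        raise ValueError("shared gene-pair list is empty")
    per_matrix_names: list[dict[str, str]] = []  # pair key a -> row name used in matrix
    for m in matrices:
        idx = set(m.values.index)
        names: dict[str, str] = {}
        for a, b in shared:
            if a in idx:
                names[a] = a
            elif b in idx:
                names[a] = b
        if not names:
            raise ValueError(
                f"dataset {m.dataset_id!r} contains none of the {len(shared)} shared genes"
            )
        per_matrix_names.append(names)

    common = [a for a, _ in shared if all(a in names for names in per_matrix_names)]
    n_dropped = len(shared) - len(common)
    if n_dropped:
        dropped = [a for a, _ in shared if a not in common]
        log.warning("dropping %d shared genes missing from some dataset: %s", n_dropped, dropped)
    if not common:
        raise ValueError("no shared gene present in every dataset")

    out = []
    for m, names in zip(matrices, per_matrix_names):
        rows = [names[a] for a in common]
        vals = m.values.loc[rows].copy()
        vals.index = pd.Index(common, name=m.values.index.name)
        out.append(replace(m, values=vals))
    return out


def merge_matrices(aligned: list[ExpressionMatrix]) -> MergedMatrix:
    """Column-concatenate aligned cohorts, recording each sample's dataset."""
    if not aligned:
        raise ValueError("no matrices to merge")
    ref_genes = aligned[0].gene_ids
    for m in aligned[1:]:
        if m.gene_ids != ref_genes:
            raise ValueError(
                f"gene order mismatch between {aligned[0].dataset_id!r} and {m.dataset_id!r}"
            )
    seen: dict[str, str] = {}
    for m in aligned:
        for s in m.sample_ids:
            if s in seen:
                raise ValueError(
                    f"duplicate sample id {s!r} in datasets {seen[s]!r} and {m.dataset_id!r}"
                )
            seen[s] = m.dataset_id
    values = pd.concat([m.values for m in aligned], axis=1)
    block = pd.Series({s: d for s, d in seen.items()}, name="dataset_id").reindex(values.columns)
    return MergedMatrix(values=values, block_of_sample=block, normalized=False)


def _unitize_group(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean()
    m = np.abs(centered).max()
    # groups constant up to float rounding are treated as constant (-> zeros)
    if m <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return np.zeros_like(centered)
    return centered / m


def normalize_unitization(
    merged: MergedMatrix, scope: str = "per_gene_per_block"
) -> MergedMatrix:
    """Unitization with zero mean: centre each group, divide by max |deviation|.

    ``scope`` selects the normalization group: every gene within every dataset
    block (default; removes per-block affine platform effects exactly) or every
    gene across the whole merged matrix.  Constant groups map to zeros.  Output
    values always lie in [-1, 1].
    """
    if merged.normalized:
        raise ValueError("matrix is already normalized")
    if scope not in ("per_gene_per_block", "per_gene_global"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    vals = merged.values.to_numpy(dtype=float).copy()
    if scope == "per_gene_global":
        for i in range(vals.shape[0]):
            vals[i, :] = _unitize_group(vals[i, :])
    else:
        blocks = merged.block_of_sample.to_numpy()
        for d in pd.unique(blocks):
            cols = np.flatnonzero(blocks == d)
            for i in range(vals.shape[0]):
                vals[i, cols] = _unitize_group(vals[i, cols])
    out = pd.DataFrame(vals, index=merged.values.index, columns=merged.values.columns)
    return MergedMatrix(
        values=out,
        block_of_sample=merged.block_of_sample.copy(),
        normalized=True,
        normalization_scope=scope,
    )
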