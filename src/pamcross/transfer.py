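"""Semi-supervised subtype label transfer by joint hierarchical co-clustering.

Labeled reference samples and unlabeled query samples are clustered together
(complete linkage on 1 - Pearson correlation over the shared gene panel).  The
tree is cut into every k clusters for k in a range (default 2..20); within
each cut, a cluster "qualifies" if it contains strictly more than ``min_ref``
reference samples (default 4, i.e. at least 5), in which case the empirical
subtype distribution of its reference members is taken as evidence.  A query
sample's subtype probability vector is the unweighted mean of the qualifying
vectors it collects across cuts; a sample whose cluster never qualifies stays
unassigned.  A nearest-centroid comparator and agreement metrics support
performance analysis of the transfer.

:class:`SubtypeTransfer` wraps the procedure as a model object whose ``fit()``
returns a :class:`SubtypeTransferResults` carrying probabilities, calls and a
``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix, MergedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "UNASSIGNED",
    "DistanceMatrix",
    "Dendrogram",
    "SubtypeProbabilities",
    "SubtypeCalls",
    "pairwise_distances",
    "complete_linkage_tree",
    "cut_tree_at_k",
    "subcluster_label_proportions",
    "transfer_subtype_probabilities",
    "call_subtypes",
    "nearest_centroid_classify",
    "classification_agreement",
    "macro_accuracy",
    "SubtypeTransfer",
    "SubtypeTransferResults",
]

UNASSIGNED = "unassigned"


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class Dendrogram:
    """Agglomerative merge tree: a scipy linkage matrix plus the leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 merges")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class SubtypeProbabilities:
    """Per-query subtype probability vectors, with per-sample audit counts.

    ``probs`` rows of unassigned samples are NaN; ``n_contributing_cuts``
    records how many tree cuts contributed to each sample's average.
    """

    probs: pd.DataFrame  # query samples × subtype labels
    n_contributing_cuts: pd.Series

    def __post_init__(self) -> None:
        assigned = self.n_contributing_cuts > 0
        arr = self.probs.to_numpy(dtype=float)
        a = arr[assigned.to_numpy()]
        if a.size:
            if np.any(a < -1e-12):
                raise ValueError("probabilities must be nonnegative")
            if np.any(np.abs(a.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("assigned probability vectors must sum to 1")

    @property
    def labels(self) -> list[str]:
        return list(self.probs.columns)

    @property
    def assigned(self) -> pd.Series:
        return self.n_contributing_cuts > 0


@dataclass
class SubtypeCalls:
    """Categorical subtype calls; ``UNASSIGNED`` marks samples without a call."""

    labels: pd.Series  # sample id -> label or UNASSIGNED
    tie_broken: pd.Series

    @property
    def assigned(self) -> pd.Series:
        return self.labels != UNASSIGNED


def pairwise_distances(
    merged: MergedMatrix, metric: str = "one_minus_pearson"
) -> DistanceMatrix:
    """Sample–sample distances over the panel genes of a normalized matrix."""
    if not merged.normalized:
        raise ValueError("distances are computed on the normalized merged matrix")
    X = merged.values.to_numpy(dtype=float)
    samples = merged.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if metric == "one_minus_pearson":
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = [samples[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance profiles under correlation distance: {bad}")
        D = 1.0 - np.corrcoef(X, rowvar=False)
        D = np.clip(D, 0.0, 2.0)
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
    elif metric == "euclidean":
        D = squareform(pdist(X.T, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=list(samples), values=D, metric=metric)


def complete_linkage_tree(d: DistanceMatrix) -> Dendrogram:
    """Agglomerate with complete (maximum) linkage."""
    if not np.isfinite(d.values).all():
        raise ValueError("non-finite distances")
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    return Dendrogram(linkage=Z, leaf_ids=list(d.sample_ids))


def cut_tree_at_k(tree: Dendrogram, k: int) -> pd.Series:
    """Partition into exactly k clusters by undoing the last k-1 merges."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel()
    return pd.Series(flat, index=tree.leaf_ids, name=f"k{k}")


def subcluster_label_proportions(
    assignment: pd.Series,
    reference_labels: pd.Series,
    min_ref: int = 4,
    labels: list[str] | None = None,
) -> dict[int, pd.Series | None]:
    """Subtype distribution of each cluster's reference members, if it qualifies.

    A cluster qualifies when it contains strictly more than ``min_ref``
    reference samples ("more than 4" read as >= 5 under the default);
    disqualified clusters map to None.
    """
    if min_ref < 0:
        raise ValueError("min_ref must be >= 0")
    if labels is None:
        labels = sorted(reference_labels.unique())
    ref_ids = assignment.index.intersection(reference_labels.index)
    out: dict[int, pd.Series | None] = {}
    for cluster in sorted(assignment.unique()):
        members = ref_ids[assignment.loc[ref_ids] == cluster]
        if len(members) > min_ref:
            counts = reference_labels.loc[members].value_counts()
            props = counts.reindex(labels, fill_value=0).astype(float) / len(members)
            out[int(cluster)] = props
        else:
            out[int(cluster)] = None
    return out


def transfer_subtype_probabilities(
    tree: Dendrogram,
    reference_labels: pd.Series,
    query_ids: list[str],
    k_min: int = 2,
    k_max: int = 20,
    min_ref: int = 4,
    labels: list[str] | None = None,
) -> SubtypeProbabilities:
    """Average qualifying sub-cluster label distributions over the cut range.

    For each k in [k_min, min(k_max, n)] the tree is cut; every query sample
    whose cluster qualifies collects that cluster's reference-label
    distribution.  The final vector is the unweighted mean over collected
    cuts.  Samples that never co-cluster with enough reference samples are
    left unassigned with ``n_contributing_cuts = 0``.
    """
    if len(reference_labels) == 0:
        raise ValueError("no reference labels provided")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if labels is None:
        labels = sorted(reference_labels.unique())
    n = tree.n_leaves
    k_hi = min(k_max, n)
    sums = pd.DataFrame(0.0, index=list(query_ids), columns=labels)
    counts = pd.Series(0, index=list(query_ids), dtype=int)
    for k in range(k_min, k_hi + 1):
        assignment = cut_tree_at_k(tree, k)
        props = subcluster_label_proportions(assignment, reference_labels, min_ref, labels)
        for q in query_ids:
            vec = props[int(assignment.loc[q])]
            if vec is not None:
                sums.loc[q] += vec
                counts.loc[q] += 1
    probs = sums.div(counts.replace(0, np.nan), axis=0)
    return SubtypeProbabilities(probs=probs, n_contributing_cuts=counts)


def call_subtypes(probs: SubtypeProbabilities, tie_rule: str = "lexicographic") -> SubtypeCalls:
    """Argmax call per sample; exact ties broken per ``tie_rule``.

    ``lexicographic`` picks the alphabetically first tied label (flagged in
    ``tie_broken``); ``unassign`` refuses to call tied samples.
    """
    if tie_rule not in ("lexicographic", "unassign"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    out, ties = {}, {}
    labels = np.array(probs.labels)
    for sample in probs.probs.index:
        if probs.n_contributing_cuts.loc[sample] == 0:
            out[sample], ties[sample] = UNASSIGNED, False
            continue
        vec = probs.probs.loc[sample].to_numpy(dtype=float)
        top = np.flatnonzero(vec == vec.max())
        if len(top) == 1:
            out[sample], ties[sample] = labels[top[0]], False
        elif tie_rule == "lexicographic":
            out[sample], ties[sample] = sorted(labels[top])[0], True
        else:
            out[sample], ties[sample] = UNASSIGNED, True
    idx = probs.probs.index
    return SubtypeCalls(
        labels=pd.Series(out, name="subtype").reindex(idx),
        tie_broken=pd.Series(ties, name="tie_broken").reindex(idx),
    )


def nearest_centroid_classify(
    reference_values: pd.DataFrame,
    reference_labels: pd.Series,
    query_values: pd.DataFrame,
) -> SubtypeCalls:
    """Comparator: assign each query to the most-correlated reference centroid.

    Centroids are per-label mean reference profiles over the shared gene
    panel; similarity is Pearson correlation.  Zero-variance query profiles
    are left unassigned with a warning.
    """
    if not reference_values.index.equals(query_values.index):
        raise ValueError("reference and query must share the same gene panel")
    labs = sorted(reference_labels.unique())
    cent = np.column_stack(
        [
            reference_values[reference_labels.index[reference_labels == lab]]
            .to_numpy(dtype=float)
            .mean(axis=1)
            for lab in labs
        ]
    )
    Q = query_values.to_numpy(dtype=float)
    calls, ties = {}, {}
    cent_c = cent - cent.mean(axis=0)
    cent_n = np.linalg.norm(cent_c, axis=0)
    for j, sample in enumerate(query_values.columns):
        q = Q[:, j] - Q[:, j].mean()
        qn = np.linalg.norm(q)
        if qn == 0 or np.any(cent_n == 0):
            warnings.warn(f"zero-variance profile; leaving {sample!r} unassigned")
            calls[sample], ties[sample] = UNASSIGNED, False
            continue
        r = cent_c.T @ q / (cent_n * qn)
        top = np.flatnonzero(r == r.max())
        calls[sample] = sorted(np.array(labs)[top])[0]
        ties[sample] = len(top) > 1
    idx = query_values.columns
    return SubtypeCalls(
        labels=pd.Series(calls, name="subtype").reindex(idx),
        tie_broken=pd.Series(ties, name="tie_broken").reindex(idx),
    )


def classification_agreement(
    calls_a: SubtypeCalls, calls_b: SubtypeCalls
) -> tuple[float, pd.DataFrame]:
    """Concordance over jointly assigned samples, plus a full confusion matrix.

    The confusion matrix includes an ``unassigned`` row/column; the scalar
    concordance counts only samples assigned by both methods.
    """
    common = calls_a.labels.index.intersection(calls_b.labels.index)
    if len(common) == 0:
        raise ValueError("call sets share no samples")
    a = calls_a.labels.loc[common]
    b = calls_b.labels.loc[common]
    levels = sorted((set(a.unique()) | set(b.unique())) - {UNASSIGNED}) + [UNASSIGNED]
    conf = pd.crosstab(a, b).reindex(index=levels, columns=levels, fill_value=0)
    joint = (a != UNASSIGNED) & (b != UNASSIGNED)
    n_joint = int(joint.sum())
    concordance = float((a[joint] == b[joint]).mean()) if n_joint else float("nan")
    return concordance, conf


def macro_accuracy(calls: SubtypeCalls, truth: pd.Series) -> float:
    """Macro-averaged per-class recall vs latent truth (unassigned = wrong)."""
    common = calls.labels.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no overlap between calls and truth")
    got = calls.labels.loc[common]
    tru = truth.loc[common]
    recalls = [float((got[tru == lab] == lab).mean()) for lab in sorted(tru.unique())]
    return float(np.mean(recalls))


class SubtypeTransfer:
    """Joint co-clustering label-transfer model.

    Parameters
    ----------
    merged : MergedMatrix
        Normalized merged reference + query matrix.
    reference_labels : pd.Series
        Subtype label per labeled (reference) sample; every merged sample not
        listed here is treated as a query.
    metric, k_min, k_max, min_ref, tie_rule, labels :
        The transfer hyper-parameters; see the module docstring.
    """

    def __init__(
        self,
        merged: MergedMatrix,
        reference_labels: pd.Series,
        *,
        metric: str = "one_minus_pearson",
        k_min: int = 2,
        k_max: int = 20,
        min_ref: int = 4,
        tie_rule: str = "lexicographic",
        labels: list[str] | None = None,
    ) -> None:
        missing = [s for s in reference_labels.index if s not in set(merged.sample_ids)]
        if missing:
            raise ValueError(f"reference samples absent from merged matrix: {missing}")
        self.merged = merged
        self.reference_labels = reference_labels
        self.query_ids = [s for s in merged.sample_ids if s not in set(reference_labels.index)]
        self.metric = metric
        self.k_min, self.k_max, self.min_ref = k_min, k_max, min_ref
        self.tie_rule = tie_rule
        self.labels = labels if labels is not None else sorted(reference_labels.unique())

    @classmethod
    def from_cohorts(
        cls, merged: MergedMatrix, annotations: pd.DataFrame, **kwargs
    ) -> "SubtypeTransfer":
        """Build from an annotation table with a ``subtype`` column (NA = query)."""
        labeled = annotations["subtype"].dropna()
        return cls(merged, labeled, **kwargs)

    def fit(self) -> "SubtypeTransferResults":
        d = pairwise_distances(self.merged, self.metric)
        tree = complete_linkage_tree(d)
        probs = transfer_subtype_probabilities(
            tree,
            self.reference_labels,
            self.query_ids,
            k_min=self.k_min,
            k_max=self.k_max,
            min_ref=self.min_ref,
            labels=self.labels,
        )
        calls = call_subtypes(probs, self.tie_rule)
        return SubtypeTransferResults(self, tree, probs, calls)


class SubtypeTransferResults:
    """Fitted label-transfer results: probabilities, calls and diagnostics."""

    def __init__(
        self,
        model: SubtypeTransfer,
        tree: Dendrogram,
        probabilities: SubtypeProbabilities,
        calls: SubtypeCalls,
    ) -> None:
        self.model = model
        self.tree = tree
        self.probabilities = probabilities
        self.calls = calls

    @property
    def n_assigned(self) -> int:
        return int(self.calls.assigned.sum())

    @property
    def n_query(self) -> int:
        return len(self.model.query_ids)

    def accuracy(self, truth: pd.Series) -> float:
        """Macro-averaged accuracy of the calls against latent truth labels."""
        return macro_accuracy(self.calls, truth)

    def concordance_with(self, other: SubtypeCalls) -> tuple[float, pd.DataFrame]:
        return classification_agreement(self.calls, other)

    def summary(self) -> str:
        lines = [
            "Subtype label transfer (joint co-clustering)",
            f"  metric: {self.model.metric}   linkage: complete",
            f"  cuts: k = {self.model.k_min}..{self.model.k_max}   min_ref > {self.model.min_ref}",
            f"  query samples: {self.n_query}   assigned: {self.n_assigned}",
            "",
            "  call distribution:",
        ]
        counts = self.calls.labels.value_counts()
        for lab in self.model.labels + [UNASSIGNED]:
            if lab in counts:
                lines.append(f"    {lab:>12}: {int(counts[lab])}")
        med = self.probabilities.n_contributing_cuts[self.probabilities.assigned]
        if len(med):
            lines.append(f"  median contributing cuts: {float(med.median()):.1f}")
        return "\n".join(lines)
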