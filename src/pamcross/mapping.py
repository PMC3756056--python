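"""Genome scans for loci associated with derived subtype calls.

Backcross designs are scanned with a two-sided exact conditional test on the
2×2 table genotype {hom, het} × phenotype {0, 1} (two-sided p-value = sum of
the probabilities of all tables, with the observed margins fixed, whose point
probability is at most the observed table's, compared with relative tolerance
1e-12).  Outbred designs are scanned by regressing the binary phenotype on
the founder-dosage matrix and taking the overall F-test against the
intercept-only model, with the founder carrying the largest (centred) effect
reported as the attribution.  Benjamini–Hochberg step-up controls the FDR
across markers within a scan.  The subtype–metastasis independence check is a
chi-square test of the subtype × metastasis table, falling back to a seeded
Monte-Carlo permutation p when any expected cell is below 5.

:class:`GenomeScan` wraps a scan as a model object; its ``fit()`` returns a
:class:`GenomeScanResults` with the per-marker table and a ``summary()``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import HET, HOM, GenotypeData
from .transfer import UNASSIGNED, SubtypeCalls

log = logging.getLogger(__name__)

__all__ = [
    "binarize_subtype",
    "exact_test_2x2",
    "marker_association_backcross",
    "marker_association_founder",
    "bh_fdr",
    "genome_scan",
    "GenomeScan",
    "GenomeScanResults",
    "IndependenceTestResult",
    "subtype_metastasis_test",
]

_P_FLOOR = 1e-300  # keeps degenerate perfect fits inside (0, 1]


def _chrom_sort_key(chrom: str):
    """Natural chromosome order: "1" < "2" < ... < "19" < "X"."""
    return (0, int(chrom)) if re.fullmatch(r"\d+", str(chrom)) else (1, str(chrom))


def binarize_subtype(calls: SubtypeCalls | pd.Series, target) -> pd.Series:
    """1 iff the call is in the target label set; unassigned samples dropped."""
    labels = calls.labels if isinstance(calls, SubtypeCalls) else calls
    targets = {target} if isinstance(target, str) else set(target)
    if not targets:
        raise ValueError("target label set must be non-empty")
    assigned = labels[labels != UNASSIGNED].dropna()
    n_dropped = len(labels) - len(assigned)
    if n_dropped:
        log.info("binarize_subtype: excluded %d unassigned samples", n_dropped)
    if len(assigned) == 0:
        raise ValueError("all samples are unassigned")
    return assigned.isin(targets).astype(int).rename("phenotype")


def exact_test_2x2(table: np.ndarray) -> float:
    """Two-sided exact conditional p-value for a 2×2 count table.

    Enumerates the hypergeometric distribution over tables with the observed
    margins and sums the probabilities of those whose point probability does
    not exceed the observed one (relative tolerance 1e-12).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 nonnegative counts")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - k_lo]
    mask = pmf <= p_obs * (1.0 + 1e-12)
    if mask.all():
        return 1.0
    p = float(pmf[mask].sum())
    return min(1.0, max(p, _P_FLOOR))


def _chisq_test_2x2(table: np.ndarray) -> float:
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return max(float(p), _P_FLOOR)


def marker_association_backcross(
    g: GenotypeData, y: pd.Series, test: str = "exact"
) -> pd.DataFrame:
    """Per-marker 2×2 association of backcross genotype with a binary phenotype.

    Returns a frame with columns p, direction (the genotype enriched among
    cases: "het"/"hom") and flagged (True for monomorphic markers, which get
    p = 1).
    """
    if g.design != "backcross":
        raise ValueError("genotypes are not from a backcross design")
    if test not in ("exact", "chisq"):
        raise ValueError(f"unknown backcross test {test!r}")
    common = [s for s in g.sample_ids if s in set(y.index)]
    if not common:
        raise ValueError("no overlap between genotype and phenotype samples")
    yv = y.loc[common].to_numpy(dtype=int)
    if yv.min() == yv.max():
        raise ValueError("phenotype must contain at least one case and one control")
    col_idx = [g.sample_ids.index(s) for s in common]
    codes = g.codes[:, col_idx]
    rows = []
    for m in range(g.n_markers):
        gm = codes[m]
        if gm.min() == gm.max():
            rows.append((1.0, None, True))
            continue
        # rows: genotype hom/het; cols: control/case
        table = np.array(
            [
                [np.sum((gm == HOM) & (yv == 0)), np.sum((gm == HOM) & (yv == 1))],
                [np.sum((gm == HET) & (yv == 0)), np.sum((gm == HET) & (yv == 1))],
            ]
        )
        p = exact_test_2x2(table) if test == "exact" else _chisq_test_2x2(table)
        with np.errstate(invalid="ignore"):
            case_rate_het = table[1, 1] / table[1].sum()
            case_rate_hom = table[0, 1] / table[0].sum()
        direction = "het" if case_rate_het >= case_rate_hom else "hom"
        rows.append((p, direction, False))
    return pd.DataFrame(rows, columns=["p", "direction", "flagged"], index=g.marker_ids)


def _founder_f_test(D: np.ndarray, yv: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Overall F-test of founder dosages vs intercept-only; returns (p, effects, flagged)."""
    n, n_f = D.shape
    X_cols = [np.ones(n)]
    kept: list[int] = []
    for j in range(n_f - 1):  # sum-to-2 constraint absorbs one founder column
        cand = np.column_stack(X_cols + [D[:, j]])
        if np.linalg.matrix_rank(cand) > len(X_cols):
            X_cols.append(D[:, j])
            kept.append(j)
    flagged = len(kept) < n_f - 1
    if not kept:
        return 1.0, np.zeros(n_f), True
    X = np.column_stack(X_cols)
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((yv - yv.mean()) ** 2))
    df1 = len(kept)
    df2 = n - X.shape[1]
    if df2 <= 0:
        return 1.0, np.zeros(n_f), True
    if rss1 <= 1e-12 * max(rss0, 1.0):
        p = _P_FLOOR
    else:
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        p = max(float(stats.f.sf(F, df1, df2)), _P_FLOOR)
    effects = np.zeros(n_f)
    effects[kept] = beta[1:]
    effects -= effects.mean()  # attribution invariant to the dropped baseline
    return p, effects, flagged


def marker_association_founder(g: GenotypeData, y: pd.Series) -> pd.DataFrame:
    """Per-marker founder-dosage regression: F-test p plus top-founder attribution."""
    if g.design != "outbred":
        raise ValueError("genotypes are not from an outbred design")
    common = [s for s in g.sample_ids if s in set(y.index)]
    if not common:
        raise ValueError("no overlap between genotype and phenotype samples")
    yv = y.loc[common].to_numpy(dtype=float)
    if yv.min() == yv.max():
        raise ValueError("phenotype is constant")
    col_idx = [g.sample_ids.index(s) for s in common]
    rows = []
    for m in range(g.n_markers):
        D = g.dosages[m, col_idx, :].astype(float)
        p, effects, flagged = _founder_f_test(D, yv)
        top = g.founder_ids[int(np.argmax(effects))] if not np.all(effects == 0) else None
        rows.append((p, top, flagged))
    return pd.DataFrame(rows, columns=["p", "direction", "flagged"], index=g.marker_ids)


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genome_scan(
    g: GenotypeData,
    y: pd.Series,
    fdr_level: float = 0.05,
    backcross_test: str = "exact",
) -> pd.DataFrame:
    """Design-appropriate per-marker scan with BH FDR across all markers.

    Returns a frame ordered by (natural chromosome, position) with columns
    marker_id, chrom, pos_mb, p, q, direction, significant, flagged.
    """
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must be in (0, 1)")
    if g.design == "backcross":
        per = marker_association_backcross(g, y, test=backcross_test)
    else:
        per = marker_association_founder(g, y)
    res = pd.DataFrame(
        {
            "marker_id": g.marker_ids,
            "chrom": [str(c) for c in g.chrom],
            "pos_mb": g.pos_mb,
            "p": per["p"].to_numpy(),
            "direction": per["direction"].to_numpy(),
            "flagged": per["flagged"].to_numpy(),
        }
    )
    res["q"] = bh_fdr(res["p"].to_numpy())
    res["significant"] = res["q"] <= fdr_level
    res["_ck"] = res["chrom"].map(_chrom_sort_key)
    res = res.sort_values(["_ck", "pos_mb"], kind="mergesort").drop(columns="_ck")
    return res.reset_index(drop=True)[
        ["marker_id", "chrom", "pos_mb", "p", "q", "direction", "significant", "flagged"]
    ]


class GenomeScan:
    """Model object for a subtype-susceptibility genome scan."""

    def __init__(
        self,
        genotypes: GenotypeData,
        phenotype: pd.Series,
        *,
        fdr_level: float = 0.05,
        backcross_test: str = "exact",
    ) -> None:
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.fdr_level = fdr_level
        self.backcross_test = backcross_test

    @classmethod
    def from_calls(cls, genotypes: GenotypeData, calls: SubtypeCalls, target, **kw) -> "GenomeScan":
        return cls(genotypes, binarize_subtype(calls, target), **kw)

    def fit(self) -> "GenomeScanResults":
        table = genome_scan(
            self.genotypes,
            self.phenotype,
            fdr_level=self.fdr_level,
            backcross_test=self.backcross_test,
        )
        return GenomeScanResults(self, table)


class GenomeScanResults:
    """Per-marker association table plus convenience summaries."""

    def __init__(self, model: GenomeScan, table: pd.DataFrame) -> None:
        self.model = model
        self.table = table

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def top_marker(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]

    def summary(self) -> str:
        top = self.top_marker
        lines = [
            f"Genome scan ({self.model.genotypes.design}, "
            f"{self.model.genotypes.n_markers} markers, "
            f"{len(self.model.phenotype)} samples)",
            f"  cases: {int(self.model.phenotype.sum())}   FDR level: {self.model.fdr_level}",
            f"  significant markers (q <= {self.model.fdr_level}): {len(self.significant)}",
            f"  top marker: {top['marker_id']} chr{top['chrom']}:{top['pos_mb']:.1f} Mb "
            f"p={top['p']:.3g} q={top['q']:.3g} ({top['direction']})",
        ]
        return "\n".join(lines)


@dataclass
class IndependenceTestResult:
    p_value: float
    statistic: float
    dof: int
    method: str  # "chi2" | "permutation"
    table: pd.DataFrame


def _chi2_stat(observed: np.ndarray) -> tuple[float, np.ndarray]:
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return float(terms.sum()), expected


def subtype_metastasis_test(
    calls: SubtypeCalls | pd.Series,
    metastasis: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> IndependenceTestResult:
    """Chi-square independence test of subtype vs metastasis status.

    Assigned samples with non-missing metastasis status form the contingency
    table.  When every expected cell is at least 5 the asymptotic chi-square
    p is used; otherwise a seeded Monte-Carlo permutation of the metastasis
    labels (same statistic) provides the p-value.
    """
    labels = calls.labels if isinstance(calls, SubtypeCalls) else calls
    common = labels.index.intersection(metastasis.dropna().index)
    sub = labels.loc[common]
    keep = sub != UNASSIGNED
    sub = sub[keep]
    met = metastasis.loc[sub.index].astype(int)
    if sub.nunique() < 2:
        raise ValueError("need at least 2 subtype levels among assigned samples")
    table = pd.crosstab(sub, met)
    obs = table.to_numpy(dtype=float)
    stat, expected = _chi2_stat(obs)
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if np.all(expected >= 5):
        p = float(stats.chi2.sf(stat, dof)) if stat > 0 else 1.0
        method = "chi2"
    else:
        # margins are fixed under permutation, so the statistic reduces to a
        # function of the per-subtype case counts; vectorize over permutations
        rng = np.random.default_rng(seed)
        met_v = met.to_numpy()
        sub_codes = pd.factorize(sub)[0]
        n_sub = sub_codes.max() + 1
        onehot = np.eye(n_sub)[sub_codes]  # (n, n_sub)
        perms = rng.permuted(np.tile(met_v, (n_permutations, 1)), axis=1)
        cases = perms @ onehot  # (B, n_sub) cases per subtype
        n_s = onehot.sum(axis=0)
        m1 = met_v.sum()
        n_tot = len(met_v)
        e1 = n_s * m1 / n_tot
        e0 = n_s * (n_tot - m1) / n_tot
        stats_b = (((cases - e1) ** 2) / e1 + (((n_s - cases) - e0) ** 2) / e0).sum(axis=1)
        count = int(np.sum(stats_b >= stat - 1e-12))
        p = (1 + count) / (1 + n_permutations)
        method = "permutation"
    return IndependenceTestResult(
        p_value=float(min(max(p, _P_FLOOR), 1.0)),
        statistic=stat,
        dof=dof,
        method=method,
        table=table,
    )
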