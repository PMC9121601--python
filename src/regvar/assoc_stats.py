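"""eQTL association scanning, multiple-testing correction, cross-dataset
consensus tallies and case/control differential expression.

The eQTL scan is an ordinary least-squares regression of (log2) expression
on alternate-allele dosage, one SNP–gene pair at a time; the published
brain eQTL resources this emulates each ran richer covariate-adjusted
models, so precomputed association tables can be ingested instead and only
the correction/tally logic applied. Significance rules mirror the two used
in practice: per-dataset FDR < α (BH step-up) and uncorrected p < τ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "EqtlAssociation",
    "ConsensusSummary",
    "DifferentialExpressionResult",
    "SignificanceRule",
    "eqtl_scan",
    "bh_fdr",
    "bonferroni",
    "annotate_significance",
    "consensus_tally",
    "differential_expression",
]

_TINY_P = 5e-324  # smallest subnormal double; flags a numerically-zero residual fit


@dataclass
class ExpressionDataset:
    """One expression resource: genes×samples expression plus SNP dosages."""

    dataset_id: str
    gene_ids: List[str]
    sample_ids: List[str]
    expression: np.ndarray  # (n_genes, n_samples), log2 scale
    snp_ids: List[str] = field(default_factory=list)
    dosages: Optional[np.ndarray] = None  # (n_snps, n_samples), values {0,1,2}
    group_labels: Optional[List[str]] = None  # 'case' / 'control'

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        n_genes, n_samples = self.expression.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValueError(f"{self.dataset_id}: expression shape mismatch")
        if self.dosages is not None:
            self.dosages = np.asarray(self.dosages, dtype=float)
            if self.dosages.shape != (len(self.snp_ids), n_samples):
                raise ValueError(f"{self.dataset_id}: dosage shape mismatch")
        if self.group_labels is not None and len(self.group_labels) != n_samples:
            raise ValueError(f"{self.dataset_id}: group label length mismatch")

    def gene(self, gene_id: str) -> np.ndarray:
        return self.expression[self.gene_ids.index(gene_id)]

    def dosage(self, snp_id: str) -> np.ndarray:
        if self.dosages is None:
            raise ValueError(f"{self.dataset_id}: no dosages")
        return self.dosages[self.snp_ids.index(snp_id)]


@dataclass
class EqtlAssociation:
    dataset_id: str
    snp_id: str
    gene_id: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    fdr: Optional[float] = None
    significant: bool = False
    flag: str = ""


def eqtl_scan(
    ds: ExpressionDataset, pairs: Sequence[Tuple[str, str]]
) -> List[EqtlAssociation]:
    """OLS of expression on dosage for each (snp, gene) pair.

    beta = cov(g, y) / var(g); two-sided p from t with n−2 df. Pairs with
    zero dosage variance are skipped with a warning. A perfect fit (zero
    residual variance, nonzero slope) gets the smallest representable
    positive p and is flagged; a constant expression vector gets beta 0,
    p 1 by convention.
    """
    n = len(ds.sample_ids)
    if n < 3:
        raise ValueError(f"{ds.dataset_id}: need at least 3 samples, have {n}")
    out: List[EqtlAssociation] = []
    for snp_id, gene_id in pairs:
        g = ds.dosage(snp_id)
        y = ds.gene(gene_id)
        g_c = g - g.mean()
        sxx = float(np.dot(g_c, g_c))
        if sxx == 0.0:
            logger.warning(
                "%s: dosage of %s has zero variance; skipping %s~%s",
                ds.dataset_id, snp_id, gene_id, snp_id,
            )
            continue
        y_c = y - y.mean()
        beta = float(np.dot(g_c, y_c) / sxx)
        resid = y_c - beta * g_c
        rss = float(np.dot(resid, resid))
        flag = ""
        if rss <= 0.0 or np.isclose(rss, 0.0, atol=1e-300):
            if beta == 0.0:
                se, t, p = 0.0, 0.0, 1.0
                flag = "constant_expression"
            else:
                se, t, p = 0.0, np.inf, _TINY_P
                flag = "perfect_fit"
        else:
            s2 = rss / (n - 2)
            se = float(np.sqrt(s2 / sxx))
            t = beta / se
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        out.append(
            EqtlAssociation(
                dataset_id=ds.dataset_id, snp_id=snp_id, gene_id=gene_id,
                beta=beta, se=se, t_stat=float(t), p_value=p, flag=flag,
            )
        )
    return out


def _check_pvalues(p_values: Sequence[float]) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = _check_pvalues(p_values)
    if p.size == 0:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def bonferroni(p_values: Sequence[float]) -> List[float]:
    """min(1, p·m) elementwise."""
    p = _check_pvalues(p_values)
    return list(np.minimum(1.0, p * p.size))


@dataclass(frozen=True)
class SignificanceRule:
    """Either 'fdr' < alpha (BH within dataset) or raw 'p' < tau."""

    kind: str = "fdr"
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("fdr", "p"):
            raise ValueError(f"rule kind must be 'fdr' or 'p', got {self.kind!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("rule threshold must lie in (0,1)")


def annotate_significance(
    associations: Sequence[EqtlAssociation], rule: SignificanceRule
) -> None:
    """Fill fdr/significant in place; FDR is adjusted within each dataset."""
    by_ds: Dict[str, List[EqtlAssociation]] = {}
    for a in associations:
        by_ds.setdefault(a.dataset_id, []).append(a)
    for assocs in by_ds.values():
        fdrs = bh_fdr([a.p_value for a in assocs])
        for a, q in zip(assocs, fdrs):
            if a.fdr is None:
                a.fdr = float(q)
            if rule.kind == "fdr":
                a.significant = a.fdr < rule.threshold
            else:
                a.significant = a.p_value < rule.threshold


@dataclass
class ConsensusSummary:
    """Cross-dataset support for SNP–gene associations."""

    n_datasets: int
    datasets_per_snp: Dict[str, int]
    support: Dict[Tuple[str, str], List[str]]  # (snp, gene) -> dataset ids
    tallies: Dict[int, int]  # k -> number of SNPs significant in >= k datasets

    def snps_with_support(self, k: int) -> List[str]:
        return sorted(s for s, c in self.datasets_per_snp.items() if c >= k)


def consensus_tally(
    associations: Sequence[EqtlAssociation],
    rule: SignificanceRule,
    snp_ids: Sequence[str],
    n_datasets: Optional[int] = None,
) -> ConsensusSummary:
    """Per-SNP count of datasets with ≥1 significant gene association.

    Associations for SNPs outside ``snp_ids`` are ignored with a warning.
    The tallies (number of SNPs with support in ≥k datasets, k=1..D) are
    non-increasing in k by construction.
    """
    annotate_significance(list(associations), rule)
    known = set(snp_ids)
    ds_ids = sorted({a.dataset_id for a in associations})
    if n_datasets is None:
        n_datasets = len(ds_ids)
    datasets_per_snp: Dict[str, set] = {s: set() for s in known}
    support: Dict[Tuple[str, str], List[str]] = {}
    for a in associations:
        if a.snp_id not in known:
            logger.warning("association for unknown SNP %s ignored", a.snp_id)
            continue
        if a.significant:
            datasets_per_snp[a.snp_id].add(a.dataset_id)
            support.setdefault((a.snp_id, a.gene_id), [])
            if a.dataset_id not in support[(a.snp_id, a.gene_id)]:
                support[(a.snp_id, a.gene_id)].append(a.dataset_id)
    counts = {s: len(ds) for s, ds in datasets_per_snp.items()}
    tallies = {
        k: sum(1 for c in counts.values() if c >= k) for k in range(1, n_datasets + 1)
    }
    return ConsensusSummary(
        n_datasets=n_datasets,
        datasets_per_snp=counts,
        support={k: sorted(v) for k, v in support.items()},
        tallies=tallies,
    )


@dataclass
class DifferentialExpressionResult:
    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float


def differential_expression(ds: ExpressionDataset) -> List[DifferentialExpressionResult]:
    """Case/control screen per gene: Welch t-test on log2 expression.

    log2FC is mean(case) − mean(control); FDR is BH across the tested genes.
    """
    if ds.group_labels is None:
        raise ValueError(f"{ds.dataset_id}: no case/control labels")
    labels = np.asarray(ds.group_labels)
    case = labels == "case"
    control = labels == "control"
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError(
            f"{ds.dataset_id}: both groups need >= 2 samples "
            f"(case={int(case.sum())}, control={int(control.sum())})"
        )
    fcs, ps = [], []
    for row in ds.expression:
        a, b = row[case], row[control]
        fcs.append(float(a.mean() - b.mean()))
        res = stats.ttest_ind(a, b, equal_var=False)
        ps.append(float(res.pvalue) if np.isfinite(res.pvalue) else 1.0)
    fdrs = bh_fdr(ps)
    return [
        DifferentialExpressionResult(gene_id=g, log2_fc=fc, p_value=p, fdr=float(q))
        for g, fc, p, q in zip(ds.gene_ids, fcs, ps, fdrs)
    ]
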