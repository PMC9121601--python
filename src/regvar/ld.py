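"""Pairwise linkage disequilibrium r² from phased haplotypes.

r² is computed by direct haplotype counting on a phased panel:
d = p_ab − p_a·p_b and r² = d² / (p_a(1−p_a) p_b(1−p_b)). Index-SNP LD
partners are all panel variants exceeding a strict r² threshold (study
convention: r² > 0.6), each assigned to the index SNP it tags best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .core import Variant

logger = logging.getLogger(__name__)

__all__ = ["HaplotypePanel", "LdPair", "MonomorphicSiteError", "r_squared", "ld_partners"]


class MonomorphicSiteError(ValueError):
    """r² is undefined when a site carries a single allele in the panel."""


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotypes: rows are 2·n_samples haplotypes, columns variants."""

    variants: List[Variant]
    haplotypes: np.ndarray
    sample_ids: List[str]
    skipped_records: int = 0

    def __post_init__(self) -> None:
        haps = np.asarray(self.haplotypes, dtype=np.int8)
        if haps.ndim != 2 or haps.shape != (2 * len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"haplotype matrix {haps.shape} does not match "
                f"(2*{len(self.sample_ids)} samples, {len(self.variants)} variants)"
            )
        if haps.size and not np.isin(haps, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 (ref) or 1 (alt)")
        self.haplotypes = haps

    @property
    def variant_ids(self) -> List[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        return self.haplotypes[:, self.variant_ids.index(variant_id)]


@dataclass(frozen=True)
class LdPair:
    id_a: str
    id_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    r2: float


def r_squared(hap_a: Sequence[int], hap_b: Sequence[int], id_a: str = "a", id_b: str = "b") -> LdPair:
    """LD between two sites from phased haplotype vectors, by direct counting.

    The allele coded 1 is arbitrary: r² is invariant under swapping labels
    at either site. Raises :class:`MonomorphicSiteError` when either site is
    fixed, where r² is undefined.
    """
    a = np.asarray(hap_a, dtype=np.int64)
    b = np.asarray(hap_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D with length >= 2")
    n = len(a)
    n_a = int(a.sum())
    n_b = int(b.sum())
    if n_a in (0, n) or n_b in (0, n):
        raise MonomorphicSiteError(
            f"undefined r2: monomorphic site ({id_a} count={n_a}/{n}, {id_b} count={n_b}/{n})"
        )
    n_ab = int((a & b).sum())
    # integer-count form of d^2 / (p_a(1-p_a) p_b(1-p_b)); exact r2 = 1 for copies
    num = n * n_ab - n_a * n_b
    r2 = num * num / (n_a * (n - n_a) * n_b * (n - n_b))
    return LdPair(
        id_a=id_a, id_b=id_b,
        p_a=n_a / n, p_b=n_b / n, p_ab=n_ab / n,
        d=num / (n * n),
        r2=min(r2, 1.0),
    )


def ld_partners(
    panel: HaplotypePanel,
    index_ids: Sequence[str],
    r2_min: float = 0.6,
) -> List[Variant]:
    """Extract panel variants in LD with index SNPs (strictly r² > r2_min).

    Each index SNP contributes itself (r² = 1) plus every panel variant with
    r² > r2_min. A variant tagging several index SNPs is assigned to the one
    with the highest r² (ties go to the earlier index in input order).
    Output is ordered by index (input order) then descending r².
    Monomorphic panel sites and absent index IDs are skipped with a warning.
    """
    if not index_ids:
        raise ValueError("empty index-SNP list")
    if not 0.0 < r2_min <= 1.0:
        raise ValueError(f"r2_min must lie in (0,1], got {r2_min}")
    ids = panel.variant_ids
    present: List[str] = []
    for idx in index_ids:
        if idx in ids:
            present.append(idx)
        else:
            logger.warning("index SNP %s absent from panel; skipped", idx)
    if not present:
        raise ValueError("none of the index SNPs are present in the panel")

    index_order = {idx: k for k, idx in enumerate(present)}
    best: dict[int, tuple[str, float]] = {}  # variant column -> (index_id, r2)
    for idx in present:
        hap_idx = panel.column(idx)
        for j, var in enumerate(panel.variants):
            if var.id == idx:
                r2 = 1.0
            else:
                try:
                    r2 = r_squared(hap_idx, panel.haplotypes[:, j], idx, var.id).r2
                except MonomorphicSiteError:
                    logger.warning("skipping monomorphic site %s", var.id)
                    continue
                # strict threshold; at the degenerate r2_min = 1.0 boundary
                # only exact copies (r2 = 1) can qualify
                if not (r2 > r2_min or (r2_min == 1.0 and r2 == 1.0)):
                    continue
            if j not in best:
                best[j] = (idx, r2)
            else:
                old_idx, old_r2 = best[j]
                if r2 > old_r2 or (r2 == old_r2 and index_order[idx] < index_order[old_idx]):
                    best[j] = (idx, r2)

    out = [
        replace(panel.variants[j], index_id=idx, r2_to_index=r2)
        for j, (idx, r2) in best.items()
    ]
    out.sort(key=lambda v: (index_order[v.index_id], -v.r2_to_index, v.pos, v.id))
    return out
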