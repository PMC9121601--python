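"""Classify TF-binding-disrupting SNPs and tally them per TF.

A SNP disrupts a TF's binding when (1) one and only one of its alleles
carries a significant occurrence of that TF's motif covering the SNP, and
(2) the SNP falls inside a ChIP-Seq peak of the same TF. Both criteria must
hold; a motif change outside the TF's bound regions is not called. A
permissive mode additionally calls SNPs where both alleles keep the motif
but the match score shifts by at least ``delta_bits``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .core import Peak, Variant, normalize_chrom
from .motif import AlleleScanResult, MotifHit

__all__ = [
    "DisruptionCall",
    "DisruptionSummary",
    "PeakIndex",
    "snp_in_peak",
    "classify_disruption",
    "summarize_disruptions",
    "calls_to_frame",
]

VERDICTS = ("disrupting", "motif_retained", "no_motif", "no_peak")


@dataclass(frozen=True)
class DisruptionCall:
    variant_id: str
    tf_name: str
    motif_id: str
    in_peak: bool
    ref_hit: Optional[MotifHit]
    alt_hit: Optional[MotifHit]
    verdict: str

    @property
    def delta_score_bits(self) -> Optional[float]:
        """ref − alt score difference, defined only when both alleles hit."""
        if self.ref_hit is None or self.alt_hit is None:
            return None
        return self.ref_hit.score_bits - self.alt_hit.score_bits

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if (self.verdict == "no_peak") != (not self.in_peak):
            raise ValueError("verdict no_peak inconsistent with in_peak flag")


class PeakIndex:
    """Interval-tree lookup of peaks, keyed by (TF, chromosome)."""

    def __init__(self, peaks: Sequence[Peak]):
        self._trees: Dict[Tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.tf_names = sorted({p.tf_name for p in peaks})
        for p in peaks:
            self._trees[(p.tf_name, normalize_chrom(p.chrom))].addi(p.start, p.end, p)

    def contains(self, variant: Variant, tf_name: str) -> bool:
        tree = self._trees.get((tf_name, normalize_chrom(variant.chrom)))
        return bool(tree) and bool(tree[variant.pos0])


def snp_in_peak(variant: Variant, peaks: Sequence[Peak], tf_name: str) -> bool:
    """True iff the SNP base (0-based pos−1) lies inside a peak of this TF."""
    return any(
        p.tf_name == tf_name and p.contains(variant.chrom, variant.pos0) for p in peaks
    )


def classify_disruption(
    scan_pair: Tuple[AlleleScanResult, AlleleScanResult],
    variant: Variant,
    peaks,
    tf_of_motif: Mapping[str, str],
    permissive_delta_bits: Optional[float] = None,
) -> List[DisruptionCall]:
    """One :class:`DisruptionCall` per scanned motif for one SNP.

    ``peaks`` may be a sequence of :class:`Peak` or a prebuilt
    :class:`PeakIndex`. When ``permissive_delta_bits`` is set, a SNP whose
    two alleles both hit but with |Δscore| ≥ that many bits is also called
    disrupting (off by default).
    """
    ref_res, alt_res = scan_pair
    if ref_res.variant_id != alt_res.variant_id or ref_res.variant_id != variant.id:
        raise ValueError("scan results and variant do not refer to the same SNP")
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(list(peaks))
    calls: List[DisruptionCall] = []
    for motif_id in ref_res.best_hit:
        if motif_id not in tf_of_motif:
            raise KeyError(f"motif {motif_id} has no TF mapping")
        tf = tf_of_motif[motif_id]
        ref_hit = ref_res.best_hit.get(motif_id)
        alt_hit = alt_res.best_hit.get(motif_id)
        in_peak = index.contains(variant, tf)
        if not in_peak:
            verdict = "no_peak"
        elif (ref_hit is None) != (alt_hit is None):
            verdict = "disrupting"
        elif ref_hit is None and alt_hit is None:
            verdict = "no_motif"
        else:
            verdict = "motif_retained"
            if permissive_delta_bits is not None:
                delta = abs(ref_hit.score_bits - alt_hit.score_bits)
                if delta >= permissive_delta_bits:
                    verdict = "disrupting"
        calls.append(
            DisruptionCall(
                variant_id=variant.id,
                tf_name=tf,
                motif_id=motif_id,
                in_peak=in_peak,
                ref_hit=ref_hit,
                alt_hit=alt_hit,
                verdict=verdict,
            )
        )
    return calls


@dataclass
class DisruptionSummary:
    """Per-TF and per-SNP tallies of disrupting calls."""

    snps_per_tf: Dict[str, int] = field(default_factory=dict)
    tfs_per_snp: Dict[str, List[str]] = field(default_factory=dict)
    n_multi_tf_snps: int = 0

    @property
    def disrupting_snps(self) -> List[str]:
        return sorted(self.tfs_per_snp)


def summarize_disruptions(calls: Sequence[DisruptionCall]) -> DisruptionSummary:
    """Tally disrupting SNPs per TF; a SNP hitting two motifs of one TF counts once."""
    tfs_per_snp: Dict[str, set] = defaultdict(set)
    for call in calls:
        if call.verdict == "disrupting":
            tfs_per_snp[call.variant_id].add(call.tf_name)
    snps_per_tf: Dict[str, int] = defaultdict(int)
    for tfs in tfs_per_snp.values():
        for tf in tfs:
            snps_per_tf[tf] += 1
    return DisruptionSummary(
        snps_per_tf=dict(sorted(snps_per_tf.items())),
        tfs_per_snp={snp: sorted(tfs) for snp, tfs in sorted(tfs_per_snp.items())},
        n_multi_tf_snps=sum(1 for tfs in tfs_per_snp.values() if len(tfs) >= 2),
    )


def calls_to_frame(calls: Sequence[DisruptionCall]) -> pd.DataFrame:
    """Flatten calls into the TSV layout used by the pipeline."""
    rows = []
    for c in calls:
        rows.append(
            {
                "snp_id": c.variant_id,
                "tf": c.tf_name,
                "motif_id": c.motif_id,
                "verdict": c.verdict,
                "in_peak": c.in_peak,
                "ref_score": c.ref_hit.score_bits if c.ref_hit else float("nan"),
                "ref_p": c.ref_hit.pvalue if c.ref_hit else float("nan"),
                "alt_score": c.alt_hit.score_bits if c.alt_hit else float("nan"),
                "alt_p": c.alt_hit.pvalue if c.alt_hit else float("nan"),
                "delta_score": c.delta_score_bits if c.delta_score_bits is not None else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "tf", "motif_id", "verdict", "in_peak",
            "ref_score", "ref_p", "alt_score", "alt_p", "delta_score",
        ],
    )
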