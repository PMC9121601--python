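"""PWM scoring with exact match p-values and allele-specific window scanning.

A motif match is scored as a log-odds sum in bits against a 0-order
background model. To attach an exact p-value to a score, the matrix is
rounded onto an integer lattice (granularity ``epsilon`` bits) and the full
null distribution of the integer score — the score of a random background
word of the motif's width — is built by per-column convolution. Scanning and
the null distribution use the same rounded matrix, so the reported p-values
are exact for the matrix actually scanned, in the style of FIMO.

Allele-specific scanning extracts the window of ``flank`` bases either side
of a SNP, substitutes the alternate allele, and records for each motif the
best significant occurrence per allele (both strands, optionally required to
cover the SNP base). A motif hit present for exactly one allele is the
signature of a binding-site-disrupting variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import BASE_INDEX, DNA_BASES, SequenceRecord, Variant, normalize_chrom, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "Background",
    "PWM",
    "LogOddsMatrix",
    "ScorePvalueTable",
    "MotifHit",
    "AlleleScanResult",
    "ScanConfig",
    "MotifScanner",
    "build_pwm_from_sites",
    "log_odds",
    "score_pvalue_table",
    "allele_windows",
    "scan_window",
    "scan_alleles",
    "motif_similarity",
    "reverse_complement_pwm",
]


@dataclass(frozen=True)
class Background:
    """0-order background base composition. Default: uniform."""

    freq: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        arr = np.asarray(self.freq, dtype=float)
        if arr.shape != (4,) or np.any(arr <= 0):
            raise ValueError("background needs 4 strictly positive frequencies (A,C,G,T)")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {arr.sum()}, not 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freq, dtype=float)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities, rows (A,C,G,T)."""

    motif_id: str
    probs: np.ndarray  # shape (w, 4)
    tf_name: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: probs must be (w, 4) with w >= 1")
        if np.any(probs < 0):
            raise ValueError(f"motif {self.motif_id}: negative probabilities")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id}: row {bad} sums to {sums[bad]:.6g}, not 1"
            )
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(DNA_BASES[a] for a in np.argmax(self.probs, axis=1))

    def information_content(self, background: Background = Background()) -> np.ndarray:
        """Per-column relative entropy vs the background, in bits."""
        bg = background.array
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.probs > 0, self.probs * np.log2(self.probs / bg), 0.0)
        return terms.sum(axis=1)


def reverse_complement_pwm(pwm: PWM) -> PWM:
    # reversing both axes maps position i,base a -> position w-1-i, complement(a)
    # because the (A,C,G,T) order is self-complementary under reversal
    return replace(pwm, probs=pwm.probs[::-1, ::-1].copy())


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the allele-specific motif scan.

    flank
        Bases either side of the SNP extracted into each allele window.
    p_threshold
        A motif occurrence must have exact p-value strictly below this.
    require_snp_overlap
        Only occurrences whose footprint covers the SNP base count; an
        occurrence away from the SNP cannot differ between alleles.
    pseudocount_fraction
        Fraction ``pc`` of the background added to PWM probabilities before
        log-odds, bounding scores away from -inf.
    epsilon
        Integer-lattice granularity of the score in bits.
    """

    flank: int = 20
    p_threshold: float = 0.001
    both_strands: bool = True
    require_snp_overlap: bool = True
    pseudocount_fraction: float = 0.01
    epsilon: float = 1e-4
    background: Background = field(default_factory=Background)
    allow_infinite_scores: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0,1)")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.pseudocount_fraction < 0:
            raise ValueError("pseudocount_fraction must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class LogOddsMatrix:
    """Background-normalized scoring matrix in bits plus its integer rounding."""

    motif_id: str
    scores: np.ndarray  # (w, 4), bits
    int_scores: np.ndarray  # (w, 4), scores rounded at epsilon
    epsilon: float
    pseudocount_fraction: float
    background: Background

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    @property
    def max_int_score(self) -> int:
        return int(self.int_scores.max(axis=1).sum())

    @property
    def min_int_score(self) -> int:
        return int(self.int_scores.min(axis=1).sum())


class LatticeOverflowError(ValueError):
    """Integer score lattice too large; rerun with a larger epsilon."""


@dataclass
class ScorePvalueTable:
    """Exact null distribution of the integer match score.

    ``pmf[j]`` is the probability that a random background word of the
    motif's width has integer score ``min_score + j``; ``sf[j]`` is the
    corresponding upper tail P(S >= min_score + j).
    """

    motif_id: str
    epsilon: float
    min_score: int
    pmf: np.ndarray
    sf: np.ndarray

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.pmf) - 1

    def pvalue(self, int_score: int) -> float:
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            return 0.0
        return float(self.sf[int_score - self.min_score])


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    strand: str  # '+' or '-'
    start: int  # 0-based offset within the scanned window, forward coordinates
    width: int
    score_bits: float
    pvalue: float
    covers_snp: bool
    int_score: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class AlleleScanResult:
    variant_id: str
    allele: str  # 'ref' or 'alt'
    window_sequence: str
    snp_index: int
    best_hit: Dict[str, Optional[MotifHit]] = field(default_factory=dict)


def build_pwm_from_sites(
    sites: Sequence[str],
    pseudocount: float = 0.0,
    motif_id: str = "derived",
    tf_name: str = "",
) -> PWM:
    """Derive a PWM from aligned binding-site sequences.

    probs(i, a) = (count(i, a) + pseudocount) / (n_sites + 4 * pseudocount)
    """
    if not sites:
        raise ValueError("no sites given")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("sites have unequal lengths")
    counts = np.zeros((width, 4), dtype=float)
    for site in sites:
        for i, base in enumerate(site.upper()):
            if base not in DNA_BASES:
                raise ValueError(f"illegal base {base!r} in site {site!r}")
            counts[i, BASE_INDEX[base]] += 1
    probs = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PWM(motif_id=motif_id, tf_name=tf_name, probs=probs)


def log_odds(pwm: PWM, cfg: ScanConfig = ScanConfig()) -> LogOddsMatrix:
    """Bits-scale scoring matrix: log2((p + pc*bg) / ((1+pc)*bg))."""
    bg = cfg.background.array
    pc = cfg.pseudocount_fraction
    adjusted = (pwm.probs + pc * bg) / (1.0 + pc)
    with np.errstate(divide="ignore"):
        scores = np.log2(adjusted / bg)
    if np.any(np.isneginf(scores)) and not cfg.allow_infinite_scores:
        raise ValueError(
            f"motif {pwm.motif_id}: zero probability with pseudocount 0 gives an "
            "infinite score; set a pseudocount or allow_infinite_scores"
        )
    finite = np.where(np.isfinite(scores), scores, 0.0)
    int_scores = np.rint(finite / cfg.epsilon).astype(np.int64)
    # -inf entries are pinned far below anything reachable so they never win a scan
    int_scores[~np.isfinite(scores)] = np.iinfo(np.int32).min
    return LogOddsMatrix(
        motif_id=pwm.motif_id,
        scores=scores,
        int_scores=int_scores,
        epsilon=cfg.epsilon,
        pseudocount_fraction=pc,
        background=cfg.background,
    )


_MAX_LATTICE = 50_000_000


def score_pvalue_table(lom: LogOddsMatrix, cfg: ScanConfig = ScanConfig()) -> ScorePvalueTable:
    """Exact distribution of the integer score under the background model.

    Built by convolving the four-point column distributions over the integer
    score lattice, one motif column at a time.
    """
    if not np.all(np.isfinite(lom.scores)):
        raise ValueError(f"motif {lom.motif_id}: infinite scores have no exact p-value table")
    ints = lom.int_scores
    bg = cfg.background.array
    mins = ints.min(axis=1)
    span = int((ints.max(axis=1) - mins).sum())
    if span > _MAX_LATTICE:
        raise LatticeOverflowError(
            f"motif {lom.motif_id}: score lattice of {span} cells exceeds "
            f"{_MAX_LATTICE}; increase epsilon (currently {lom.epsilon})"
        )
    pmf = np.ones(1, dtype=float)
    for i in range(lom.width):
        new = np.zeros(len(pmf) + int(ints[i].max() - mins[i]), dtype=float)
        for a in range(4):
            off = int(ints[i, a] - mins[i])
            new[off : off + len(pmf)] += bg[a] * pmf
        pmf = new
    sf = np.cumsum(pmf[::-1])[::-1]
    return ScorePvalueTable(
        motif_id=lom.motif_id,
        epsilon=lom.epsilon,
        min_score=int(mins.sum()),
        pmf=pmf,
        sf=sf,
    )


def _reference_lookup(
    reference, chrom: str
) -> SequenceRecord:
    """Find a chromosome in a reference given as record, list or mapping."""
    if isinstance(reference, SequenceRecord):
        records = [reference]
    elif isinstance(reference, Mapping):
        records = list(reference.values())
    else:
        records = list(reference)
    want = normalize_chrom(chrom)
    for rec in records:
        if normalize_chrom(rec.name) == want:
            return rec
    raise KeyError(f"chromosome {chrom!r} not found in reference")


def allele_windows(
    variant: Variant, reference, cfg: ScanConfig = ScanConfig()
) -> Tuple[str, str, int]:
    """Extract the ±flank windows carrying each allele of a SNP.

    Returns (ref_window, alt_window, snp_index). The windows are identical
    except at snp_index; they are clamped at sequence ends.
    """
    rec = _reference_lookup(reference, variant.chrom)
    seq = rec.sequence
    pos0 = variant.pos0
    if not 0 <= pos0 < len(seq):
        raise ValueError(
            f"variant {variant.id}: position {variant.pos} outside sequence "
            f"{rec.name!r} of length {len(seq)}"
        )
    observed = seq[pos0]
    if observed != variant.ref:
        raise ValueError(
            f"variant {variant.id}: REF mismatch at {variant.chrom}:{variant.pos} "
            f"(expected {variant.ref}, reference has {observed})"
        )
    start = max(0, pos0 - cfg.flank)
    end = min(len(seq), pos0 + cfg.flank + 1)
    snp_index = pos0 - start
    ref_window = seq[start:end]
    alt_window = ref_window[:snp_index] + variant.alt + ref_window[snp_index + 1 :]
    return ref_window, alt_window, snp_index


def _encode(window: str) -> np.ndarray:
    return np.array([BASE_INDEX.get(b, 4) for b in window.upper()], dtype=np.int64)


def _window_int_scores(encoded: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Integer score at every offset; N positions contribute 0 (background)."""
    w = ints.shape[0]
    n_offsets = len(encoded) - w + 1
    out = np.empty(n_offsets, dtype=np.int64)
    for start in range(n_offsets):
        total = 0
        for i in range(w):
            base = encoded[start + i]
            if base < 4:
                total += ints[i, base]
        out[start] = total
    return out


def scan_window(
    window: str,
    lom: LogOddsMatrix,
    table: ScorePvalueTable,
    cfg: ScanConfig = ScanConfig(),
    snp_index: int = 0,
) -> Optional[MotifHit]:
    """Best significant occurrence of one motif in a window.

    Scans every offset on the forward strand and, when configured, of the
    reverse complement (mapped back to forward coordinates). Candidates must
    have exact p-value < cfg.p_threshold and, when cfg.require_snp_overlap,
    cover snp_index. Ties are broken by score, then leftmost start, then '+'
    strand. Returns None when no candidate qualifies.
    """
    w = lom.width
    if len(window) < w:
        logger.warning(
            "window of length %d shorter than motif %s (width %d); no scan",
            len(window), lom.motif_id, w,
        )
        return None
    strands = [("+", window)]
    if cfg.both_strands:
        strands.append(("-", reverse_complement(window)))
    best: Optional[MotifHit] = None
    for strand, seq in strands:
        scores = _window_int_scores(_encode(seq), lom.int_scores)
        for offset, int_score in enumerate(scores):
            fwd_start = offset if strand == "+" else len(window) - w - offset
            covers = fwd_start <= snp_index < fwd_start + w
            if cfg.require_snp_overlap and not covers:
                continue
            pval = table.pvalue(int(int_score))
            if not pval < cfg.p_threshold:
                continue
            hit = MotifHit(
                motif_id=lom.motif_id,
                strand=strand,
                start=fwd_start,
                width=w,
                score_bits=float(int_score) * lom.epsilon,
                pvalue=pval,
                covers_snp=covers,
                int_score=int(int_score),
            )
            if best is None or (
                (hit.int_score, -hit.start, hit.strand == "+")
                > (best.int_score, -best.start, best.strand == "+")
            ):
                best = hit
    return best


class MotifScanner:
    """Precomputed log-odds matrices and exact p-value tables for a motif set."""

    def __init__(self, pwms: Sequence[PWM], cfg: ScanConfig = ScanConfig()):
        self.cfg = cfg
        self.pwms = list(pwms)
        max_w = max((p.width for p in self.pwms), default=1)
        if cfg.flank < max_w - 1:
            logger.warning(
                "flank %d < max motif width - 1 (%d); edge occurrences may be missed",
                cfg.flank, max_w - 1,
            )
        self.log_odds = {p.motif_id: log_odds(p, cfg) for p in self.pwms}
        self.tables = {
            mid: score_pvalue_table(lom, cfg) for mid, lom in self.log_odds.items()
        }
        self.tf_of_motif = {p.motif_id: p.tf_name for p in self.pwms}

    def scan_window(self, window: str, motif_id: str, snp_index: int = 0) -> Optional[MotifHit]:
        return scan_window(
            window, self.log_odds[motif_id], self.tables[motif_id], self.cfg, snp_index
        )

    def scan_alleles(
        self, variant: Variant, reference
    ) -> Tuple[AlleleScanResult, AlleleScanResult]:
        ref_win, alt_win, snp_index = allele_windows(variant, reference, self.cfg)
        results = []
        for allele, window in (("ref", ref_win), ("alt", alt_win)):
            res = AlleleScanResult(
                variant_id=variant.id,
                allele=allele,
                window_sequence=window,
                snp_index=snp_index,
            )
            for pwm in self.pwms:
                res.best_hit[pwm.motif_id] = self.scan_window(window, pwm.motif_id, snp_index)
            results.append(res)
        return results[0], results[1]


def scan_alleles(
    variant: Variant,
    reference,
    pwms: Sequence[PWM],
    cfg: ScanConfig = ScanConfig(),
    scanner: Optional[MotifScanner] = None,
) -> Tuple[AlleleScanResult, AlleleScanResult]:
    """Scan both allele windows of a SNP against a motif set.

    Builds a throwaway :class:`MotifScanner` unless one is supplied; callers
    scanning many variants should construct the scanner once.
    """
    if scanner is None:
        scanner = MotifScanner(pwms, cfg)
    return scanner.scan_alleles(variant, reference)


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.dot(da, da))
    vb = float(np.dot(db, db))
    if va == 0.0 or vb == 0.0:
        return 0.0  # zero-variance column carries no shape information
    return float(np.dot(da, db) / math.sqrt(va * vb))


def motif_similarity(
    pwm_a: PWM, pwm_b: PWM, min_overlap: int = 5
) -> Tuple[float, int, str]:
    """Best ungapped alignment similarity between two PWMs.

    Over all offsets with at least ``min_overlap`` aligned columns and both
    orientations of ``pwm_b``, the maximum mean column-wise Pearson
    correlation of the probability vectors. Ties break to the smallest
    |offset|, then to the '+' orientation. Returns (similarity, offset,
    orientation); offset is the position of pwm_b's first column relative to
    pwm_a's.
    """
    wa, wb = pwm_a.width, pwm_b.width
    if min_overlap > wa or min_overlap > wb:
        raise ValueError(f"min_overlap {min_overlap} exceeds a motif width ({wa}, {wb})")
    best: Optional[Tuple[float, int, str]] = None
    for orientation in "+-":
        probs_b = pwm_b.probs if orientation == "+" else reverse_complement_pwm(pwm_b).probs
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a = max(0, offset)
            hi_a = min(wa, offset + wb)
            if hi_a - lo_a < min_overlap:
                continue
            corrs = [
                _column_corr(pwm_a.probs[i], probs_b[i - offset])
                for i in range(lo_a, hi_a)
            ]
            sim = float(np.mean(corrs))
            key = (sim, -abs(offset), orientation == "+")
            if best is None or key > (best[0], -abs(best[1]), best[2] == "+"):
                best = (sim, offset, orientation)
    assert best is not None
    return best
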