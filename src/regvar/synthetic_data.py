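"""Seeded generator for a complete synthetic regulatory-genomics study.

One scenario bundles every input the pipeline consumes — a reference
sequence, TF motifs with planted genomic instances, ChIP-Seq-style peaks, a
phased haplotype panel with LD structure around index SNPs, multi-dataset
expression with planted eQTL effects, a case/control expression matrix, and
allelic read counts — together with a machine-readable truth table.

Planted SNP classes
    disrupting      in a planted motif (max-information column) inside a
                    same-TF peak; the alternate allele minimizes the column
                    probability and abolishes the motif match.
    in_peak_no_motif  inside a peak but with no motif occurrence near the SNP.
    motif_no_peak   in a planted motif instance that lies outside all peaks.
    background      away from peaks and motifs.
    index           a GWAS index SNP (LD anchor; placed like background).

Class semantics are verified at generation time with the same scanner the
pipeline uses: windows that would violate a class label (e.g. a chance
motif occurrence at a background SNP) are resampled, so truth labels hold
by construction. LD partners are built by marginal resampling: a partner
copies the index haplotype and independently redraws each entry with
probability m = 1 − sqrt(r²_target), giving expected correlation
sqrt(r²_target). Everything is a pure function of the configuration seed;
regenerated scenarios are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .assoc_stats import ExpressionDataset
from .core import DNA_BASES, Peak, SequenceRecord, Variant
from .ld import HaplotypePanel, r_squared
from .motif import PWM, Background, MotifScanner, ScanConfig

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "ScenarioFiles",
    "generate_reference",
    "generate_ld_panel",
    "generate_regulatory_scenario",
    "generate_eqtl_expression",
    "generate_case_control_expression",
    "generate_ase_counts",
    "solve_consensus_probability",
]

_BLOCK = 400  # bp reserved per planted entity; keeps windows/peaks disjoint


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario. ``seed`` is mandatory."""

    seed: int
    # reference
    reference_length: int = 60_000
    gc_content: float = 0.5
    chrom_name: str = "chrSim"
    # motifs and peaks
    n_tfs: int = 2
    motif_width: int = 6
    motif_info_bits_per_column: float = 1.5
    n_peaks_per_tf: int = 4
    peak_halfwidth: int = 75
    # SNP panel and LD
    n_index_snps: int = 2
    partner_r2_high: float = 0.9
    partner_r2_low: float = 0.3
    n_low_ld_partners_per_index: int = 2
    n_samples_panel: int = 100
    panel_maf_range: Tuple[float, float] = (0.2, 0.5)
    # planted SNP classes
    n_disrupting_snps: int = 5
    n_inpeak_no_motif: int = 3
    n_motif_no_peak: int = 2
    n_background_snps: int = 4
    # eQTL
    n_eqtl_datasets: int = 5
    n_samples_per_dataset: int = 200
    n_consensus_snps: int = 3
    eqtl_beta: float = 1.0
    dosage_maf: float = 0.3
    noise_sd: float = 1.0
    n_null_genes: int = 10
    # differential expression
    n_samples_de: int = 100
    de_shift: float = 0.5
    de_noise_sd: float = 0.2
    # ASE
    ase_depth: int = 100
    ase_imbalance_delta: float = 0.4
    # scanning
    scan: ScanConfig = field(default_factory=ScanConfig)
    ld_r2_min: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must lie in (0,1), got {self.gc_content}")
        counts = (
            self.n_tfs, self.n_peaks_per_tf, self.n_index_snps,
            self.n_disrupting_snps, self.n_inpeak_no_motif, self.n_motif_no_peak,
            self.n_background_snps, self.n_low_ld_partners_per_index,
        )
        if any(c < 0 for c in counts):
            raise ValueError("scenario counts must be >= 0")
        for r2 in (self.partner_r2_high, self.partner_r2_low):
            if not 0.0 < r2 <= 1.0:
                raise ValueError(f"target r2 must lie in (0,1], got {r2}")
        n_peaks = self.n_tfs * self.n_peaks_per_tf
        if self.n_disrupting_snps + self.n_inpeak_no_motif > n_peaks:
            raise ValueError(
                f"{self.n_disrupting_snps} disrupting + {self.n_inpeak_no_motif} "
                f"in-peak decoy SNPs exceed the {n_peaks} available peaks"
            )
        if self.n_consensus_snps > self.n_disrupting_snps:
            raise ValueError("n_consensus_snps exceeds n_disrupting_snps")
        if self._n_blocks() * _BLOCK > self.reference_length:
            raise ValueError(
                f"cfg demands {self._n_blocks()} placement blocks of {_BLOCK} bp "
                f"but the reference has only {self.reference_length} bp"
            )

    def _n_blocks(self) -> int:
        return (
            self.n_tfs * self.n_peaks_per_tf
            + self.n_motif_no_peak
            + self.n_background_snps
            + self.n_index_snps * (1 + self.n_low_ld_partners_per_index)
        )

    def tf_names(self) -> List[str]:
        return [f"TF{i + 1}" for i in range(self.n_tfs)]


@dataclass
class ScenarioTruth:
    """Ground truth for every planted entity, as plain tables."""

    snps: pd.DataFrame     # snp_id, klass, tf, motif_id, chrom, pos, ref, alt, index_id, target_r2, realized_r2
    eqtl: pd.DataFrame     # snp_id, gene_id, dataset_id, beta (non-zero effects only)
    de: pd.DataFrame       # gene_id, shift
    ase: pd.DataFrame      # snp_id, is_ase

    @property
    def disrupting(self) -> pd.DataFrame:
        return self.snps[self.snps.klass == "disrupting"]

    def snps_of_class(self, klass: str) -> List[str]:
        return list(self.snps.loc[self.snps.klass == klass, "snp_id"])

    def tf_disruption_counts(self) -> Dict[str, int]:
        return self.disrupting.groupby("tf").size().to_dict()


@dataclass
class ScenarioFiles:
    """Paths of everything one scenario writes."""

    outdir: Path
    reference: Path
    vcf: Path
    motifs: Path
    peaks: Dict[str, Path]
    index_snps: Path
    expression: Dict[str, Path]
    dosages: Dict[str, Path]
    de_expression: Path
    de_labels: Path
    ase_counts: Path
    truth_snps: Path
    truth_eqtl: Path
    truth_de: Path
    truth_ase: Path
    config: Path


def solve_consensus_probability(info_bits: float) -> float:
    """Consensus-base probability q giving a column q/(1−q)/3-split the
    requested relative entropy (bits) against a uniform background."""
    if not 0.0 < info_bits < 2.0:
        raise ValueError("per-column information must lie in (0, 2) bits")

    def ic(q: float) -> float:
        rest = (1.0 - q) / 3.0
        h = -(q * math.log2(q) + 3 * rest * math.log2(rest)) if 0 < q < 1 else 0.0
        return 2.0 - h

    lo, hi = 0.2500001, 1.0 - 1e-9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ic(mid) < info_bits:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_reference(length: int, gc: float, seed) -> SequenceRecord:
    """i.i.d. reference sequence with the requested GC content.

    ``seed`` may be an integer or a numpy Generator.
    """
    if length < 100:
        raise ValueError(f"reference length must be >= 100, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in (0,1), got {gc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(list(DNA_BASES), size=length, p=probs)
    return SequenceRecord(name="chrSim", sequence="".join(bases))


# ---------------------------------------------------------------- LD panel

def _partner_haplotype(rng: np.random.Generator, index_hap: np.ndarray,
                       maf: float, target_r2: float) -> np.ndarray:
    """Copy the index haplotype, resampling each entry with prob 1 − sqrt(r²)."""
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError(f"target r2 must lie in (0,1], got {target_r2}")
    m = 1.0 - math.sqrt(target_r2)
    resample = rng.random(len(index_hap)) < m
    fresh = (rng.random(len(index_hap)) < maf).astype(np.int8)
    out = index_hap.copy()
    out[resample] = fresh[resample]
    return out


def _polymorphic_hap(rng: np.random.Generator, n_hap: int, maf: float) -> np.ndarray:
    for _ in range(100):
        hap = (rng.random(n_hap) < maf).astype(np.int8)
        if 0 < hap.sum() < n_hap:
            return hap
    raise RuntimeError("failed to draw a polymorphic haplotype")


def generate_ld_panel(
    cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[HaplotypePanel, pd.DataFrame]:
    """Standalone LD block: one index SNP plus partners at the configured
    high/low r² targets. Returns the panel and a truth table with target and
    realized r² per partner."""
    if cfg.n_samples_panel < 50:
        raise ValueError("n_samples_panel must be >= 50")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_hap = 2 * cfg.n_samples_panel
    maf = float(rng.uniform(*cfg.panel_maf_range))
    index_hap = _polymorphic_hap(rng, n_hap, maf)
    variants = [Variant(chrom=cfg.chrom_name, pos=1000, id="idx1", ref="A", alt="G")]
    columns = [index_hap]
    records = []
    targets = [cfg.partner_r2_high, cfg.partner_r2_low]
    for i, tgt in enumerate(targets):
        hap = _partner_haplotype(rng, index_hap, maf, tgt)
        while hap.sum() in (0, n_hap):
            hap = _partner_haplotype(rng, index_hap, maf, tgt)
        vid = f"prt{i + 1}"
        variants.append(
            Variant(chrom=cfg.chrom_name, pos=2000 + 1000 * i, id=vid, ref="A", alt="G")
        )
        columns.append(hap)
        records.append(
            {
                "snp_id": vid,
                "index_id": "idx1",
                "target_r2": tgt,
                "realized_r2": r_squared(index_hap, hap).r2,
            }
        )
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=np.column_stack(columns),
        sample_ids=[f"S{i + 1:04d}" for i in range(cfg.n_samples_panel)],
    )
    return panel, pd.DataFrame(records)


# ---------------------------------------------------------------- expression

def generate_eqtl_expression(
    cfg: ScenarioConfig,
    eqtl_truth: pd.DataFrame,
    gene_ids: Sequence[str],
    snp_ids: Sequence[str],
    rng: np.random.Generator,
) -> List[ExpressionDataset]:
    """Per-dataset expression with planted dosage effects.

    ``eqtl_truth`` rows (snp_id, gene_id, dataset_id, beta) list the
    non-zero effects; every other (gene, dataset) cell is pure noise.
    Dosages are drawn fresh per dataset at ``cfg.dosage_maf`` (each dataset
    emulates an independent cohort).
    """
    datasets = []
    gene_snp = dict(zip(eqtl_truth.gene_id, eqtl_truth.snp_id))
    for d in range(cfg.n_eqtl_datasets):
        ds_id = f"DS{d + 1}"
        n = cfg.n_samples_per_dataset
        dosages = rng.binomial(2, cfg.dosage_maf, size=(len(snp_ids), n)).astype(float)
        dos_index = {s: i for i, s in enumerate(snp_ids)}
        active = eqtl_truth[eqtl_truth.dataset_id == ds_id]
        beta_of_gene = dict(zip(active.gene_id, active.beta))
        expr = rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), n))
        for gi, gene in enumerate(gene_ids):
            beta = beta_of_gene.get(gene, 0.0)
            if beta != 0.0 and gene in gene_snp:
                expr[gi] += beta * dosages[dos_index[gene_snp[gene]]]
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                gene_ids=list(gene_ids),
                sample_ids=[f"{ds_id}_S{i + 1:03d}" for i in range(n)],
                expression=expr,
                snp_ids=list(snp_ids),
                dosages=dosages,
            )
        )
    return datasets


def generate_case_control_expression(
    cfg: ScenarioConfig,
    gene_ids: Sequence[str],
    shifts: Dict[str, float],
    rng: np.random.Generator,
) -> ExpressionDataset:
    """Case/control matrix: cases of true-DE genes are shifted by ``shifts``."""
    n = cfg.n_samples_de
    n_case = n // 2
    labels = ["case"] * n_case + ["control"] * (n - n_case)
    expr = rng.normal(0.0, cfg.de_noise_sd, size=(len(gene_ids), n))
    for gi, gene in enumerate(gene_ids):
        expr[gi, :n_case] += shifts.get(gene, 0.0)
    return ExpressionDataset(
        dataset_id="DE",
        gene_ids=list(gene_ids),
        sample_ids=[f"DE_S{i + 1:03d}" for i in range(n)],
        expression=expr,
        group_labels=labels,
    )


def generate_ase_counts(
    cfg: ScenarioConfig,
    snp_ids: Sequence[str],
    ase_flags: Sequence[bool],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Allelic read counts: Binomial(depth, 0.5 + delta) for ASE-true SNPs,
    Binomial(depth, 0.5) otherwise."""
    if cfg.ase_depth < 10:
        raise ValueError(f"ase_depth must be >= 10, got {cfg.ase_depth}")
    p1 = 0.5 + cfg.ase_imbalance_delta
    if not 0.0 < p1 < 1.0:
        raise ValueError(f"0.5 + ase_imbalance_delta = {p1} outside (0,1)")
    rows = []
    for snp, is_ase in zip(snp_ids, ase_flags):
        p = p1 if is_ase else 0.5
        c1 = int(rng.binomial(cfg.ase_depth, p))
        rows.append(
            {
                "snp_id": snp,
                "tissue": "brain",
                "count_allele1": c1,
                "count_allele2": cfg.ase_depth - c1,
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "tissue", "count_allele1", "count_allele2"])


# ---------------------------------------------------------------- full scenario

def _build_motifs(cfg: ScenarioConfig, rng: np.random.Generator) -> List[PWM]:
    q = solve_consensus_probability(cfg.motif_info_bits_per_column)
    pwms = []
    for tf in cfg.tf_names():
        consensus = rng.integers(0, 4, size=cfg.motif_width)
        probs = np.full((cfg.motif_width, 4), (1.0 - q) / 3.0)
        probs[np.arange(cfg.motif_width), consensus] = q
        pwms.append(PWM(motif_id=f"{tf}_motif", tf_name=tf, probs=probs))
    return pwms


def _resample_window(
    seq: list, rng: np.random.Generator, lo: int, hi: int, protected: set, gc: float
) -> None:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for i in range(lo, hi):
        if i not in protected:
            seq[i] = DNA_BASES[rng.choice(4, p=probs)]


def generate_regulatory_scenario(
    cfg: ScenarioConfig, outdir
) -> Tuple[ScenarioFiles, ScenarioTruth]:
    """Generate and write one complete synthetic study.

    All files parse back through :mod:`regvar.io_formats`; every SNP in the
    VCF appears in the truth table exactly once; identical configurations
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    scan_cfg = cfg.scan

    # --- reference and motifs
    ref = generate_reference(cfg.reference_length, cfg.gc_content, rng)
    seq = list(ref.sequence)
    pwms = _build_motifs(cfg, rng)
    scanner_probe = MotifScanner(pwms, scan_cfg)

    # --- block layout: one planted entity per block
    n_blocks = cfg._n_blocks()
    block_starts = [i * (cfg.reference_length // n_blocks) for i in range(n_blocks)]
    centers = [s + (cfg.reference_length // n_blocks) // 2 for s in block_starts]
    block_iter = iter(centers)

    tfs = cfg.tf_names()
    peaks: Dict[str, List[Peak]] = {tf: [] for tf in tfs}
    motif_sites: List[Tuple[str, int]] = []  # (tf, motif start) inside peaks
    protected: set = set()

    for p in range(cfg.n_peaks_per_tf):
        for tf, pwm in zip(tfs, pwms):
            center = next(block_iter)
            mstart = center - cfg.motif_width // 2
            consensus = pwm.consensus()
            for i, base in enumerate(consensus):
                seq[mstart + i] = base
                protected.add(mstart + i)
            peaks[tf].append(
                Peak(
                    chrom=cfg.chrom_name,
                    start=center - cfg.peak_halfwidth,
                    end=center + cfg.peak_halfwidth,
                    tf_name=tf,
                )
            )
            motif_sites.append((tf, mstart))

    free_motif_sites: List[Tuple[str, int]] = []  # planted motifs outside peaks
    for k in range(cfg.n_motif_no_peak):
        tf, pwm = tfs[k % len(tfs)], pwms[k % len(tfs)]
        center = next(block_iter)
        mstart = center - cfg.motif_width // 2
        for i, base in enumerate(pwm.consensus()):
            seq[mstart + i] = base
            protected.add(mstart + i)
        free_motif_sites.append((tf, mstart))

    plain_centers = [next(block_iter) for _ in range(
        cfg.n_background_snps + cfg.n_index_snps * (1 + cfg.n_low_ld_partners_per_index)
    )]

    # --- SNP placement; classes are verified (and windows resampled) below
    pwm_of_tf = {p.tf_name: p for p in pwms}
    snp_rows: List[dict] = []

    def snp_column(pwm: PWM) -> Tuple[int, str]:
        info = pwm.information_content(scan_cfg.background)
        col = int(np.argmax(info))
        worst = int(np.argmin(pwm.probs[col]))
        return col, DNA_BASES[worst]

    sid = 0

    def next_id(prefix: str) -> str:
        nonlocal sid
        sid += 1
        return f"{prefix}{sid:03d}"

    for k in range(cfg.n_disrupting_snps):
        tf, mstart = motif_sites[k]
        pwm = pwm_of_tf[tf]
        col, alt = snp_column(pwm)
        pos0 = mstart + col
        snp_rows.append(
            {
                "snp_id": next_id("rsD"), "klass": "disrupting", "tf": tf,
                "motif_id": pwm.motif_id, "pos0": pos0,
                "ref": seq[pos0], "alt": alt,
            }
        )

    inpeak_sites = motif_sites[cfg.n_disrupting_snps :]
    for k in range(cfg.n_inpeak_no_motif):
        tf, mstart = inpeak_sites[k]
        # far enough from the motif that a ±flank window cannot touch it
        pos0 = mstart + cfg.motif_width + scan_cfg.flank + 5
        alt = DNA_BASES[("ACGT".index(seq[pos0]) + 1) % 4]
        snp_rows.append(
            {
                "snp_id": next_id("rsP"), "klass": "in_peak_no_motif", "tf": tf,
                "motif_id": "", "pos0": pos0, "ref": seq[pos0], "alt": alt,
            }
        )

    for tf, mstart in free_motif_sites:
        pwm = pwm_of_tf[tf]
        col, alt = snp_column(pwm)
        pos0 = mstart + col
        snp_rows.append(
            {
                "snp_id": next_id("rsM"), "klass": "motif_no_peak", "tf": tf,
                "motif_id": pwm.motif_id, "pos0": pos0, "ref": seq[pos0], "alt": alt,
            }
        )

    plain_iter = iter(plain_centers)
    for _ in range(cfg.n_background_snps):
        pos0 = next(plain_iter)
        alt = DNA_BASES[("ACGT".index(seq[pos0]) + 1) % 4]
        snp_rows.append(
            {
                "snp_id": next_id("rsB"), "klass": "background", "tf": "",
                "motif_id": "", "pos0": pos0, "ref": seq[pos0], "alt": alt,
            }
        )

    index_rows, lowld_rows = [], []
    for i in range(cfg.n_index_snps):
        pos0 = next(plain_iter)
        alt = DNA_BASES[("ACGT".index(seq[pos0]) + 1) % 4]
        row = {
            "snp_id": f"rsIDX{i + 1}", "klass": "index", "tf": "",
            "motif_id": "", "pos0": pos0, "ref": seq[pos0], "alt": alt,
        }
        index_rows.append(row)
        for j in range(cfg.n_low_ld_partners_per_index):
            pos0 = next(plain_iter)
            alt = DNA_BASES[("ACGT".index(seq[pos0]) + 1) % 4]
            lowld_rows.append(
                {
                    "snp_id": next_id("rsL"), "klass": "background", "tf": "",
                    "motif_id": "", "pos0": pos0, "ref": seq[pos0], "alt": alt,
                    "low_ld": True,
                }
            )
    snp_rows.extend(lowld_rows)

    # --- verify class semantics; resample offending windows
    def covering_hits(window: str, snp_index: int) -> bool:
        return any(
            scanner_probe.scan_window(window, p.motif_id, snp_index) is not None
            for p in pwms
        )

    def window_of(pos0: int, allele: str) -> Tuple[str, int]:
        lo = max(0, pos0 - scan_cfg.flank)
        hi = min(len(seq), pos0 + scan_cfg.flank + 1)
        window = "".join(seq[lo:hi])
        idx = pos0 - lo
        window = window[:idx] + allele + window[idx + 1 :]
        return window, idx

    for row in snp_rows + index_rows:
        pos0 = row["pos0"]
        lo = max(0, pos0 - scan_cfg.flank)
        hi = min(len(seq), pos0 + scan_cfg.flank + 1)
        for _ in range(100):
            ref_win, idx = window_of(pos0, row["ref"])
            alt_win, _ = window_of(pos0, row["alt"])
            if row["klass"] in ("disrupting", "motif_no_peak"):
                pwm = pwm_of_tf[row["tf"]]
                ref_hit = scanner_probe.scan_window(ref_win, pwm.motif_id, idx)
                ok = ref_hit is not None and not covering_hits(alt_win, idx)
            else:
                ok = not covering_hits(ref_win, idx) and not covering_hits(alt_win, idx)
            if ok:
                break
            _resample_window(seq, rng, lo, hi, protected | {pos0}, cfg.gc_content)
        else:
            raise RuntimeError(f"could not realize class {row['klass']} at {pos0}")

    ref = SequenceRecord(name=cfg.chrom_name, sequence="".join(seq))

    # --- haplotype panel with LD structure
    n_hap = 2 * cfg.n_samples_panel
    index_haps: List[np.ndarray] = []
    for row in index_rows:
        maf = float(rng.uniform(*cfg.panel_maf_range))
        index_haps.append(_polymorphic_hap(rng, n_hap, maf))
        row["maf"] = maf
        row["index_id"] = row["snp_id"]
        row["target_r2"] = 1.0
        row["realized_r2"] = 1.0

    for k, row in enumerate(snp_rows):
        idx = k % cfg.n_index_snps if cfg.n_index_snps else 0
        target = cfg.partner_r2_low if row.get("low_ld") else cfg.partner_r2_high
        index_hap = index_haps[idx]
        maf = index_rows[idx]["maf"]
        hap = _partner_haplotype(rng, index_hap, maf, target)
        while hap.sum() in (0, n_hap):
            hap = _partner_haplotype(rng, index_hap, maf, target)
        row["hap"] = hap
        row["index_id"] = index_rows[idx]["snp_id"]
        row["target_r2"] = target
        row["realized_r2"] = r_squared(index_hap, hap).r2
    for row, hap in zip(index_rows, index_haps):
        row["hap"] = hap

    all_rows = snp_rows + index_rows
    all_rows.sort(key=lambda r: r["pos0"])
    variants = [
        Variant(
            chrom=cfg.chrom_name, pos=r["pos0"] + 1, id=r["snp_id"],
            ref=r["ref"], alt=r["alt"],
        )
        for r in all_rows
    ]
    haplotypes = np.column_stack([r["hap"] for r in all_rows])
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples_panel)]

    truth_snps = pd.DataFrame(
        [
            {
                "snp_id": r["snp_id"], "klass": r["klass"], "tf": r["tf"],
                "motif_id": r["motif_id"], "chrom": cfg.chrom_name,
                "pos": r["pos0"] + 1, "ref": r["ref"], "alt": r["alt"],
                "index_id": r["index_id"],
                "target_r2": round(float(r["target_r2"]), 6),
                "realized_r2": round(float(r["realized_r2"]), 6),
            }
            for r in all_rows
        ]
    )

    # --- eQTL plan: consensus SNPs active in all datasets, the rest in one
    disrupting_ids = [r["snp_id"] for r in snp_rows if r["klass"] == "disrupting"]
    target_genes = [f"GENE{i + 1:02d}" for i in range(len(disrupting_ids))]
    eqtl_records = []
    ds_ids = [f"DS{d + 1}" for d in range(cfg.n_eqtl_datasets)]
    for i, (snp, gene) in enumerate(zip(disrupting_ids, target_genes)):
        if i < cfg.n_consensus_snps:
            active = ds_ids
        else:
            active = [ds_ids[i % cfg.n_eqtl_datasets]]
        for ds in active:
            eqtl_records.append(
                {"snp_id": snp, "gene_id": gene, "dataset_id": ds, "beta": cfg.eqtl_beta}
            )
    truth_eqtl = pd.DataFrame(
        eqtl_records, columns=["snp_id", "gene_id", "dataset_id", "beta"]
    )

    null_genes = [f"NULL{i + 1:02d}" for i in range(cfg.n_null_genes)]
    all_genes = target_genes + null_genes
    eqtl_datasets = generate_eqtl_expression(
        cfg, truth_eqtl, all_genes, disrupting_ids, rng
    )

    # --- DE: consensus-SNP target genes are shifted in cases
    de_genes = target_genes[: cfg.n_consensus_snps]
    shifts = {g: cfg.de_shift for g in de_genes}
    de_ds = generate_case_control_expression(cfg, all_genes, shifts, rng)
    truth_de = pd.DataFrame(
        [{"gene_id": g, "shift": shifts.get(g, 0.0)} for g in all_genes]
    )

    # --- ASE: consensus SNPs show imbalance
    ase_flags = [i < cfg.n_consensus_snps for i in range(len(disrupting_ids))]
    ase_counts = generate_ase_counts(cfg, disrupting_ids, ase_flags, rng)
    truth_ase = pd.DataFrame({"snp_id": disrupting_ids, "is_ase": ase_flags})

    truth = ScenarioTruth(snps=truth_snps, eqtl=truth_eqtl, de=truth_de, ase=truth_ase)

    # --- write everything
    files = ScenarioFiles(
        outdir=outdir,
        reference=outdir / "reference.fa",
        vcf=outdir / "panel.vcf",
        motifs=outdir / "motifs.meme",
        peaks={tf: outdir / f"peaks_{tf}.bed" for tf in tfs},
        index_snps=outdir / "index_snps.txt",
        expression={d.dataset_id: outdir / f"expression_{d.dataset_id}.tsv" for d in eqtl_datasets},
        dosages={d.dataset_id: outdir / f"dosage_{d.dataset_id}.tsv" for d in eqtl_datasets},
        de_expression=outdir / "de_expression.tsv",
        de_labels=outdir / "de_labels.tsv",
        ase_counts=outdir / "ase_counts.tsv",
        truth_snps=outdir / "truth_snps.tsv",
        truth_eqtl=outdir / "truth_eqtl.tsv",
        truth_de=outdir / "truth_de.tsv",
        truth_ase=outdir / "truth_ase.tsv",
        config=outdir / "scenario_config.yaml",
    )
    io_formats.write_fasta([ref], files.reference)
    io_formats.write_vcf(
        variants, haplotypes, sample_ids, files.vcf,
        contig_lengths={cfg.chrom_name: cfg.reference_length},
    )
    io_formats.write_meme_motifs(pwms, files.motifs, background=scan_cfg.background)
    for tf in tfs:
        io_formats.write_bed(peaks[tf], files.peaks[tf])
    files.index_snps.write_text("".join(r["snp_id"] + "\n" for r in index_rows))
    for d in eqtl_datasets:
        expr = pd.DataFrame(d.expression, index=d.gene_ids, columns=d.sample_ids)
        expr.rename_axis("gene_id").reset_index().pipe(
            io_formats.write_table, files.expression[d.dataset_id]
        )
        dos = pd.DataFrame(d.dosages, index=d.snp_ids, columns=d.sample_ids)
        dos.rename_axis("snp_id").reset_index().pipe(
            io_formats.write_table, files.dosages[d.dataset_id]
        )
    de_expr = pd.DataFrame(de_ds.expression, index=de_ds.gene_ids, columns=de_ds.sample_ids)
    de_expr.rename_axis("gene_id").reset_index().pipe(
        io_formats.write_table, files.de_expression
    )
    io_formats.write_table(
        pd.DataFrame({"sample_id": de_ds.sample_ids, "group": de_ds.group_labels}),
        files.de_labels,
    )
    io_formats.write_table(ase_counts, files.ase_counts)
    io_formats.write_table(truth_snps, files.truth_snps)
    io_formats.write_table(truth_eqtl, files.truth_eqtl)
    io_formats.write_table(truth_de, files.truth_de)
    io_formats.write_table(truth_ase, files.truth_ase)
    files.config.write_text(yaml.safe_dump(_cfg_to_dict(cfg), sort_keys=True))
    return files, truth


def _cfg_to_dict(cfg: ScenarioConfig) -> dict:
    def plain(obj):
        if isinstance(obj, tuple):
            return [plain(x) for x in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    return plain(asdict(cfg))
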