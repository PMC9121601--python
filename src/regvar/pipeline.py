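"""End-to-end orchestration: LD extraction → allele-specific motif scan →
disruption classification → eQTL consensus → ASE enrichment → report.

Each stage reads and writes plain TSV files, so any stage can be rerun in
isolation; all randomness is confined to the synthetic-data generator, so a
pipeline run is a deterministic function of its input files and
configuration, and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__, io_formats
from .ase import ase_enrichment_test, evaluate_ase_table
from .assoc_stats import (
    EqtlAssociation,
    ExpressionDataset,
    SignificanceRule,
    consensus_tally,
    eqtl_scan,
)
from .core import Variant
from .disruption import PeakIndex, calls_to_frame, classify_disruption, summarize_disruptions
from .ld import ld_partners
from .motif import MotifScanner, ScanConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "render_report"]

# defaults from the GTEx v8 ASE catalogue: ASE variants / all catalogued variants
DEFAULT_ASE_BACKGROUND = (571_220, 46_526_292)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    reference: Path
    vcf: Path
    motifs: Path
    peaks: Dict[str, Path]           # tf_name -> BED path ('' = take TF from column 4)
    index_snps: Path
    outdir: Path
    # optional association inputs: either precomputed tables or matrices
    eqtl_tables: Optional[Path] = None        # TSV: dataset_id snp_id gene_id beta p [fdr]
    expression: Dict[str, Path] = field(default_factory=dict)   # dataset -> genes×samples TSV
    dosages: Dict[str, Path] = field(default_factory=dict)      # dataset -> snps×samples TSV
    eqtl_pairs: Optional[Sequence[Tuple[str, str]]] = None
    ase_counts: Optional[Path] = None         # TSV: snp_id tissue count_allele1 count_allele2
    # thresholds
    scan: ScanConfig = field(default_factory=ScanConfig)
    r2_min: float = 0.6
    eqtl_rule: SignificanceRule = field(default_factory=lambda: SignificanceRule("p", 0.01))
    ase_alpha: float = 0.05
    ase_background: Tuple[int, int] = DEFAULT_ASE_BACKGROUND
    assume_phased: bool = False

    def validate(self) -> None:
        for label, path in [
            ("reference", self.reference), ("vcf", self.vcf),
            ("motifs", self.motifs), ("index_snps", self.index_snps),
            *[(f"peaks[{tf}]", p) for tf, p in self.peaks.items()],
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")


@dataclass
class PipelineResult:
    outdir: Path
    candidates: List[Variant]
    calls_frame: pd.DataFrame
    summary: "object"
    consensus: Optional[object]
    ase_line: Optional[dict]
    report_path: Path
    manifest_path: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("ld")
def _run_ld(cfg: PipelineConfig, outdir: Path) -> List[Variant]:
    _, panel = io_formats.parse_vcf(cfg.vcf, assume_phased=cfg.assume_phased)
    index_ids = [
        line.strip() for line in Path(cfg.index_snps).read_text().splitlines() if line.strip()
    ]
    candidates = ld_partners(panel, index_ids, r2_min=cfg.r2_min)
    frame = pd.DataFrame(
        [
            {
                "index_id": v.index_id, "snp_id": v.id, "chrom": v.chrom,
                "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "r2": round(v.r2_to_index, 6),
            }
            for v in candidates
        ],
        columns=["index_id", "snp_id", "chrom", "pos", "ref", "alt", "r2"],
    )
    io_formats.write_table(frame, outdir / "ld_partners.tsv")
    logger.info("ld: %d candidate SNPs from %d index SNPs", len(candidates), len(index_ids))
    return candidates


@_stage("scan")
def _run_scan(cfg: PipelineConfig, outdir: Path, candidates: List[Variant]):
    reference = io_formats.parse_fasta(cfg.reference)
    pwms = io_formats.parse_meme_motifs(cfg.motifs)
    scanner = MotifScanner(pwms, cfg.scan)
    pairs = {}
    hit_rows = []
    for variant in candidates:
        pair = scanner.scan_alleles(variant, reference)
        pairs[variant.id] = pair
        for res in pair:
            for motif_id, hit in res.best_hit.items():
                if hit is None:
                    continue
                hit_rows.append(
                    {
                        "snp_id": variant.id, "allele": res.allele,
                        "motif_id": motif_id, "tf": scanner.tf_of_motif[motif_id],
                        "strand": hit.strand,
                        "window_start_genomic": variant.pos - res.snp_index + hit.start,
                        "score_bits": round(hit.score_bits, 4),
                        "pvalue": hit.pvalue, "covers_snp": hit.covers_snp,
                    }
                )
    frame = pd.DataFrame(
        hit_rows,
        columns=[
            "snp_id", "allele", "motif_id", "tf", "strand",
            "window_start_genomic", "score_bits", "pvalue", "covers_snp",
        ],
    )
    io_formats.write_table(frame, outdir / "motif_hits.tsv")
    logger.info("scan: %d allele-level motif hits", len(frame))
    return scanner, pairs


@_stage("classify")
def _run_classify(cfg: PipelineConfig, outdir: Path, scanner, pairs, candidates):
    peaks = []
    for tf, path in cfg.peaks.items():
        peaks.extend(io_formats.parse_bed(path, tf_name=tf))
    index = PeakIndex(peaks)
    calls = []
    for variant in candidates:
        calls.extend(
            classify_disruption(pairs[variant.id], variant, index, scanner.tf_of_motif)
        )
    frame = calls_to_frame(calls)
    io_formats.write_table(frame, outdir / "disruption_calls.tsv")
    summary = summarize_disruptions(calls)
    io_formats.write_table(
        pd.DataFrame(
            [{"tf": tf, "n_disrupting_snps": n} for tf, n in summary.snps_per_tf.items()],
            columns=["tf", "n_disrupting_snps"],
        ),
        outdir / "disruption_summary.tsv",
    )
    logger.info(
        "classify: %d calls, %d disrupting SNPs", len(frame), len(summary.tfs_per_snp)
    )
    return calls, frame, summary


@_stage("eqtl")
def _run_eqtl(cfg: PipelineConfig, outdir: Path, snp_ids: Sequence[str]):
    associations: List[EqtlAssociation] = []
    if cfg.eqtl_tables is not None:
        table = io_formats.read_table(cfg.eqtl_tables)
        for r in table.itertuples():
            associations.append(
                EqtlAssociation(
                    dataset_id=str(r.dataset_id), snp_id=str(r.snp_id),
                    gene_id=str(r.gene_id), beta=float(getattr(r, "beta", 0.0)),
                    se=float(getattr(r, "se", float("nan"))),
                    t_stat=float(getattr(r, "t_stat", float("nan"))),
                    p_value=float(r.p),
                    fdr=float(r.fdr) if hasattr(r, "fdr") else None,
                )
            )
    else:
        for ds_id in sorted(cfg.expression):
            expr = io_formats.read_table(cfg.expression[ds_id]).set_index("gene_id")
            dos = io_formats.read_table(cfg.dosages[ds_id]).set_index("snp_id")
            ds = ExpressionDataset(
                dataset_id=ds_id,
                gene_ids=list(expr.index),
                sample_ids=list(expr.columns),
                expression=expr.to_numpy(),
                snp_ids=list(dos.index),
                dosages=dos.to_numpy(),
            )
            pairs = cfg.eqtl_pairs or [
                (s, g) for s in ds.snp_ids for g in ds.gene_ids
            ]
            pairs = [(s, g) for s, g in pairs if s in ds.snp_ids and g in ds.gene_ids]
            associations.extend(eqtl_scan(ds, pairs))
    tested = sorted({a.snp_id for a in associations} & set(snp_ids))
    summary = consensus_tally(associations, cfg.eqtl_rule, tested or list(snp_ids))
    io_formats.write_table(
        pd.DataFrame(
            [
                {
                    "dataset_id": a.dataset_id, "snp_id": a.snp_id, "gene_id": a.gene_id,
                    "beta": a.beta, "p": a.p_value, "fdr": a.fdr,
                    "significant": a.significant,
                }
                for a in associations
            ],
            columns=["dataset_id", "snp_id", "gene_id", "beta", "p", "fdr", "significant"],
        ),
        outdir / "eqtl_associations.tsv",
    )
    io_formats.write_table(
        pd.DataFrame(
            [{"k": k, "n_snps": n} for k, n in summary.tallies.items()],
            columns=["k", "n_snps"],
        ),
        outdir / "eqtl_consensus.tsv",
    )
    logger.info("eqtl: %d associations across %d datasets", len(associations), summary.n_datasets)
    return summary


@_stage("ase")
def _run_ase(cfg: PipelineConfig, outdir: Path, functional_ids: Sequence[str]):
    counts = io_formats.read_table(cfg.ase_counts)
    observations = evaluate_ase_table(counts, alpha=cfg.ase_alpha)
    io_formats.write_table(
        pd.DataFrame(
            [
                {
                    "snp_id": o.snp_id, "tissue": o.tissue,
                    "count_allele1": o.count_allele1, "count_allele2": o.count_allele2,
                    "p": o.p_value, "significant": o.significant,
                }
                for o in observations
            ],
            columns=["snp_id", "tissue", "count_allele1", "count_allele2", "p", "significant"],
        ),
        outdir / "ase_tests.tsv",
    )
    tested = [o for o in observations if not functional_ids or o.snp_id in set(functional_ids)]
    n = len({o.snp_id for o in tested})
    k = len({o.snp_id for o in tested if o.significant})
    K, N = cfg.ase_background
    enrichment = ase_enrichment_test(k, n, K, N) if n else None
    if enrichment:
        io_formats.write_table(
            pd.DataFrame(
                [{"k": k, "n": n, "K": K, "N": N, "p": enrichment.p_value}],
            ),
            outdir / "ase_enrichment.tsv",
        )
        logger.info("ase: %d/%d functional SNPs with ASE, enrichment p=%.3g", k, n, enrichment.p_value)
    return {
        "k": k, "n": n, "K": K, "N": N,
        "p": enrichment.p_value if enrichment else None,
    } if n else None


def render_report(
    summary,
    consensus=None,
    ase_line: Optional[dict] = None,
    skipped: Sequence[str] = (),
) -> str:
    """Plain-markdown run summary mirroring the study's reporting surfaces."""
    lines = ["# regvar pipeline report", ""]
    n_func = len(summary.tfs_per_snp)
    lines.append("## TF-binding-disrupting SNPs")
    if n_func == 0:
        lines.append("Zero functional (TF-binding-disrupting) SNPs identified.")
    else:
        lines.append(f"{n_func} functional SNP(s) identified.")
        lines.append("")
        lines.append("| TF | disrupting SNPs |")
        lines.append("|----|-----------------|")
        for tf, n in summary.snps_per_tf.items():
            lines.append(f"| {tf} | {n} |")
        lines.append("")
        lines.append(f"SNPs disrupting two or more TFs: {summary.n_multi_tf_snps}")
        for snp, tfs in summary.tfs_per_snp.items():
            lines.append(f"- {snp}: {', '.join(tfs)}")
    lines.append("")
    lines.append("## eQTL consensus")
    if consensus is None:
        lines.append("skipped (no eQTL inputs)")
    else:
        for k, n in consensus.tallies.items():
            lines.append(f"- SNPs significant in >= {k} dataset(s): {n}")
    lines.append("")
    lines.append("## ASE enrichment")
    if ase_line is None:
        lines.append("skipped (no ASE inputs)")
    else:
        lines.append(
            "- k={k} of n={n} functional SNPs show ASE; background {K}/{N}; "
            "binomial p = {p:.3g}".format(**ase_line)
        )
    for stage in skipped:
        lines.append("")
        lines.append(f"_stage {stage}: skipped_")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages; raises :class:`StageError` naming a failed stage."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    candidates = _run_ld(cfg, outdir)
    scanner, pairs = _run_scan(cfg, outdir, candidates)
    calls, calls_frame, summary = _run_classify(cfg, outdir, scanner, pairs, candidates)
    functional_ids = summary.disrupting_snps

    skipped = []
    consensus = None
    if cfg.eqtl_tables is not None or cfg.expression:
        consensus = _run_eqtl(cfg, outdir, functional_ids)
    else:
        skipped.append("eqtl")
    ase_line = None
    if cfg.ase_counts is not None:
        ase_line = _run_ase(cfg, outdir, functional_ids)
    else:
        skipped.append("ase")

    report = render_report(summary, consensus, ase_line, skipped)
    report_path = outdir / "report.md"
    report_path.write_text(report)

    manifest = {
        "regvar_version": __version__,
        "config_hash": hashlib.sha256(
            repr({k: v for k, v in sorted(vars(cfg).items()) if k != "outdir"}).encode()
        ).hexdigest()[:16],
        "n_candidates": len(candidates),
        "n_calls": int(len(calls_frame)),
        "n_functional_snps": len(functional_ids),
        "functional_snps": functional_ids,
        "skipped_stages": skipped,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        outdir=outdir, candidates=candidates, calls_frame=calls_frame,
        summary=summary, consensus=consensus, ase_line=ase_line,
        report_path=report_path, manifest_path=manifest_path,
    )
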