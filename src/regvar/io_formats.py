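"""Readers and writers for the file formats the pipeline touches.

FASTA is read through Bio.SeqIO and VCF through cyvcf2; BED and the TSV
result tables go through pandas. The MEME minimal motif format is parsed by
a strict local implementation so that malformed probability rows are
rejected rather than silently renormalized.

Coordinate conventions: VCF positions are 1-based, BED intervals 0-based
half-open; conversion happens only through :func:`regvar.core.pos_to_zero_based`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .core import DNA_BASES, FormatError, Peak, SequenceRecord, Variant
from .ld import HaplotypePanel
from .motif import PWM

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord", "Variant", "Peak", "FormatError",
    "parse_fasta", "write_fasta",
    "parse_vcf", "write_vcf",
    "parse_bed", "write_bed",
    "parse_meme_motifs", "write_meme_motifs",
    "read_table", "write_table",
]


# ---------------------------------------------------------------- FASTA

def parse_fasta(path) -> List[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects."""
    # Bio.SeqIO silently drops interior whitespace, so residues are
    # validated on the raw sequence lines first
    with open(path) as fh:
        pos = 0
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                pos = 0
                continue
            for ch in line:
                pos += 1
                if ch.upper() not in "ACGTN":
                    raise FormatError(
                        f"{path}: illegal residue {ch!r} at sequence position {pos}"
                    )
    records: List[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(name=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------- VCF

def parse_vcf(path, assume_phased: bool = False) -> Tuple[List[Variant], HaplotypePanel]:
    """Read biallelic SNPs and their phased haplotypes from a VCF.

    Multi-allelic and indel rows are skipped with a warning and counted
    (the count is logged). Unphased genotypes raise unless ``assume_phased``.

    Returns the variants plus a :class:`HaplotypePanel` whose haplotype
    matrix has shape (2 * n_samples, n_variants), sample order preserved.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample/GT columns")
    variants: List[Variant] = []
    columns: List[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if (not rec.is_snp) or len(rec.ALT) != 1 or len(rec.REF) != 1:
            skipped += 1
            continue
        genotypes = rec.genotypes  # [allele_a, allele_b, phased] per sample
        haps = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for s, gt in enumerate(genotypes):
            *alleles, phased = gt
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                raise FormatError(
                    f"{path}: sample {samples[s]} at {rec.CHROM}:{rec.POS} has a "
                    "missing or non-diploid genotype"
                )
            if not phased and not assume_phased:
                raise FormatError(
                    f"{path}: unphased genotype for sample {samples[s]} at "
                    f"{rec.CHROM}:{rec.POS}; pass assume_phased to accept"
                )
            haps[2 * s] = alleles[0]
            haps[2 * s + 1] = alleles[1]
        if not ok:
            continue
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variants.append(
            Variant(chrom=rec.CHROM, pos=rec.POS, id=vid, ref=rec.REF, alt=rec.ALT[0])
        )
        columns.append(haps)
    if skipped:
        logger.warning("%s: skipped %d non-biallelic-SNP rows", path, skipped)
    haplotypes = (
        np.column_stack(columns) if columns else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel(
        variants=variants, haplotypes=haplotypes, sample_ids=samples,
        skipped_records=skipped,
    )
    return variants, panel


def write_vcf(
    variants: Sequence[Variant],
    haplotypes: np.ndarray,
    sample_ids: Sequence[str],
    path,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write biallelic SNPs with phased GT fields (plain-text VCF 4.2)."""
    n_samples = len(sample_ids)
    if haplotypes.shape != (2 * n_samples, len(variants)):
        raise ValueError(
            f"haplotype matrix {haplotypes.shape} does not match "
            f"(2*{n_samples}, {len(variants)})"
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=regvar\n")
        chroms = dict.fromkeys(v.chrom for v in variants)
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
        for i in order:
            v = variants[i]
            gts = "\t".join(
                f"{haplotypes[2 * s, i]}|{haplotypes[2 * s + 1, i]}"
                for s in range(n_samples)
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------- BED

def parse_bed(path, tf_name: str = "") -> List[Peak]:
    """Read BED3+ peaks; column 4 names the TF when ``tf_name`` is empty."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval [{start},{end})"
                )
            name = tf_name or (fields[3] if len(fields) > 3 else "")
            peaks.append(Peak(chrom=fields[0], start=start, end=end, tf_name=name))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_name}\n")


# ---------------------------------------------------------------- MEME minimal

_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")
_MATRIX_RE = re.compile(r"^letter-probability matrix:(.*)$")


def parse_meme_motifs(path) -> List[PWM]:
    """Parse motifs from MEME minimal format into PWMs.

    Probability rows deviating from sum 1 by more than 0.01 are rejected;
    smaller deviations are renormalized. Width comes from ``w=`` when given,
    otherwise from the row count.
    """
    text = Path(path).read_text().splitlines()
    if not any(line.startswith("MEME version") for line in text):
        raise FormatError(f"{path}: missing 'MEME version' line")
    for line in text:
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
            if alphabet != "ACGT":
                raise FormatError(f"{path}: unsupported alphabet {alphabet!r}")
    pwms: List[PWM] = []
    i = 0
    while i < len(text):
        m = _MOTIF_RE.match(text[i])
        if not m:
            i += 1
            continue
        motif_id, alt_name = m.group(1), m.group(2) or ""
        width: Optional[int] = None
        rows: List[List[float]] = []
        i += 1
        while i < len(text) and not _MOTIF_RE.match(text[i]):
            header = _MATRIX_RE.match(text[i].strip())
            if header:
                wm = re.search(r"w=\s*(\d+)", header.group(1))
                if wm:
                    width = int(wm.group(1))
                am = re.search(r"alength=\s*(\d+)", header.group(1))
                if am and int(am.group(1)) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: alength != 4")
                i += 1
                while i < len(text):
                    stripped = text[i].strip()
                    parts = stripped.split()
                    if len(parts) == 4:
                        try:
                            row = [float(x) for x in parts]
                        except ValueError:
                            break
                        if abs(sum(row) - 1.0) > 0.01:
                            raise FormatError(
                                f"{path}: motif {motif_id}: probability row "
                                f"{len(rows) + 1} sums to {sum(row):.4g}, not 1"
                            )
                        rows.append(row)
                        i += 1
                    else:
                        break
                continue
            i += 1
        if not rows:
            raise FormatError(f"{path}: motif {motif_id}: no letter-probability matrix")
        if width is not None and width != len(rows):
            raise FormatError(
                f"{path}: motif {motif_id}: w={width} but {len(rows)} matrix rows"
            )
        probs = np.asarray(rows, dtype=float)
        probs = probs / probs.sum(axis=1, keepdims=True)
        pwms.append(PWM(motif_id=motif_id, tf_name=alt_name, probs=probs))
    if not pwms:
        raise FormatError(f"{path}: no MOTIF blocks")
    return pwms


def write_meme_motifs(pwms: Sequence[PWM], path, background=None) -> None:
    """Write motifs in MEME minimal format (probabilities to 6 decimals)."""
    bg = background.array if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(bg)
        )
        for pwm in pwms:
            name = f"{pwm.motif_id} {pwm.tf_name}".rstrip()
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" %.6f %.6f %.6f %.6f\n" % tuple(row))
            fh.write("\n")


# ---------------------------------------------------------------- TSV tables

def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
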