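"""Readers and writers for the standard formats the toolkit touches.

FASTA (reference genomes), VCF 4.x (SNV catalogues; plain or bgzipped),
BED3/BED6 (interval sets) and labelled TSV/CSV matrices (mutation count,
signature and contribution matrices).
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .core import Interval, IntervalSet, MutationCatalogue, ReferenceGenome, Snv, VALID_BASES

logger = logging.getLogger("mutpatterns")

_ALLOWED_FASTA = frozenset("ACGTN")


def read_reference(fasta_path) -> ReferenceGenome:
    """Read a FASTA reference genome into memory.

    Sequences are upper-cased (soft-masking is discarded); IUPAC ambiguity
    codes other than N are mapped to N with a logged notice. Record order
    is preserved. Duplicate chromosome names and empty files are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate chromosome {record.id!r} in {fasta_path}")
        seq = str(record.seq).upper()
        if not set(seq) <= _ALLOWED_FASTA:
            bad = sorted(set(seq) - _ALLOWED_FASTA)
            logger.info("chromosome %s: mapping ambiguity codes %s to N", record.id, bad)
            seq = "".join(b if b in _ALLOWED_FASTA else "N" for b in seq)
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_snvs(vcf_path, sample_id: str | None = None, keep_filtered: bool = False) -> MutationCatalogue:
    """Import biallelic single-nucleotide substitutions from a VCF file.

    One VCF is one sample catalogue; genotype columns are ignored. Records
    that are not simple SNVs (indels, MNVs, symbolic/breakend alleles), that
    fail FILTER (unless ``keep_filtered``), or that duplicate an earlier
    (chrom, pos, alt) are excluded and tallied in ``catalogue.skipped``.
    Multi-allelic SNV records are split into one variant per alternate
    allele. Contig names are not validated here (that happens against the
    reference genome later).
    """
    vcf_path = str(vcf_path)
    if sample_id is None:
        sample_id = Path(vcf_path).name
        for suffix in (".gz", ".vcf"):
            if sample_id.endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
    skipped: Counter = Counter()
    snvs: list[Snv] = []
    seen: set[tuple[str, int, str]] = set()
    save = pysam.set_verbosity(0)  # silence the no-index warning
    try:
        with pysam.VariantFile(vcf_path) as vcf:
            for rec in vcf:
                try:
                    filters = list(rec.filter)
                except Exception:
                    filters = []
                if not keep_filtered and filters not in ([], ["PASS"]):
                    skipped["filtered"] += 1
                    continue
                alts = rec.alts or ()
                if not alts:
                    skipped["no_alt"] += 1
                    continue
                ref = (rec.ref or "").upper()
                for alt in alts:
                    alt = (alt or "").upper()
                    if alt.startswith("<") or any(c in alt for c in "[]*."):
                        skipped["symbolic"] += 1
                    elif len(ref) != len(alt):
                        skipped["indel"] += 1
                    elif len(ref) != 1:
                        skipped["mnv"] += 1
                    elif ref not in VALID_BASES or alt not in VALID_BASES:
                        skipped["non_canonical"] += 1
                    elif ref == alt:
                        skipped["ref_equals_alt"] += 1
                    else:
                        key = (rec.chrom, rec.pos, alt)
                        if key in seen:
                            skipped["duplicate"] += 1
                        else:
                            seen.add(key)
                            snvs.append(Snv(rec.chrom, rec.pos, ref, alt))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {vcf_path}: {exc}") from exc
    finally:
        pysam.set_verbosity(save)
    return MutationCatalogue(sample_id=sample_id, snvs=snvs, skipped=skipped)


def write_vcf(catalogue: MutationCatalogue, path, genome: ReferenceGenome | None = None) -> None:
    """Write a catalogue as a minimal sites-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=mutpatterns\n##SAMPLE=<ID={catalogue.sample_id}>\n")
        if genome is not None:
            for name, length in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snv in catalogue.snvs:
            fh.write(f"{snv.chrom}\t{snv.pos}\t.\t{snv.ref}\t{snv.alt}\t.\tPASS\t.\n")


def read_intervals(bed_path, label: str = "", stranded: bool = False) -> IntervalSet:
    """Read a BED3/BED6 file into a 1-based inclusive IntervalSet.

    BED is 0-based half-open; ``start >= end`` lines are rejected. With
    ``stranded=False`` (or when column 6 is absent) the strand is ".".
    """
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: BED start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = "."
            if stranded and len(fields) > 5:
                strand = fields[5]
                if strand not in ("+", "-", "."):
                    raise ValueError(f"{bed_path}:{lineno}: invalid strand {strand!r}")
            intervals.append(Interval(chrom, start + 1, end, strand, name))
    return IntervalSet(intervals, label=label or Path(str(bed_path)).stem)


def write_bed(iset: IntervalSet, path) -> None:
    """Write an IntervalSet as BED6 (coordinates converted back to 0-based half-open)."""
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled matrix (first column = row labels, header = column names)."""
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep=_sep_for(path))


def read_signature_matrix(path) -> pd.DataFrame:
    """Read a 96-channel signature matrix from delimited text.

    Rows are keyed by channel label (e.g. ``A[C>A]A``) and are reordered
    into the canonical channel order; any column whose sum deviates from 1
    by more than 1e-6 is renormalized with a logged notice. Missing or
    duplicated channel labels and negative entries are errors.
    """
    from .channels import CHANNELS_96

    df = read_matrix(path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated channel label(s) {dup} in {path}")
    missing = set(CHANNELS_96) - set(df.index)
    if missing or len(df) != 96:
        raise ValueError(
            f"expected 96 channels in {path}; missing {sorted(missing)[:3]}..."
            if missing
            else f"expected 96 channels in {path}, found {len(df)}"
        )
    df = df.loc[list(CHANNELS_96)].astype(float)
    if (df.values < 0).any():
        raise ValueError(f"negative signature entry in {path}")
    sums = df.sum(axis=0)
    off = (sums - 1.0).abs() > 1e-6
    if off.any():
        logger.info(
            "renormalizing signature column(s) %s (sums deviate from 1)",
            list(df.columns[off]),
        )
        df.loc[:, off] = df.loc[:, off] / sums[off]
    return df
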