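"""Classification of SNVs into substitution types and trinucleotide channels.

Every base substitution is reported in the pyrimidine reference frame: a
G>A call becomes C>T on the opposite strand, and its sequence context is
reverse-complemented accordingly. The 96 channels cross the six
substitution types (C>A, C>G, C>T, T>A, T>C, T>G) with the 5' and 3'
flanking bases, in the column order used by published signature
catalogues: substitution-major, then 5' base A<C<G<T, then 3' base.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import COMPLEMENT, ReferenceGenome, Snv, VALID_BASES, revcomp

logger = logging.getLogger("mutpatterns")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
PYRIMIDINES = frozenset("CT")

#: canonical 96-channel labels, e.g. "A[C>A]A" ... "T[T>G]T"
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

#: with split_cpg, C>T splits into CpG (3' base G) and all other contexts
TYPES_7 = ("C>A", "C>G", "C>T at CpG", "C>T other", "T>A", "T>C", "T>G")

#: minimum classifiable mutations for a representative 96-channel profile
MIN_PROFILE_MUTATIONS = 200


def channel_index(label: str) -> int:
    """Canonical index of a channel label: 16*type + 4*five_prime + three_prime."""
    five, sub, three = parse_channel(label)
    return 16 * SUBSTITUTIONS.index(sub) + 4 * BASES.index(five) + BASES.index(three)


def channel_label(sub: str, five: str, three: str) -> str:
    return f"{five}[{sub}]{three}"


def parse_channel(label: str) -> tuple[str, str, str]:
    """Split "A[C>T]G" into ("A", "C>T", "G")."""
    if len(label) != 7 or label[1] != "[" or label[5] != "]":
        raise ValueError(f"malformed channel label {label!r}")
    five, sub, three = label[0], label[2:5], label[6]
    if sub not in SUBSTITUTIONS or five not in BASES or three not in BASES:
        raise ValueError(f"malformed channel label {label!r}")
    return five, sub, three


def classify_substitution(ref: str, alt: str) -> str:
    """Six-type substitution class in the pyrimidine reference frame."""
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"non-canonical base in {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref equals alt: {ref}>{alt}")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def channel_96(genome: ReferenceGenome, snv: Snv) -> str | None:
    """Trinucleotide channel of an SNV, or None when unclassifiable.

    Unclassifiable means the SNV sits at a chromosome edge (no flanking
    base) or its context contains N. A disagreement between the genome
    base and the variant's REF allele raises RefMismatchError.
    """
    from .core import RefMismatchError

    if snv.chrom not in genome:
        raise ValueError(f"chromosome {snv.chrom!r} absent from genome")
    if snv.pos > genome.lengths[snv.chrom]:
        raise ValueError(f"{snv.chrom}:{snv.pos} beyond chromosome end")
    if genome.base(snv.chrom, snv.pos) != snv.ref:
        raise RefMismatchError(
            f"{snv.chrom}:{snv.pos} genome has {genome.base(snv.chrom, snv.pos)!r} "
            f"but variant REF is {snv.ref!r} — wrong reference build?"
        )
    triplet = genome.context(snv.chrom, snv.pos)
    if triplet is None or "N" in triplet:
        return None
    alt = snv.alt
    if snv.ref not in PYRIMIDINES:
        triplet = revcomp(triplet)
        alt = COMPLEMENT[alt]
    return channel_label(f"{triplet[1]}>{alt}", triplet[0], triplet[2])


def build_mut_matrix(catalogues, genome: ReferenceGenome) -> pd.DataFrame:
    """96 x samples mutation count matrix in canonical channel order.

    Column sums equal the number of classifiable SNVs per sample;
    unclassifiable SNVs (edge/N context) are tallied in the log. Samples
    with fewer than ``MIN_PROFILE_MUTATIONS`` classifiable SNVs trigger a
    UserWarning: such profiles are typically not representative.
    """
    catalogues = list(catalogues)
    if not catalogues:
        raise ValueError("no catalogues given")
    counts = {}
    for cat in catalogues:
        cat.validate_against(genome)
        col = np.zeros(96, dtype=np.int64)
        unclassifiable = 0
        for snv in cat:
            label = channel_96(genome, snv)
            if label is None:
                unclassifiable += 1
            else:
                col[channel_index(label)] += 1
        if unclassifiable:
            logger.info("sample %s: %d unclassifiable SNV(s) excluded", cat.sample_id, unclassifiable)
        total = int(col.sum())
        if total < MIN_PROFILE_MUTATIONS:
            warnings.warn(
                f"sample {cat.sample_id}: only {total} classifiable mutations; "
                f"at least {MIN_PROFILE_MUTATIONS} are typically required for a "
                "representative profile",
                UserWarning,
                stacklevel=2,
            )
        counts[cat.sample_id] = col
    return pd.DataFrame(counts, index=list(CHANNELS_96))


def spectrum_by_type(matrix96: pd.DataFrame, split_cpg: bool = False) -> pd.DataFrame:
    """Collapse a 96-channel matrix to the 6 substitution types per sample.

    With ``split_cpg`` the C>T type is divided into C>T at CpG sites
    (3' neighbour G, i.e. channels N[C>T]G) and C>T at all other sites —
    deamination of 5-methylcytosine acts specifically at CpG.
    """
    if list(matrix96.index) != list(CHANNELS_96):
        raise ValueError("matrix rows are not in canonical 96-channel order")
    rows = {}
    for sub in SUBSTITUTIONS:
        mask = [parse_channel(ch)[1] == sub for ch in CHANNELS_96]
        rows[sub] = matrix96.loc[mask].sum(axis=0)
    if not split_cpg:
        return pd.DataFrame(rows).T.loc[list(SUBSTITUTIONS)]
    cpg = [parse_channel(ch)[1] == "C>T" and parse_channel(ch)[2] == "G" for ch in CHANNELS_96]
    rows["C>T at CpG"] = matrix96.loc[cpg].sum(axis=0)
    rows["C>T other"] = rows["C>T"] - rows["C>T at CpG"]
    del rows["C>T"]
    return pd.DataFrame(rows).T.loc[list(TYPES_7)]


@dataclass
class GroupSpectrum:
    """Per-group mean relative type spectrum with sample standard deviations."""

    mean: pd.DataFrame  # types x groups, columns sum to 1
    sd: pd.DataFrame  # types x groups
    totals: pd.Series  # mutations per group


def group_spectrum(spectrum: pd.DataFrame, groups: dict[str, str]) -> GroupSpectrum:
    """Aggregate a per-sample type spectrum into per-group mean +/- sd.

    Each sample's spectrum is first normalized to sum 1 (all-zero samples
    are excluded with a notice); the group mean and sample standard
    deviation are then taken per category. Single-sample groups report
    sd = 0 with a notice.
    """
    missing = set(spectrum.columns) - set(groups)
    if missing:
        raise ValueError(f"samples missing from group map: {sorted(missing)}")
    totals = spectrum.sum(axis=0)
    keep = totals > 0
    for sample in spectrum.columns[~keep]:
        logger.info("sample %s has zero mutations; excluded from group spectrum", sample)
    rel = spectrum.loc[:, keep] / totals[keep]
    by_group: dict[str, list[str]] = {}
    for sample in rel.columns:
        by_group.setdefault(groups[sample], []).append(sample)
    mean, sd, group_totals = {}, {}, {}
    for group, samples in by_group.items():
        sub = rel[samples]
        mean[group] = sub.mean(axis=1)
        if len(samples) == 1:
            logger.info("group %s has a single sample; sd reported as 0", group)
            sd[group] = pd.Series(0.0, index=rel.index)
        else:
            sd[group] = sub.std(axis=1, ddof=1)
        group_totals[group] = int(totals[samples].sum())
    return GroupSpectrum(
        mean=pd.DataFrame(mean), sd=pd.DataFrame(sd), totals=pd.Series(group_totals)
    )


@dataclass
class ProfileComparison:
    """Difference between two sum-1-normalized mutation profiles."""

    difference: np.ndarray  # p1 - p2 after normalization
    rss: float  # residual sum of squares Σ(p1_i − p2_i)²
    cosine: float


def compare_profiles(p1, p2) -> ProfileComparison:
    """Compare two non-negative profiles of equal length.

    Both are normalized to sum 1; RSS and cosine similarity quantify the
    disagreement (identical profiles: RSS 0, cosine 1).
    """
    from .signatures import cos_sim

    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles have different lengths")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all-zero profile")
    a = a / a.sum()
    b = b / b.sum()
    diff = a - b
    return ProfileComparison(difference=diff, rss=float(diff @ diff), cosine=cos_sim(a, b))
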