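"""Transcriptional and replicative strand asymmetry of somatic mutations.

Gene annotations report the coding (untranscribed) strand. Working in the
pyrimidine reference frame, a mutation whose pyrimidine (C or T) lies on
the same strand as the gene is labelled *untranscribed*; on the opposite
strand, *transcribed*. Transcription-coupled repair acting on the
transcribed strand shows up as an excess of one label.

Replication mode uses the same machinery with a replication-direction
annotation: interval strand "+" denotes a right-moving fork, and the
mutation is labelled *leading* when its pyrimidine strand equals the
interval strand, *lagging* otherwise.

Asymmetry per substitution type is tested with the exact conditional
version of the two-sided equal-rates Poisson test: conditional on the
total n = n1 + n2, n1 is Binomial(n, 1/2) under the null, and
p = min(1, 2 * min(P[X <= n1], P[X >= n1])).
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy.stats import binom, false_discovery_control

from .channels import CHANNELS_96, PYRIMIDINES, SUBSTITUTIONS, channel_96, parse_channel
from .core import IntervalSet, MutationCatalogue, ReferenceGenome

logger = logging.getLogger("mutpatterns")

STRAND_PAIRS = {
    "transcription": ("transcribed", "untranscribed"),
    "replication": ("leading", "lagging"),
}

SIGNIFICANCE_LEVEL = 0.05


def channels_192(mode: str = "transcription") -> list[str]:
    """Canonical 192-row labels: per channel, strand1 then strand2 rows."""
    s1, s2 = STRAND_PAIRS[mode]
    return [f"{ch}-{s}" for ch in CHANNELS_96 for s in (s1, s2)]


def assign_strand(
    catalogue: MutationCatalogue,
    intervals: IntervalSet,
    mode: str = "transcription",
) -> list[str]:
    """Strand label per SNV, in catalogue order.

    Labels are strand1/strand2 of the mode, plus ``outside`` (not covered
    by any interval) and ``ambiguous`` (covered on both annotation
    strands). Same-strand overlaps are merged before assignment.
    """
    if mode not in STRAND_PAIRS:
        raise ValueError(f"unknown mode {mode!r}")
    if len(intervals) == 0 or not intervals.stranded:
        raise ValueError("strand assignment needs a non-empty, stranded interval set")
    s1, s2 = STRAND_PAIRS[mode]
    plus = intervals.merged_by_strand("+").point_lookup()
    minus = intervals.merged_by_strand("-").point_lookup()
    labels = []
    for snv in catalogue:
        on_plus = plus.covers(snv.chrom, snv.pos)
        on_minus = minus.covers(snv.chrom, snv.pos)
        if on_plus and on_minus:
            labels.append("ambiguous")
        elif not on_plus and not on_minus:
            labels.append("outside")
        else:
            anno_strand = "+" if on_plus else "-"
            pyr_strand = "+" if snv.ref in PYRIMIDINES else "-"
            if mode == "transcription":
                # pyrimidine on the coding (annotation) strand -> untranscribed
                labels.append(s2 if pyr_strand == anno_strand else s1)
            else:
                # pyrimidine on the fork-direction strand -> leading
                labels.append(s1 if pyr_strand == anno_strand else s2)
    return labels


def build_mut_matrix_stranded(
    catalogues,
    genome: ReferenceGenome,
    intervals: IntervalSet,
    mode: str = "transcription",
) -> pd.DataFrame:
    """192 x samples stranded mutation count matrix.

    Rows are channel-major with the two strand rows adjacent (strand1
    first). SNVs outside the annotation, on ambiguously annotated
    positions, or unclassifiable by context are excluded and tallied in
    the log.
    """
    catalogues = list(catalogues)
    if not catalogues:
        raise ValueError("no catalogues given")
    index = channels_192(mode)
    row_of = {label: i for i, label in enumerate(index)}
    counts = {}
    for cat in catalogues:
        cat.validate_against(genome)
        labels = assign_strand(cat, intervals, mode)
        col = np.zeros(192, dtype=np.int64)
        excluded = Counter()
        for snv, strand in zip(cat, labels):
            if strand in ("outside", "ambiguous"):
                excluded[strand] += 1
                continue
            channel = channel_96(genome, snv)
            if channel is None:
                excluded["unclassifiable"] += 1
                continue
            col[row_of[f"{channel}-{strand}"]] += 1
        if excluded:
            logger.info("sample %s: excluded from stranded matrix: %s", cat.sample_id, dict(excluded))
        counts[cat.sample_id] = col
    return pd.DataFrame(counts, index=index)


def collapse_stranded(matrix192: pd.DataFrame) -> pd.DataFrame:
    """Sum the two strand rows of each channel (96 x samples marginal)."""
    chans = [label.rsplit("-", 1)[0] for label in matrix192.index]
    out = matrix192.groupby(chans, sort=False).sum()
    return out.loc[list(CHANNELS_96)]


def two_sided_binomial_p(n1: int, n: int) -> float:
    """Two-sided exact p for n1 successes out of n under success prob 1/2.

    Doubling-of-smaller-tail definition: p = min(1, 2 * min(P[X <= n1],
    P[X >= n1])); this is the exact conditional form of the two-sided
    equal-rates Poisson test.
    """
    if n == 0:
        return 1.0
    lower = binom.cdf(n1, n, 0.5)
    upper = binom.sf(n1 - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _strand_sums_by_type(matrix192: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    """(substitution type, strand) -> per-sample counts summed over contexts."""
    sums: dict[tuple[str, str], pd.Series] = {}
    for label in matrix192.index:
        channel, strand = label.rsplit("-", 1)
        sub = parse_channel(channel)[1]
        key = (sub, strand)
        row = matrix192.loc[label]
        sums[key] = sums.get(key, 0) + row
    return sums


def _bias_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["p_adjust"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    df["significant"] = df["p_value"] < SIGNIFICANCE_LEVEL
    return df


def strand_bias_test(matrix192: pd.DataFrame, by: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-group, per-substitution-type strand asymmetry test.

    For each group and each of the 6 substitution types, counts on the
    two strands are pooled over samples and contexts and compared with
    the exact two-sided test at rate 1/2. The effect size is
    log2(n_strand1 / n_strand2) (transcribed/untranscribed in
    transcription mode), undefined (NaN) when either count is zero.
    Raw p-values carry the significance flag (P < 0.05, mirroring common
    practice for these figures); a Benjamini-Hochberg column is always
    included.
    """
    strands = sorted({label.rsplit("-", 1)[1] for label in matrix192.index})
    mode = "transcription" if "transcribed" in strands else "replication"
    s1, s2 = STRAND_PAIRS[mode]
    if by is None:
        by = {s: s for s in matrix192.columns}
    missing = set(matrix192.columns) - set(by)
    if missing:
        raise ValueError(f"samples missing from group map: {sorted(missing)}")
    sums = _strand_sums_by_type(matrix192)
    groups = sorted(set(by.values()), key=list(by.values()).index)
    rows = []
    for group in groups:
        samples = [s for s in matrix192.columns if by[s] == group]
        for sub in SUBSTITUTIONS:
            n1 = int(sums[(sub, s1)][samples].sum())
            n2 = int(sums[(sub, s2)][samples].sum())
            ratio = np.log2(n1 / n2) if n1 > 0 and n2 > 0 else float("nan")
            rows.append(
                {
                    "group": group,
                    "type": sub,
                    f"n_{s1}": n1,
                    f"n_{s2}": n2,
                    "log2_ratio": ratio,
                    "p_value": two_sided_binomial_p(n1, n1 + n2),
                }
            )
    return _bias_table(rows)


def signature_strand_bias(signatures192: pd.DataFrame, total_per_signature) -> pd.DataFrame:
    """Strand asymmetry of stranded (192-feature) signatures.

    Signature loadings are probabilities, so they are scaled by the total
    number of mutations attributed to each signature (from the
    contributions) and rounded to pseudo-counts before applying the same
    exact two-sided binomial test per substitution type.
    """
    if (np.asarray(signatures192) < 0).any():
        raise ValueError("negative signature entries")
    totals = pd.Series(total_per_signature, index=signatures192.columns) if not isinstance(
        total_per_signature, pd.Series
    ) else total_per_signature
    strands = sorted({label.rsplit("-", 1)[1] for label in signatures192.index})
    mode = "transcription" if "transcribed" in strands else "replication"
    s1, s2 = STRAND_PAIRS[mode]
    sums = _strand_sums_by_type(signatures192)
    rows = []
    for sig in signatures192.columns:
        for sub in SUBSTITUTIONS:
            n1 = int(round(sums[(sub, s1)][sig] * totals[sig]))
            n2 = int(round(sums[(sub, s2)][sig] * totals[sig]))
            ratio = np.log2(n1 / n2) if n1 > 0 and n2 > 0 else float("nan")
            rows.append(
                {
                    "group": sig,
                    "type": sub,
                    f"n_{s1}": n1,
                    f"n_{s2}": n2,
                    "log2_ratio": ratio,
                    "p_value": two_sided_binomial_p(n1, n1 + n2),
                }
            )
    return _bias_table(rows)
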